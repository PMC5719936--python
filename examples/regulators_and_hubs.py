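"""Infer module regulators from a reference TF->target network.

TFs whose reference targets are enriched in a module (hypergeometric
p < 0.05) are its candidate regulators, classified by the correlation of the
TF's own profile with the module eigengene (|r| > 0.7).  Mutual reference
edges among retained TFs form the TF-TF subnetwork, scored by HITS hub
centrality.
"""

import emtdyn as e
from emtdyn.benchmarks import detect

# a denser reference network than the default so the TF-TF subnetwork is
# nonempty and hub scoring has something to rank
cfg = e.default_config(seed=0, bg_edge_prob=0.05)
Xa, _, truth = e.generate_timeseries_pair(cfg)
net = e.generate_reference_regnet(cfg, truth)
print(f"reference network: {len(net.edges)} edges, {len(net.tfs)} TFs "
      f"({sum(m is not None for m in truth.tf_module.values())} planted, "
      f"{sum(m is None for m in truth.tf_module.values())} decoys)")

part, eig = detect(Xa)
regs = e.module_regulators(part, eig, net, Xa, p_threshold=0.05,
                           r_threshold=0.7)
planted = {tf for tf, m in truth.tf_module.items() if m is not None}
print(f"\nretained {regs['tf'].nunique()} TFs over "
      f"{regs['module'].nunique()} modules; "
      f"planted-TF recall = {len(set(regs['tf']) & planted) / len(planted):.0%}")
print(regs.head(4).to_string(index=False))

G = e.tf_subnetwork(regs, net)
print(f"\nTF-TF subnetwork: {G.number_of_nodes()} nodes, "
      f"{G.number_of_edges()} edges")
if G.number_of_edges():
    hubs = e.hub_scores(G).sort_values(ascending=False)
    print("top hub regulators (score 1 = most influential):")
    print(hubs.head(3).to_string())
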