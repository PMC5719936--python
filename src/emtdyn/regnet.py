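"""Regulatory-network inference: TF enrichment, classification and hubs.

A transcription factor is called a regulator of a co-expression module when
its reference targets are over-represented among the module's genes
(one-sided hypergeometric test, p < 0.05).  Retained TFs are classified by
the Pearson correlation of their own expression profile with the module
eigengene (positive / negative at |r| > 0.7), the retained TFs' mutual
reference edges form the TF-TF subnetwork, and influence is scored with
Kleinberg's HITS hub centrality (max-normalized to 1).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import TimeSeriesMatrix, ValidationError
from .coexpression import EigengeneSet, ModulePartition
from .simulate import RegulatoryEdges

__all__ = [
    "hypergeom_enrichment",
    "module_regulators",
    "tf_subnetwork",
    "hub_scores",
]


def hypergeom_enrichment(module_genes, tf_targets, universe) -> dict:
    """Upper-tail hypergeometric p-value of the module/target overlap.

    With ``N = |universe|`` genes of which ``K`` are TF targets, drawing the
    ``n`` module genes without replacement, returns
    ``p = P(X >= overlap)`` computed as an exact survival-function tail in
    log space (scipy's hypergeometric distribution).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe is empty")
    module_genes = set(module_genes) & universe
    tf_targets = set(tf_targets) & universe
    if not module_genes:
        raise ValidationError("module has no genes inside the universe")
    N, K, n = len(universe), len(tf_targets), len(module_genes)
    overlap = len(module_genes & tf_targets)
    # P(X >= overlap); sf(overlap - 1) is exact and stable
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    return {"overlap": overlap, "K": K, "n": n, "N": N, "pvalue": min(p, 1.0)}


def module_regulators(
    modules: ModulePartition,
    eig: EigengeneSet,
    regnet: RegulatoryEdges,
    tf_expr: TimeSeriesMatrix,
    p_threshold: float = 0.05,
    r_threshold: float = 0.7,
    universe=None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-module TF enrichment with eigengene-correlation classes.

    The test universe defaults to the intersection of the expression genes
    and the reference network's target space.  TFs with enrichment
    ``p < p_threshold`` (strict) are retained per module, each labelled
    ``positive`` (r > r_threshold), ``negative`` (r < -r_threshold) or
    ``unclassified`` (in between, or TF missing from ``tf_expr``).  Results
    are sorted by p-value within modules.  ``bh_correct=True`` applies a
    Benjamini-Hochberg adjustment per module before thresholding.
    """
    if universe is None:
        universe = set(tf_expr.gene_ids) & set(regnet.edges["target"])
    universe = set(universe)
    targets_by_tf = {
        tf: set(sub["target"]) for tf, sub in regnet.edges.groupby("tf")
    }
    expr_genes = set(tf_expr.gene_ids)
    n_stages = tf_expr.values.shape[1]
    Ze = eig.profiles.to_numpy()
    Ze = (Ze - Ze.mean(axis=1, keepdims=True)) / Ze.std(axis=1, keepdims=True)

    rows = []
    for mi, m in enumerate(eig.modules):
        module_genes = set(modules.members(m)) & universe
        if not module_genes:
            continue
        tf_list, pvals, overlaps, Ks = [], [], [], []
        for tf, targets in targets_by_tf.items():
            res = hypergeom_enrichment(module_genes, targets, universe)
            tf_list.append(tf)
            pvals.append(res["pvalue"])
            overlaps.append(res["overlap"])
            Ks.append(res["K"])
        pvals = np.asarray(pvals)
        shown = multipletests(pvals, method="fdr_bh")[1] if bh_correct else pvals
        for tf, p, ov, K in zip(tf_list, shown, overlaps, Ks):
            if not p < p_threshold:
                continue
            if tf in expr_genes:
                prof = tf_expr.values.loc[tf].to_numpy()
                sd = prof.std()
                if sd > 0:
                    zt = (prof - prof.mean()) / sd
                    r = float(zt @ Ze[mi] / n_stages)
                else:
                    r = float("nan")
            else:
                r = float("nan")
            if np.isnan(r):
                cls = "unclassified"
            elif r > r_threshold:
                cls = "positive"
            elif r < -r_threshold:
                cls = "negative"
            else:
                cls = "unclassified"
            rows.append((m, tf, ov, K, len(module_genes), len(universe), p, r, cls))
    out = pd.DataFrame(
        rows,
        columns=["module", "tf", "overlap", "K", "n", "N", "pvalue", "r", "class"],
    )
    return out.sort_values(["module", "pvalue", "tf"]).reset_index(drop=True)


def tf_subnetwork(regulators: pd.DataFrame, regnet: RegulatoryEdges) -> nx.DiGraph:
    """Directed network among retained TFs, using reference edges only.

    Nodes are the TFs appearing in ``regulators``; an edge TF1 -> TF2 exists
    iff the reference list contains it.  Node attribute ``cls`` carries the
    correlation class (a TF retained for several modules keeps the class of
    its most significant enrichment).
    """
    if regulators.empty:
        return nx.DiGraph()
    best = regulators.sort_values("pvalue").drop_duplicates("tf")
    cls = dict(zip(best["tf"], best["class"]))
    G = nx.DiGraph()
    for tf, c in cls.items():
        G.add_node(tf, cls=c)
    retained = set(cls)
    e = regnet.edges
    mask = e["tf"].isin(retained) & e["target"].isin(retained)
    G.add_edges_from(e.loc[mask, ["tf", "target"]].itertuples(index=False))
    return G


def hub_scores(
    network: nx.DiGraph,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> pd.Series:
    """Kleinberg HITS hub centrality, max-normalized to 1.

    Power iteration with alternating hub/authority normalization on the
    adjacency matrix A (hubs are the principal eigenvector of ``A @ A.T``).
    An edgeless network returns all-zero scores with a warning.
    """
    nodes = list(network.nodes)
    if not nodes:
        raise ValidationError("network has no nodes")
    if network.number_of_edges() == 0:
        warnings.warn("edgeless network: all hub scores are 0")
        return pd.Series(0.0, index=nodes, name="hub_score")
    A = nx.to_numpy_array(network, nodelist=nodes, weight=None)
    h = np.ones(len(nodes))
    for _ in range(max_iter):
        a = A.T @ h
        norm = np.linalg.norm(a)
        if norm > 0:
            a /= norm
        h_new = A @ a
        norm = np.linalg.norm(h_new)
        if norm > 0:
            h_new /= norm
        if np.abs(h_new - h).max() < tol:
            h = h_new
            break
        h = h_new
    h = np.abs(h)
    h /= h.max()
    return pd.Series(h, index=nodes, name="hub_score")
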