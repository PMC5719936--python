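"""Stage a bulk cohort by personalized EMT period and stratify survival.

Each patient is assigned the time-course stage whose signature-gene profile
best correlates with the patient's expression (PEP).  PEP hours pool into
named clusters; major clusters (> 10 patients) are compared by Kaplan-Meier
curves, the log-rank test, and Cox hazard ratios against the earliest
cluster.
"""

import emtdyn as e

cfg = e.default_config(seed=0)
Xa, _, truth = e.generate_timeseries_pair(cfg)
cohort, surv = e.generate_patient_cohort(cfg, truth, Xa)

signature = truth.gene_module.index[truth.gene_module != "background"]
profiles = e.stage_profiles(Xa, signature)
pep = e.assign_pep(cohort, profiles)
truth_hours = Xa.stages[truth.patient_stage.values]
print(f"staged {len(pep)} patients over {len(signature)} signature genes; "
      f"exact stage recovery = {(pep['pep_hours'].values == truth_hours).mean():.1%}")

pep["cluster"] = e.pool_pep_bins(pep["pep_hours"])
print("\ncluster sizes:")
print(pep["cluster"].value_counts().to_string())

reports, pmat = e.silhouette_compare(
    cohort, pep["cluster"],
    {"signature": signature, "all_genes": cohort.gene_ids})
print(f"\nmean silhouette in signature space: {reports['signature'].mean:.3f}"
      f" vs all-gene space: {reports['all_genes'].mean:.3f}")

data = e.make_survival_data(surv, pep["cluster"])
data = e.filter_major_clusters(data, min_n=10, reference="h0-8")
lr = e.logrank_test(data)
print(f"\nlog-rank over {data['group'].nunique()} PEP clusters: "
      f"chi2 = {lr.statistic:.2f} (df {lr.df}), p = {lr.pvalue:.2e}")
cox = e.cox_hazard_ratios(data, reference="h0-8")
print("hazard ratios vs the h0-8 reference cluster:")
print(cox.table.round(3).to_string(index=False))
# HR > 1 means later EMT periods carry higher mortality, mirroring the
# planted per-stage log hazard ratios (0, 0.3, 0.7, 1.1).
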