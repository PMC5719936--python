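"""Planted-truth benchmark studies used for validation.

Each function simulates a study under the package's standard synthetic
conditions, runs the relevant pipeline stages, and measures recovery of the
planted structure (module ARI, eigengene fidelity, signature recall,
TF recall / false-positive rate, PEP stage recovery, silhouette contrast,
survival-model calibration).  All randomness is controlled by an explicit
seed; child seeds are spawned deterministically per replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import coexpression as cx
from . import regnet as rn
from . import signature as sg
from . import staging as st
from . import survival as sv
from .containers import TimeSeriesMatrix
from .simulate import (
    SimConfig,
    default_config,
    generate_patient_cohort,
    generate_reference_regnet,
    generate_timeseries_pair,
    sample_survival,
    signature_config,
    staging_config,
)

__all__ = [
    "detect",
    "module_recovery",
    "signature_recovery",
    "tf_recall",
    "decoy_false_positive_rate",
    "hits_eigen_agreement",
    "pep_recovery",
    "silhouette_contrast_winrate",
    "cox_hr_recovery",
    "logrank_null_type1",
]

BETA = 6
MIN_SIZE = 30


def _child(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31)


def detect(X: TimeSeriesMatrix, min_size: int = MIN_SIZE, beta: int = BETA):
    """Standard detection chain on one dataset (signed network)."""
    corr = cx.correlation_matrix(X)
    adj = cx.adjacency(corr, beta, mode="signed")
    tom = cx.tom_similarity(adj)
    part = cx.detect_modules(tom, min_size=min_size, expr=X)
    eig = cx.module_eigengenes(X, part)
    return part, eig


def module_recovery(seed: int, config: SimConfig | None = None) -> dict:
    """Detect modules in both datasets; score ARI against the planted
    partition and eigengene fidelity against the planted module profiles."""
    cfg = config or default_config(seed=seed)
    Xa, Xb, truth = generate_timeseries_pair(cfg)
    out = {"truth": truth, "cfg": cfg, "X": {"a": Xa, "b": Xb}, "ari": {},
           "eig_min_abs_r": {}, "parts": {}, "eigs": {}}
    for tag, X in (("a", Xa), ("b", Xb)):
        part, eig = detect(X)
        ari = adjusted_rand_score(
            truth.gene_module.values,
            part.assignment.loc[truth.gene_module.index].values,
        )
        worst = 1.0
        for m in part.module_labels:
            best = max(
                abs(np.corrcoef(eig.profiles.loc[m],
                                truth.module_profile(pm, X.stages))[0, 1])
                for pm in truth.module_archetype
            )
            worst = min(worst, best)
        out["ari"][tag] = float(ari)
        out["eig_min_abs_r"][tag] = float(worst)
        out["parts"][tag], out["eigs"][tag] = part, eig
    return out


def signature_recovery(seed: int, k: int = 50) -> dict:
    """Run the full signature extraction on the signature-scale study and
    score recall of planted dynamic-module genes and background
    contamination of the recovered list."""
    cfg = signature_config(seed=seed)
    Xa, Xb, truth = generate_timeseries_pair(cfg)
    cands = {}
    for tag, X in (("a", Xa), ("b", Xb)):
        part, eig = detect(X)
        mem = sg.module_membership(X, eig)
        flags = sg.flag_emt_modules(X.restrict(truth.seed_emt_genes), eig)
        cands[tag] = sg.top_membership_genes(mem, flags, k=k)
    signature = sg.intersect_signature(cands["a"], cands["b"])
    planted = set(truth.gene_module.index[truth.gene_module != "background"])
    got = set(signature.genes)
    recall = len(got & planted) / len(planted)
    contamination = len(got - planted) / max(len(got), 1)
    return {"recall": recall, "contamination": contamination,
            "signature_size": len(got), "n_planted": len(planted)}


def tf_recall(seed: int, n_seeds: int = 5, p_threshold: float = 0.05) -> dict:
    """Fraction of planted TFs recovered as regulators of some module."""
    found = total = 0
    for i in range(n_seeds):
        cfg = default_config(seed=_child(seed, 10 + i))
        Xa, _, truth = generate_timeseries_pair(cfg)
        net = generate_reference_regnet(cfg, truth)
        part, eig = detect(Xa)
        regs = rn.module_regulators(part, eig, net, Xa,
                                    p_threshold=p_threshold)
        planted = {tf for tf, m in truth.tf_module.items() if m is not None}
        found += len(set(regs["tf"]) & planted)
        total += len(planted)
    return {"recall": found / total, "n_tfs": total}


def decoy_false_positive_rate(
    seed: int, n_sims: int = 100, p_threshold: float = 0.05
) -> dict:
    """Per-(module, decoy TF) retention rate under the null.

    Decoy TFs draw targets uniformly, so any module enrichment is a false
    positive; the rate at p < 0.05 should sit near (at most) 5%.
    """
    cfg = default_config(seed=seed, n_tfs=24)  # 8 planted + 16 decoys
    Xa, _, truth = generate_timeseries_pair(cfg)
    universe = set(truth.gene_module.index)
    modules = {m: set(truth.module_members(m))
               for m in truth.module_archetype}
    hits = total = 0
    for i in range(n_sims):
        cfg_i = default_config(seed=_child(seed, 100 + i), n_tfs=24)
        net = generate_reference_regnet(cfg_i, truth)
        for tf, m in truth.tf_module.items():
            if m is not None:
                continue
            targets = net.targets_of(tf)
            for module_genes in modules.values():
                res = rn.hypergeom_enrichment(module_genes, targets, universe)
                hits += res["pvalue"] < p_threshold
                total += 1
    return {"fpr": hits / total, "n_tests": total}


def hits_eigen_agreement(seed: int, n_networks: int = 50, n_nodes: int = 8) -> dict:
    """Max deviation of the HITS hub vector from the principal eigenvector
    of A A^T over random digraphs, plus the max-normalization check."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    max_dev, min_max_score = 0.0, 1.0
    for _ in range(n_networks):
        A = (rng.random((n_nodes, n_nodes)) < 0.35).astype(float)
        np.fill_diagonal(A, 0.0)
        if A.sum() == 0:
            A[0, 1] = 1.0
        G = nx.from_numpy_array(A, create_using=nx.DiGraph)
        h = rn.hub_scores(G).to_numpy()
        w, V = np.linalg.eigh(A @ A.T)
        want = np.abs(V[:, np.argmax(w)])
        want /= want.max()
        max_dev = max(max_dev, float(np.abs(h - want).max()))
        min_max_score = min(min_max_score, float(h.max()))
    return {"max_dev": max_dev, "min_max_score": min_max_score}


def pep_recovery(seed: int) -> dict:
    """Fraction of synthetic patients assigned their planted stage when
    staged against the planted signature genes (patient noise 0.5 x signal)."""
    cfg = default_config(seed=seed)
    Xa, _, truth = generate_timeseries_pair(cfg)
    cohort, _ = generate_patient_cohort(cfg, truth, Xa)
    sig_genes = truth.gene_module.index[truth.gene_module != "background"]
    profiles = st.stage_profiles(Xa, sig_genes)
    pep = st.assign_pep(cohort, profiles)
    true_hours = Xa.stages[truth.patient_stage.values]
    rate = float((pep["pep_hours"].values == true_hours).mean())
    return {"recovery": rate, "n_patients": cfg.n_patients}


def silhouette_contrast_winrate(seed: int, n_sims: int = 100) -> dict:
    """How often PEP clusters are tighter in planted-signature space than in
    an equal-size random gene set (the cohort-clustering contrast)."""
    wins = 0
    for i in range(n_sims):
        cfg = staging_config(seed=_child(seed, 200 + i))
        Xa, _, truth = generate_timeseries_pair(cfg)
        cohort, _ = generate_patient_cohort(cfg, truth, Xa)
        sig = truth.gene_module.index[truth.gene_module != "background"]
        profiles = st.stage_profiles(Xa, sig)
        pep = st.assign_pep(cohort, profiles)
        labels = st.pool_pep_bins(pep["pep_hours"])
        rng = np.random.default_rng(_child(seed, 500 + i))
        random_set = rng.choice(cohort.gene_ids, size=len(sig), replace=False)
        reports, _ = st.silhouette_compare(
            cohort, labels, {"signature": sig, "random": random_set}
        )
        wins += reports["signature"].mean > reports["random"].mean
    return {"win_rate": wins / n_sims, "n_sims": n_sims}


def cox_hr_recovery(
    seed: int, n_sims: int = 100, n: int = 500,
    true_hr: float = 2.0, band: tuple = (1.6, 2.5),
) -> dict:
    """Two-group exponential survival with a known hazard ratio: fraction of
    replicates whose Cox estimate lands inside the recovery band."""
    rng = np.random.default_rng(seed)
    inside = 0
    for _ in range(n_sims):
        stage = rng.integers(0, 2, size=n)
        s = sample_survival(stage, [0.0, np.log(true_hr)], 0.02, 120.0, rng)
        data = pd.DataFrame(
            {"sample": np.arange(n), "time_months": s["time_months"],
             "event": s["event"],
             "group": np.where(stage == 0, "ref", "exposed")})
        hr = sv.cox_hazard_ratios(data, reference="ref").table["hr"].iloc[0]
        inside += band[0] <= hr <= band[1]
    return {"coverage": inside / n_sims, "n_sims": n_sims, "n": n}


def logrank_null_type1(
    seed: int, n_sims: int = 500, n: int = 200, alpha: float = 0.05
) -> dict:
    """Log-rank false-positive rate when the two groups share one hazard."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        stage = rng.integers(0, 2, size=n)
        s = sample_survival(stage, [0.0, 0.0], 0.02, 120.0, rng)
        data = pd.DataFrame(
            {"sample": np.arange(n), "time_months": s["time_months"],
             "event": s["event"],
             "group": np.where(stage == 0, "g0", "g1")})
        hits += sv.logrank_test(data).pvalue < alpha
    return {"type1": hits / n_sims, "n_sims": n_sims}
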