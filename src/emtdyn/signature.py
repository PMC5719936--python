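"""EMT-dynamic signature extraction and temporal grouping.

A module is flagged as an *EMT module* when its eigengene correlates strongly
(r > 0.9 by default) with at least one seed EMT gene's time-course profile.
The per-dataset candidate set takes the top-k genes by module membership
(kME) of every flagged module; the cross-dataset signature is the
intersection of the two candidate sets, carrying per-dataset provenance
(source module, membership, rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .containers import PatientMatrix, TimeSeriesMatrix, ValidationError
from .coexpression import EigengeneSet

__all__ = [
    "module_membership",
    "flag_emt_modules",
    "top_membership_genes",
    "intersect_signature",
    "DynamicSignature",
    "temporal_groups",
    "gene_set_correlation_contrast",
    "ContrastReport",
]


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=1, keepdims=True)
    return (M - M.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)


def module_membership(X: TimeSeriesMatrix, eig: EigengeneSet) -> pd.DataFrame:
    """kME matrix: Pearson r of every gene profile with every eigengene."""
    if X.values.shape[1] != eig.profiles.shape[1] or not np.allclose(
        X.stages, eig.stages
    ):
        raise ValidationError("expression and eigengenes use different stage grids")
    n = X.values.shape[1]
    Zg = _standardize_rows(X.values.to_numpy())
    Ze = _standardize_rows(eig.profiles.to_numpy())
    kme = Zg @ Ze.T / n
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=X.gene_ids, columns=eig.modules
    )


def flag_emt_modules(
    seed_expr: TimeSeriesMatrix,
    eig: EigengeneSet,
    r_threshold: float = 0.9,
    absolute: bool = False,
) -> pd.DataFrame:
    """Flag modules whose eigengene tracks at least one seed EMT gene.

    A module is flagged iff the maximum over seed genes of
    r(seed profile, eigengene) strictly exceeds ``r_threshold``.  By default
    the signed correlation is used; ``absolute=True`` flags anti-correlated
    seeds as well.

    Returns a frame indexed by module with columns ``flagged``,
    ``best_seed`` and ``best_r``.
    """
    if seed_expr.n_genes == 0:
        raise ValidationError("seed gene list is empty")
    kme = module_membership(seed_expr, eig)
    scores = kme.abs() if absolute else kme
    best_idx = scores.values.argmax(axis=0)
    best_r = scores.values[best_idx, np.arange(scores.shape[1])]
    return pd.DataFrame(
        {
            "flagged": best_r > r_threshold,
            "best_seed": seed_expr.gene_ids[best_idx],
            "best_r": best_r,
        },
        index=scores.columns,
    )


def top_membership_genes(
    mem: pd.DataFrame,
    flags: pd.DataFrame,
    k: int = 50,
    absolute: bool = False,
) -> pd.DataFrame:
    """Top-k genes by membership of every flagged module (union).

    Ranking is by descending signed kME (``absolute=True`` ranks by |kME|),
    ties broken by lexicographic gene ID.  Modules with fewer than ``k``
    genes contribute all of them.  Returns one row per (gene, module) pair
    with columns ``gene, module, kme, rank``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    flagged = flags.index[flags["flagged"]]
    if len(flagged) == 0:
        warnings.warn("no flagged modules; candidate set is empty")
        return pd.DataFrame(columns=["gene", "module", "kme", "rank"])
    rows = []
    for m in flagged:
        col = mem[m]
        score = col.abs() if absolute else col
        order = sorted(zip(-score.values, col.index), key=lambda t: (t[0], t[1]))
        for rank, (neg, gene) in enumerate(order[:k], start=1):
            rows.append((gene, m, float(col.loc[gene]), rank))
    return pd.DataFrame(rows, columns=["gene", "module", "kme", "rank"])


@dataclass
class DynamicSignature:
    """Cross-dataset EMT-dynamic gene list with per-dataset provenance."""

    table: pd.DataFrame  # gene, module_a, kme_a, rank_a, module_b, kme_b, rank_b

    @property
    def genes(self) -> list:
        return self.table["gene"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def _best_provenance(cand: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: the module where its membership is largest."""
    idx = cand.groupby("gene")["kme"].idxmax()
    return cand.loc[idx].set_index("gene")


def intersect_signature(
    cand_a: pd.DataFrame, cand_b: pd.DataFrame
) -> DynamicSignature:
    """Genes in the top-k candidate sets of BOTH datasets, sorted by ID.

    A gene selected via several flagged modules keeps the provenance of its
    best (largest-kME) module in each dataset.  An empty intersection is
    allowed but warned about.
    """
    genes_a = set(cand_a["gene"]) if len(cand_a) else set()
    genes_b = set(cand_b["gene"]) if len(cand_b) else set()
    common = sorted(genes_a & genes_b)
    if not common:
        warnings.warn("cross-dataset signature is empty")
        return DynamicSignature(
            pd.DataFrame(columns=["gene", "module_a", "kme_a", "rank_a",
                                  "module_b", "kme_b", "rank_b"])
        )
    pa = _best_provenance(cand_a).loc[common]
    pb = _best_provenance(cand_b).loc[common]
    table = pd.DataFrame(
        {
            "gene": common,
            "module_a": pa["module"].values,
            "kme_a": pa["kme"].values,
            "rank_a": pa["rank"].values,
            "module_b": pb["module"].values,
            "kme_b": pb["kme"].values,
            "rank_b": pb["rank"].values,
        }
    )
    return DynamicSignature(table)


def temporal_groups(
    X: TimeSeriesMatrix,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """PCA + K-means grouping of genes by temporal pattern.

    Genes (standardized across stages) are projected on the first two
    principal components and clustered by K-means with ``k`` centers and
    ``n_restarts`` initializations, keeping the best inertia.  Returns a
    frame indexed by gene with columns ``PC1, PC2, group`` (groups 1..k).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if X.n_genes < k:
        raise ValidationError(f"need at least k={k} genes, got {X.n_genes}")
    Zg = _standardize_rows(X.values.to_numpy())
    n_comp = min(2, Zg.shape[1])
    coords = PCA(n_components=n_comp, random_state=seed).fit_transform(Zg)
    if n_comp == 1:
        coords = np.c_[coords, np.zeros(len(coords))]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(coords)
    return pd.DataFrame(
        {"PC1": coords[:, 0], "PC2": coords[:, 1], "group": labels + 1},
        index=X.gene_ids,
    )


@dataclass
class ContrastReport:
    """Welch t / KS comparison of per-gene covariate correlations."""

    gene_r: pd.Series          # per-gene Pearson r with the covariate
    set_genes: list
    t_statistic: float
    t_pvalue: float
    ks_statistic: float
    ks_pvalue: float
    set_mean_r: float
    complement_mean_r: float


def gene_set_correlation_contrast(
    cohort: PatientMatrix,
    covariate,
    set_genes,
    log_transform: bool = True,
) -> ContrastReport:
    """Do ``set_genes`` correlate with a per-sample covariate more than the rest?

    Computes the per-gene Pearson correlation between expression (by default
    log2(x+1)-transformed) and the covariate across samples, then compares
    the correlation distributions of the gene set against its complement via
    a Welch two-sample t-test and a two-sample Kolmogorov-Smirnov test.
    This mirrors the tumor-purity contrast used to show that dynamic
    signature genes track sample composition.
    """
    covariate = np.asarray(covariate, dtype=float)
    if len(covariate) != len(cohort.sample_ids):
        raise ValidationError("covariate length must equal the number of samples")
    set_genes = pd.Index(set_genes)
    missing = set_genes.difference(cohort.gene_ids)
    if len(missing):
        raise ValidationError(f"set genes absent from cohort: {missing[:5].tolist()}")
    if len(set_genes) == len(cohort.gene_ids):
        raise ValidationError("complement gene set is empty")
    M = cohort.log2().to_numpy() if log_transform else cohort.values.to_numpy()
    Zm = _standardize_rows(M)
    zc = (covariate - covariate.mean()) / covariate.std()
    r = pd.Series(Zm @ zc / len(covariate), index=cohort.gene_ids)
    in_set = cohort.gene_ids.isin(set_genes)
    r_set, r_comp = r[in_set], r[~in_set]
    t_stat, t_p = stats.ttest_ind(r_set, r_comp, equal_var=False)
    ks_stat, ks_p = stats.ks_2samp(r_set, r_comp)
    return ContrastReport(
        gene_r=r,
        set_genes=set_genes.tolist(),
        t_statistic=float(t_stat),
        t_pvalue=float(t_p),
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        set_mean_r=float(r_set.mean()),
        complement_mean_r=float(r_comp.mean()),
    )
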