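"""Personalized EMT period (PEP) staging of bulk cohort samples.

Each patient sample is assigned the EMT time-course stage whose signature-
gene expression profile is maximally Pearson-correlated with the sample's
own profile.  Cluster quality of the resulting staging is assessed by PCA
scatter and silhouette values in competing gene-set spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .containers import PatientMatrix, TimeSeriesMatrix, ValidationError

__all__ = [
    "stage_profiles",
    "assign_pep",
    "pool_pep_bins",
    "patient_pca",
    "silhouette_compare",
    "SilhouetteReport",
    "DEFAULT_PEP_BINS",
]

# pooled PEP clusters (bin upper edges in hours -> labels); the last label
# catches everything beyond the final edge
DEFAULT_PEP_BINS = ((8.0, "h0-8"), (24.0, "h16-24"), (72.0, "h72"),
                    (168.0, "h168"), (float("inf"), ">h500"))


def stage_profiles(timecourse: TimeSeriesMatrix, signature_genes) -> TimeSeriesMatrix:
    """Restrict a cell-line time course to the signature genes (stage profiles)."""
    return timecourse.restrict(pd.Index(signature_genes))


def assign_pep(
    cohort: PatientMatrix,
    stages: TimeSeriesMatrix,
    log_transform: bool = True,
    zscore_genes: bool = False,
) -> pd.DataFrame:
    """Assign every sample its personalized EMT period.

    For each sample, Pearson r between its (by default log2(x+1)) expression
    and every stage column of ``stages`` is computed over the shared
    signature genes; the assigned stage is the argmax, ties resolved toward
    the earliest stage.  Samples with zero variance over the signature genes
    are left unassigned (NaN) with a warning.

    Returns a frame indexed by sample with ``pep_hours``, ``r_max`` and one
    ``r_h{stage}`` column per stage.
    """
    shared = stages.gene_ids.intersection(cohort.gene_ids)
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 shared signature genes to correlate, got {len(shared)}"
        )
    S = stages.restrict(shared).values.to_numpy()
    C = cohort.values.loc[shared].to_numpy()
    if log_transform:
        C = np.log2(C + 1.0)
    if zscore_genes:
        def z(M):
            sd = M.std(axis=1, keepdims=True)
            return (M - M.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)
        S, C = z(S), z(C)

    def col_standardize(M):
        sd = M.std(axis=0, keepdims=True)
        return (M - M.mean(axis=0, keepdims=True)) / np.where(sd == 0, 1, sd), sd

    Zs, _ = col_standardize(S)
    Zc, c_sd = col_standardize(C)
    R = Zc.T @ Zs / len(shared)          # samples x stages
    hours = stages.stages
    degenerate = (c_sd == 0).ravel()
    best = R.argmax(axis=1)              # argmax takes the first (earliest) tie
    pep = hours[best].astype(float)
    r_max = R[np.arange(len(best)), best]
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) have zero variance over the "
            "signature genes and were left unassigned"
        )
        pep[degenerate] = np.nan
        r_max[degenerate] = np.nan
    out = pd.DataFrame(
        {"pep_hours": pep, "r_max": r_max}, index=cohort.sample_ids
    )
    for j, h in enumerate(hours):
        col = R[:, j].copy()
        col[degenerate] = np.nan
        out[f"r_h{h:g}"] = col
    return out


def pool_pep_bins(pep_hours: pd.Series, bins=DEFAULT_PEP_BINS) -> pd.Series:
    """Pool per-sample PEP hours into named clusters (e.g. h0-8, h16-24)."""
    edges = [b[0] for b in bins]
    labels = [b[1] for b in bins]
    def _label(h):
        if pd.isna(h):
            return np.nan
        for edge, lab in zip(edges, labels):
            if h <= edge:
                return lab
        return labels[-1]
    return pep_hours.map(_label).rename("pep_cluster")


def patient_pca(
    cohort: PatientMatrix,
    gene_set,
    scale: bool = False,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PC1/PC2 coordinates of samples in a gene set's expression space.

    Samples are observations and genes features; features are centered
    (optionally scaled to unit variance).  Returns the coordinate frame
    (indexed by sample) and the explained-variance fractions.
    """
    genes = pd.Index(gene_set).intersection(cohort.gene_ids)
    if len(genes) < 2:
        raise ValidationError(f"need >= 2 usable genes for PCA, got {len(genes)}")
    M = cohort.values.loc[genes].to_numpy().T
    if log_transform:
        M = np.log2(M + 1.0)
    M = M - M.mean(axis=0, keepdims=True)
    if scale:
        sd = M.std(axis=0, keepdims=True)
        M = M / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=2)
    coords = pca.fit_transform(M)
    df = pd.DataFrame(coords, index=cohort.sample_ids, columns=["PC1", "PC2"])
    return df, pca.explained_variance_ratio_


@dataclass
class SilhouetteReport:
    """Per-sample silhouettes of the PEP clustering in one gene-set space."""

    samples: pd.Series      # per-sample silhouette values
    mean: float


def silhouette_compare(
    cohort: PatientMatrix,
    labels: pd.Series,
    gene_sets: dict,
    log_transform: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Silhouette distributions of one clustering under several gene sets.

    Distances are Euclidean in each gene set's (by default log2(x+1))
    expression space; singleton clusters score 0.  Returns per-set
    :class:`SilhouetteReport` objects plus a frame of pairwise Welch t-test
    p-values between the per-sample silhouette distributions.
    """
    labels = labels.reindex(cohort.sample_ids).dropna()
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("silhouette needs >= 2 clusters")
    samples = labels.index
    reports = {}
    for name, genes in gene_sets.items():
        genes = pd.Index(genes).intersection(cohort.gene_ids)
        if len(genes) == 0:
            raise ValidationError(f"gene set {name!r} shares no genes with cohort")
        M = cohort.values.loc[genes, samples].to_numpy().T
        if log_transform:
            M = np.log2(M + 1.0)
        sil = silhouette_samples(M, labels.values)
        reports[name] = SilhouetteReport(
            samples=pd.Series(sil, index=samples), mean=float(np.mean(sil))
        )
    names = list(reports)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                        columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            _, p = stats.ttest_ind(
                reports[a].samples, reports[b].samples, equal_var=False
            )
            pmat.loc[a, b] = pmat.loc[b, a] = float(p)
    return reports, pmat
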