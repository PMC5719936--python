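"""Weighted gene co-expression network construction and module detection.

The workflow follows the weighted correlation network analysis recipe:
Pearson correlation of time-course profiles -> soft-thresholded adjacency
(unsigned ``|r|**beta`` or signed ``((1+r)/2)**beta``) -> topological overlap
similarity -> average-linkage hierarchical clustering of ``1 - TOM`` with a
constant-height cut -> per-module eigengenes (first principal component of
the standardized member profiles).

Determinism: genes are processed in lexicographic ID order, so permuting the
input row order permutes assignments identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import TimeSeriesMatrix, ValidationError

__all__ = [
    "SoftPowerReport",
    "ModulePartition",
    "EigengeneSet",
    "correlation_matrix",
    "pick_soft_power",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_eigengenes",
]

UNASSIGNED = "unassigned"


def correlation_matrix(X: TimeSeriesMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation of time-course profiles.

    Zero-variance genes are rejected by name; filter them upstream with
    :meth:`TimeSeriesMatrix.drop_zero_variance`.
    """
    sd = X.values.std(axis=1, ddof=0)
    bad = X.gene_ids[sd == 0]
    if len(bad):
        raise ValidationError(
            f"zero-variance genes cannot be correlated: {bad[:5].tolist()}"
        )
    C = np.corrcoef(X.values.to_numpy())
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=X.gene_ids, columns=X.gene_ids)


def adjacency(corr: pd.DataFrame, beta: int, mode: str = "unsigned") -> pd.DataFrame:
    """Soft-thresholded network adjacency with zero diagonal.

    ``unsigned``: ``|r|**beta`` (anti-correlated genes stay connected);
    ``signed``: ``((1+r)/2)**beta`` (anti-correlation maps to ~0).
    """
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    r = corr.to_numpy()
    if mode == "unsigned":
        a = np.abs(r) ** beta
    elif mode == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValidationError(f"mode must be 'unsigned' or 'signed', got {mode!r}")
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


@dataclass
class SoftPowerReport:
    """Scale-free fit diagnostics per candidate soft power."""

    table: pd.DataFrame        # power, fit_r2, mean_connectivity
    chosen_power: int
    target_fit: float
    fallback: bool             # True if no power reached target_fit

    @property
    def candidate_powers(self) -> list:
        return self.table["power"].tolist()


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10 p(k) against log10 k over connectivity bins.

    Empty bins are dropped; returns NaN when fewer than 3 usable bins remain
    (degenerate connectivity).
    """
    k = k[k > 0]
    if len(k) == 0 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def pick_soft_power(
    corr: pd.DataFrame,
    powers=tuple(range(1, 21)),
    target_fit: float = 0.8,
    mode: str = "unsigned",
) -> SoftPowerReport:
    """Choose the soft-threshold power by scale-free topology fit.

    The chosen power is the smallest candidate whose fit exceeds
    ``target_fit``; when none does, the best-fitting power is used and the
    report is flagged as a fallback.
    """
    powers = list(powers)
    if not powers:
        raise ValidationError("powers must be nonempty")
    rows = []
    for beta in powers:
        a = adjacency(corr, beta, mode=mode).to_numpy()
        k = a.sum(axis=1)
        if np.ptp(k) == 0:
            rows.append((beta, float("nan"), float(k.mean())))
            continue
        rows.append((beta, _scale_free_fit(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit_r2", "mean_connectivity"])
    passing = table.loc[table["fit_r2"] > target_fit, "power"]
    if len(passing):
        chosen, fallback = int(passing.iloc[0]), False
    else:
        fits = table["fit_r2"]
        if fits.isna().all():
            warnings.warn("degenerate connectivity: scale-free fit undefined "
                          "for every candidate power; using the smallest")
            chosen = int(table["power"].iloc[0])
        else:
            chosen = int(table.loc[fits.idxmax(), "power"])
            warnings.warn(
                f"no candidate power reached scale-free fit {target_fit}; "
                f"falling back to best-fitting power {chosen}"
            )
        fallback = True
    return SoftPowerReport(table, chosen, target_fit, fallback)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of a weighted network.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    unit diagonal; two nodes overlap when they share strong neighbours even
    if their direct edge is weak.
    """
    a = adj.to_numpy()
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if np.diag(a).any():
        raise ValidationError("adjacency must have zero diagonal")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModulePartition:
    """Gene -> module assignment ("M1", "M2", ... by decreasing size)."""

    assignment: pd.Series
    min_size: int
    cut_height: float = float("nan")

    @property
    def module_labels(self) -> list:
        labels = [m for m in self.assignment.unique() if m != UNASSIGNED]
        return sorted(labels, key=lambda s: int(s[1:]))

    def members(self, module: str) -> pd.Index:
        return self.assignment.index[self.assignment == module]

    def sizes(self) -> pd.Series:
        return self.assignment[self.assignment != UNASSIGNED].value_counts()


def _kme_null_quantile(n_stages: int, q: float) -> float:
    """One-sided null quantile of a Pearson r on ``n_stages`` points."""
    t = stats.t.ppf(q, n_stages - 2)
    return float(t / np.sqrt(t * t + n_stages - 2))


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 100,
    expr: TimeSeriesMatrix | None = None,
    prune_quantile: float = 0.99,
    cut_quantiles: np.ndarray | None = None,
) -> ModulePartition:
    """Cut the TOM dendrogram into co-expression modules.

    Average-linkage hierarchical clustering on ``1 - TOM`` with a constant
    height cut.  The height is picked from a quantile grid of the merge
    heights by maximizing, in order: the number of clusters of at least
    ``min_size``; the number of genes inside such clusters; and lower
    height.  Clusters below ``min_size`` are left unassigned.

    When ``expr`` is given, assignments are refined by module membership:
    each provisional module's eigengene is computed and members whose
    correlation with it falls below the one-sided ``prune_quantile`` null
    quantile of a Pearson r at the grid's stage count are released.  This
    removes unstructured genes swept up by the constant-height cut; modules
    that fall below ``min_size`` after pruning dissolve.
    """
    genes = tom.index
    order = np.argsort(genes)          # lexicographic processing order
    genes_sorted = genes[order]
    D = 1.0 - tom.to_numpy()[np.ix_(order, order)]
    np.fill_diagonal(D, 0.0)

    if len(genes) < min_size:
        warnings.warn(f"fewer genes ({len(genes)}) than min_size ({min_size}); "
                      "all genes unassigned")
        return ModulePartition(
            pd.Series(UNASSIGNED, index=genes, name="module"), min_size
        )

    Z = linkage(squareform(D, checks=False), method="average")
    if cut_quantiles is None:
        cut_quantiles = np.arange(0.02, 1.0, 0.02)
    best_key, best = None, None
    for q in cut_quantiles:
        h = float(np.quantile(Z[:, 2], q))
        lab = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(lab)
        good = sizes >= min_size
        key = (int(good.sum()), int(sizes[good].sum()), -h)
        if best_key is None or key > best_key:
            best_key, best = key, (lab, good, h)
    lab, good, height = best
    lab = np.where(good[lab], lab, -1)

    if expr is not None and (lab >= 0).any():
        X = expr.restrict(genes_sorted).values.to_numpy()
        n_stages = X.shape[1]
        r_crit = _kme_null_quantile(n_stages, prune_quantile)
        sd = X.std(axis=1, keepdims=True)
        Zx = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        for c in np.unique(lab[lab >= 0]):
            idx = np.where(lab == c)[0]
            e, _, _ = _first_pc(X[idx])
            en = (e - e.mean()) / e.std()
            kme = Zx[idx] @ en / n_stages
            lab[idx[kme < r_crit]] = -1
        for c in np.unique(lab[lab >= 0]):
            if (lab == c).sum() < min_size:
                lab[lab == c] = -1

    # stable labels: decreasing size, ties by smallest member gene ID
    clusters = []
    for c in np.unique(lab[lab >= 0]):
        members = genes_sorted[lab == c]
        clusters.append((len(members), str(members.min()), members))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    assignment = pd.Series(UNASSIGNED, index=genes_sorted, name="module")
    for rank, (_, _, members) in enumerate(clusters, start=1):
        assignment.loc[members] = f"M{rank}"
    return ModulePartition(assignment.loc[genes], min_size, cut_height=height)


def _first_pc(block: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """First right-singular vector of the standardized gene x stage block.

    Returns (eigengene with unit L2 norm, explained variance fraction,
    single_gene flag); the sign is oriented toward the mean member profile.
    """
    single = block.shape[0] == 1
    sd = block.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValidationError("zero-variance gene inside module")
    Zb = (block - block.mean(axis=1, keepdims=True)) / sd
    if single:
        e = Zb[0] / np.linalg.norm(Zb[0])
        return e, 1.0, True
    _, s, vt = np.linalg.svd(Zb, full_matrices=False)
    e = vt[0]
    ev = float(s[0] ** 2 / (s**2).sum())
    mean_profile = Zb.mean(axis=0)
    if np.corrcoef(e, mean_profile)[0, 1] < 0:
        e = -e
    return e, ev, False


def module_eigengene(
    X: TimeSeriesMatrix, members
) -> tuple[np.ndarray, float, bool]:
    """Eigengene (first PC over stages) of one module's member genes.

    Genes are standardized to mean 0 / SD 1 across stages first.  The
    returned vector has unit L2 norm and nonnegative correlation with the
    modular mean profile.  A single-gene module degenerates to that gene's
    standardized profile (flagged via the third return value).
    """
    members = pd.Index(members)
    if len(members) == 0:
        raise ValidationError("module has no members")
    block = X.restrict(members).values.to_numpy()
    e, ev, single = _first_pc(block)
    if single:
        warnings.warn("single-gene module: eigengene is the gene profile")
    return e, ev, single


@dataclass
class EigengeneSet:
    """Per-module temporal eigengenes over one dataset's stage grid."""

    profiles: pd.DataFrame              # module x stage
    explained_variance: pd.Series       # module -> fraction in [0, 1]

    @property
    def stages(self) -> np.ndarray:
        return np.asarray(self.profiles.columns, dtype=float)

    @property
    def modules(self) -> list:
        return self.profiles.index.tolist()


def module_eigengenes(X: TimeSeriesMatrix, partition: ModulePartition) -> EigengeneSet:
    """Eigengenes for every module of a partition, in label order."""
    rows, evs = {}, {}
    for m in partition.module_labels:
        e, ev, _ = module_eigengene(X, partition.members(m))
        rows[m] = e
        evs[m] = ev
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=X.stages)
    return EigengeneSet(profiles, pd.Series(evs, name="explained_variance"))
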