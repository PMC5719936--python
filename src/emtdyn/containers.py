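"""Core in-memory containers shared across the pipeline.

Expression data is kept in two shapes: a :class:`TimeSeriesMatrix` holds one
cell line's log-scale EMT time course (genes x ordered stages, in hours), and
a :class:`PatientMatrix` holds a bulk cohort on a nonnegative FPKM-like scale
(genes x samples).  Both wrap a pandas DataFrame and validate the invariants
the downstream statistics rely on (no missing values, unique gene identifiers,
strictly increasing stage grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "PatientMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input container violates a documented invariant."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


@dataclass
class TimeSeriesMatrix:
    """Log-scale expression of one cell line's EMT time course.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per stage; column labels
        are the stage times in hours and must be strictly increasing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        _check_unique(df.index, "gene IDs")
        stages = np.asarray([float(c) for c in df.columns], dtype=float)
        if len(stages) < 3:
            raise ValidationError(
                f"need at least 3 stages for Pearson correlation, got {len(stages)}"
            )
        if not np.all(np.diff(stages) > 0):
            raise ValidationError("stage hours must be strictly increasing")
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)][:5].tolist()
            raise ValidationError(f"missing values in genes {bad}")
        self.values = df.astype(float)
        self.values.columns = stages

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def restrict(self, genes) -> "TimeSeriesMatrix":
        """Subset to ``genes`` (kept in the given order); missing IDs error."""
        genes = pd.Index(genes)
        missing = genes.difference(self.gene_ids)
        if len(missing):
            raise KeyError(f"genes absent from matrix: {missing[:5].tolist()}")
        return TimeSeriesMatrix(self.values.loc[genes])

    def drop_zero_variance(self) -> "TimeSeriesMatrix":
        keep = self.values.std(axis=1, ddof=0) > 0
        return TimeSeriesMatrix(self.values.loc[keep])


@dataclass
class PatientMatrix:
    """Nonnegative FPKM-like expression for a bulk cohort (genes x samples)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("values must be a pandas DataFrame")
        _check_unique(df.index, "gene IDs")
        _check_unique(df.columns, "sample IDs")
        if df.isna().any().any():
            raise ValidationError("missing values in cohort matrix")
        if (df.values < 0).any():
            raise ValidationError("cohort expression must be nonnegative")
        self.values = df.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(x + pseudocount) view used by staging and contrasts."""
        return np.log2(self.values + pseudocount)
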