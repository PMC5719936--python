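"""TSV / gene-list / GMT adapters.

All matrices travel as TSV: expression with genes as rows and a header of
stage hours (time courses) or sample IDs (cohorts); regulatory networks as
two-column edge lists (TF, target); survival as three columns (sample,
time_months, event).  Readers validate structure and report offending line
numbers; ``write(read(f))`` round-trips values and ordering exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PatientMatrix, TimeSeriesMatrix, ValidationError
from .simulate import RegulatoryEdges

__all__ = [
    "read_timeseries_tsv", "write_timeseries_tsv",
    "read_cohort_tsv", "write_cohort_tsv",
    "read_gene_list", "write_gene_list", "read_gmt",
    "read_regnet_tsv", "write_regnet_tsv",
    "read_survival_tsv", "write_survival_tsv",
]

_FLOAT_FMT = "%.10g"


def _read_matrix(path, value_kind: str) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, index = [], []
        seen = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise ValidationError(
                    f"{path.name}:{lineno}: ragged row "
                    f"({len(parts)} fields, expected {ncol})"
                )
            gene = parts[0]
            if gene in seen:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate gene {gene!r} "
                    f"(first seen on line {seen[gene]})"
                )
            seen[gene] = lineno
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValidationError(
                    f"{path.name}:{lineno}: non-numeric cell ({exc})"
                ) from None
            index.append(gene)
    columns = header[1:]
    if value_kind == "stages":
        try:
            columns = [float(c) for c in columns]
        except ValueError:
            raise ValidationError(
                f"{path.name}: header must list stage hours, got {columns[:5]}"
            ) from None
    return pd.DataFrame(np.asarray(rows), index=pd.Index(index, name=header[0]),
                        columns=columns)


def read_timeseries_tsv(path) -> TimeSeriesMatrix:
    """Read a gene x stage log-expression TSV (header = hours)."""
    return TimeSeriesMatrix(_read_matrix(path, "stages"))


def write_timeseries_tsv(X: TimeSeriesMatrix, path) -> None:
    df = X.values.copy()
    df.columns = [f"{c:g}" for c in df.columns]
    df.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def read_cohort_tsv(path) -> PatientMatrix:
    """Read a gene x sample FPKM-like TSV (header = sample IDs)."""
    return PatientMatrix(_read_matrix(path, "samples"))


def write_cohort_tsv(cohort: PatientMatrix, path) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene",
                         float_format=_FLOAT_FMT)


def read_gene_list(path) -> list:
    """One gene ID per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"GMT line {lineno}: expected name, description and >= 1 gene"
            )
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_regnet_tsv(path) -> RegulatoryEdges:
    """Two-column TF -> target edge list (a header line 'tf\\ttarget' is
    accepted and skipped)."""
    path = Path(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(
                f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
            )
        if lineno == 1 and parts == ["tf", "target"]:
            continue
        rows.append(parts)
    return RegulatoryEdges(pd.DataFrame(rows, columns=["tf", "target"]))


def write_regnet_tsv(regnet: RegulatoryEdges, path) -> None:
    regnet.edges.to_csv(path, sep="\t", index=False)


def read_survival_tsv(path) -> pd.DataFrame:
    """Survival records: sample, time_months, event (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "time_months", "event"]
    if list(df.columns[:3]) != required:
        raise ValidationError(
            f"survival TSV must start with columns {required}, "
            f"got {list(df.columns[:3])}"
        )
    return df


def write_survival_tsv(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
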