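"""Core data model and tabular I/O for RPPA probe-level analysis.

The pipeline operates on three tables delivered by an RPPA core facility
(after SuperCurve interpolation of the dilution series, which is upstream
of this package):

* an expression matrix of relative protein levels (probes x samples,
  log2 scale internally),
* per-sample metadata (treatment group, batch/run, replicate, and the
  core's protein-loading correction factors CF1/CF2),
* probe annotation (antibody target, phospho site, validation flag,
  exclusion flag and context tags).

All tables are plain CSV/TSV; writers emit UTF-8, RFC-4180-quoted CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENT_GROUPS",
    "ExpressionMatrix",
    "SampleTable",
    "ProbeAnnotation",
    "read_expression_table",
    "write_expression_table",
    "read_sample_table",
    "read_probe_annotation",
    "flag_loading_outliers",
    "filter_probes",
    "median_center",
]

#: The seven treatment arms of the acute amyloid-beta / insulin design.
TREATMENT_GROUPS = (
    "untreated",
    "vehicle",
    "insulin",
    "ab40",
    "ab42",
    "ab40_insulin",
    "ab42_insulin",
)

# CF2 bounds outside of which a sample is a protein-loading outlier
# (strict inequalities).
CF2_LOW = 0.25
CF2_HIGH = 2.5


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what} identifier(s): {', '.join(map(str, dups.index))}")


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of relative protein levels.

    Parameters
    ----------
    data
        DataFrame with probe identifiers as index and sample identifiers
        as columns. Values are finite reals or NaN (explicitly missing).
    scale
        Either ``"log2"`` (the analysis scale) or ``"linear"``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite or missing (NaN)")
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (identity if already log2)."""
        if self.scale == "log2":
            return self
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals) <= 0:
            raise ValueError("linear-scale values must be positive for log2 transform")
        return ExpressionMatrix(np.log2(self.data), scale="log2")

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], scale=self.scale)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(probe_ids)], scale=self.scale)


@dataclass
class SampleTable:
    """Per-sample metadata: treatment group, batch, replicate, CF1/CF2.

    Invariant: a treatment group never spans batches (each group was
    processed in exactly one RPPA run).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "batch", "replicate", "cf1", "cf2")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table missing column(s): {', '.join(missing)}")
        _check_unique(self.data["sample_id"], "sample")
        df = self.data.copy()
        if "qc_flag" not in df.columns:
            df["qc_flag"] = False
        if "weight" not in df.columns:
            df["weight"] = 1.0
        span = df.groupby("group", observed=True)["batch"].nunique()
        bad = span[span > 1]
        if len(bad):
            raise ValueError(f"group(s) span multiple batches: {', '.join(map(str, bad.index))}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def samples_in_groups(self, groups) -> "SampleTable":
        sub = self.data[self.data["group"].isin(list(groups))]
        return SampleTable(sub.copy())

    def batch_of(self, group: str) -> str:
        sub = self.data.loc[self.data["group"] == group, "batch"]
        if sub.empty:
            raise KeyError(f"no samples for group {group!r}")
        return sub.iloc[0]


@dataclass
class ProbeAnnotation:
    """Antibody probe annotation.

    ``is_phospho`` is true exactly when ``phospho_site`` is non-empty;
    ``excluded`` probes are removed by :func:`filter_probes` unless one of
    their ``context_tags`` matches the active analysis context.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "probe_id" in df.columns:
            _check_unique(df["probe_id"], "probe")
            df = df.set_index("probe_id")
        _check_unique(df.index, "probe")
        if "phospho_site" not in df.columns:
            df["phospho_site"] = ""
        df["phospho_site"] = df["phospho_site"].fillna("").astype(str)
        df["is_phospho"] = df["phospho_site"].str.len() > 0
        for col, default in (("validated", True), ("excluded", False)):
            if col not in df.columns:
                df[col] = default
            df[col] = df[col].astype(bool)
        if "context_tags" not in df.columns:
            df["context_tags"] = ""
        df["context_tags"] = df["context_tags"].fillna("").astype(str)
        self.data = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def is_phospho(self, probe_id: str) -> bool:
        return bool(self.data.loc[probe_id, "is_phospho"])

    def tags_of(self, probe_id: str) -> frozenset:
        raw = self.data.loc[probe_id, "context_tags"]
        return frozenset(t for t in str(raw).split(";") if t)

    def total_protein_probes(self) -> list[str]:
        return list(self.data.index[~self.data["is_phospho"]])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_expression_table(path, scale: str = "log2") -> ExpressionMatrix:
    """Read a probes-x-samples delimited table.

    The first column holds probe identifiers; the header row holds sample
    identifiers. ``scale="linear"`` input is log2-transformed on read.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    _check_unique(df.index, "probe")
    _check_unique(df.columns, "sample")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric value at probe {row!r}, sample {col!r}")
        df[col] = coerced
    mat = ExpressionMatrix(df, scale=scale)
    return mat.to_log2() if scale == "linear" else mat


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep=_sep_for(path), encoding="utf-8", quoting=csv.QUOTE_MINIMAL)


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep=_sep_for(path)))


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep=_sep_for(path))
    df = df.rename(columns={"target": "target_name"})
    return ProbeAnnotation(df)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def flag_loading_outliers(samples: SampleTable) -> SampleTable:
    """Flag protein-loading outliers by the core facility's CF2 rule.

    Samples with CF2 < 0.25 or CF2 > 2.5 get ``qc_flag = True``. The rule
    uses strict inequalities and flags only — no sample is removed.
    """
    df = samples.data.copy()
    cf2 = pd.to_numeric(df["cf2"], errors="coerce")
    if cf2.isna().any():
        bad = df.loc[cf2.isna(), "sample_id"].tolist()
        raise ValueError(f"missing CF2 for sample(s): {', '.join(map(str, bad))}")
    if (cf2 <= 0).any():
        raise ValueError("CF2 must be positive")
    df["qc_flag"] = (cf2 < CF2_LOW) | (cf2 > CF2_HIGH)
    return SampleTable(df)


def filter_probes(
    matrix: ExpressionMatrix,
    annot: ProbeAnnotation,
    context: str | None = None,
) -> ExpressionMatrix:
    """Drop excluded probes, keeping those re-admitted by the context.

    A probe marked ``excluded`` is removed unless ``context`` is one of
    its context tags (e.g. pericyte-biology probes retained when the
    analysis context is ``"pericyte"``). Every matrix probe must be
    annotated.
    """
    unannotated = [p for p in matrix.probe_ids if p not in annot.data.index]
    if unannotated:
        raise ValueError(f"unannotated probe(s): {', '.join(unannotated[:10])}")
    keep = []
    for p in matrix.probe_ids:
        if not bool(annot.data.loc[p, "excluded"]):
            keep.append(p)
        elif context is not None and context in annot.tags_of(p):
            keep.append(p)
    return matrix.subset_probes(keep)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's median (over non-missing probes).

    Requires log2 scale; idempotent; leaves missing values missing.
    """
    if matrix.scale != "log2":
        raise ValueError("median centering requires log2 scale; call to_log2() first")
    med = matrix.data.median(axis=0, skipna=True)
    return ExpressionMatrix(matrix.data.sub(med, axis=1), scale="log2")
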