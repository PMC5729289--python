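"""Expression and clinical data ingestion and preprocessing.

Covers the steps between normalized expression data and module scoring:
detection-call filtering, probe-to-gene collapse, cross-cohort gene
intersection, and mapping of network sub-modules onto the measured gene
space.  Normalization itself (e.g. RMA for microarrays) is out of scope;
matrices are consumed as given, on a log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .modules import ModuleSet

__all__ = [
    "ExpressionMatrix",
    "DetectionMatrix",
    "ClinicalTable",
    "read_expression",
    "read_detection",
    "read_clinical",
    "filter_by_detection",
    "collapse_probes",
    "intersect_cohorts",
    "map_modules_to_expression",
    "check_sample_alignment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale expression, rows = features (probes or genes), columns = samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("expression row ids must be unique")
        if df.columns.has_duplicates:
            raise ValueError("expression sample ids must be unique")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def features(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


@dataclass(frozen=True)
class DetectionMatrix:
    """0/1 detection flags (1 = "Present"), aligned with an expression matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("detection flags must be 0 or 1")

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")


REQUIRED_CLINICAL = ("rfs_time", "rfs_event", "treatment")
OPTIONAL_ENDPOINTS = ("os_time", "os_event")


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival endpoints, treatment arm, and free covariates.

    The frame is indexed by sample id and holds at least relapse-free
    survival (``rfs_time`` in years, ``rfs_event`` 0/1) and a binary
    ``treatment`` indicator (0 = surgery alone, 1 = adjuvant chemotherapy);
    overall survival (``os_time``/``os_event``) is optional.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValueError("clinical sample ids must be unique")
        missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        for col in self.endpoints_available():
            tcol, ecol = f"{col}_time", f"{col}_event"
            if (df[tcol] < 0).any():
                raise ValueError(f"{tcol} must be non-negative")
            if not df[ecol].isin((0, 1)).all():
                raise ValueError(f"{ecol} must be 0/1")
        if not df["treatment"].isin((0, 1)).all():
            raise ValueError("treatment must be 0/1")
        unknown = [c for c in self.covariates if c not in df.columns]
        if unknown:
            raise ValueError(f"declared covariates not in table: {unknown}")

    @property
    def samples(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def endpoints_available(self) -> list[str]:
        out = ["rfs"]
        if all(c in self.data.columns for c in OPTIONAL_ENDPOINTS):
            out.append("os")
        return out

    def endpoint(self, name: str) -> tuple[pd.Series, pd.Series]:
        if name not in self.endpoints_available():
            raise ValueError(f"endpoint {name!r} not available")
        return self.data[f"{name}_time"], self.data[f"{name}_event"]

    def subset(self, sample_ids) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)], self.covariates)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# readers


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV; tolerate a GCT preamble (#1.2 + dims)."""
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
        skip = 0
        if first.startswith("#1.2"):
            fh.readline()  # dimensions line
            skip = 2
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_expression(path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(_read_matrix(path).astype(float))


def read_detection(path: str | Path) -> DetectionMatrix:
    return DetectionMatrix(_read_matrix(path).astype(int))


def read_clinical(path: str | Path, covariates: tuple[str, ...] = ()) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index = df.index.astype(str)
    return ClinicalTable(df, covariates)


# ---------------------------------------------------------------------------
# operations


def filter_by_detection(
    expr: ExpressionMatrix, det: DetectionMatrix, min_fraction: float = 0.2
) -> ExpressionMatrix:
    """Retain features flagged present in *more than* ``min_fraction`` of samples.

    The inequality is strict: a feature present in exactly
    ``min_fraction * n`` samples is dropped.
    """
    if not (0.0 <= min_fraction < 1.0):
        raise ValueError("min_fraction must lie in [0, 1)")
    if list(det.values.index) != list(expr.values.index) or list(
        det.values.columns
    ) != list(expr.values.columns):
        raise ValueError("detection matrix ids do not match expression matrix")
    frac = det.values.mean(axis=1)
    keep = frac > min_fraction
    return ExpressionMatrix(expr.values.loc[keep])


def collapse_probes(
    expr: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For genes measured by several probes the probe with the highest mean
    expression is kept (ties broken by probe id); probes without a mapping
    are dropped.  Rows of the result are sorted by gene id.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    df = expr.values
    mapped = [p for p in df.index if p in probe_to_gene]
    if not mapped:
        raise ValueError("no probe of the matrix is covered by the mapping")
    sub = df.loc[mapped]
    means = sub.mean(axis=1)
    choice: dict[str, str] = {}
    for probe in sorted(mapped):  # sorted => deterministic tie-break by probe id
        gene = str(probe_to_gene[probe])
        if gene not in choice or means[probe] > means[choice[gene]]:
            choice[gene] = probe
    genes = sorted(choice)
    out = sub.loc[[choice[g] for g in genes]]
    out.index = pd.Index(genes)
    return ExpressionMatrix(out)


def intersect_cohorts(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two gene-level matrices to their common genes, same row order."""
    common = sorted(set(a.features) & set(b.features))
    if not common:
        raise ValueError("cohorts share no genes")
    return (
        ExpressionMatrix(a.values.loc[common]),
        ExpressionMatrix(b.values.loc[common]),
    )


def map_modules_to_expression(
    modules: ModuleSet, expr: ExpressionMatrix, min_mapped: int = 2
) -> ModuleSet:
    """Intersect each module with the measured genes; drop sparse modules.

    Modules whose intersection with the expression rows falls below
    ``min_mapped`` genes are removed; kept/dropped counts are logged.
    """
    if min_mapped < 1:
        raise ValueError("min_mapped must be >= 1")
    measured = set(expr.features)
    kept: dict[str, list[str]] = {}
    dropped = 0
    for name, members in modules.items():
        hit = [g for g in members if g in measured]
        if len(hit) >= min_mapped:
            kept[name] = hit
        else:
            dropped += 1
    logger.info(
        "module mapping: %d kept, %d dropped (min_mapped=%d)",
        len(kept),
        dropped,
        min_mapped,
    )
    return ModuleSet(sets=kept, provenance=dict(modules.provenance))


def check_sample_alignment(expr_samples, clinical: ClinicalTable) -> None:
    """Refuse cohorts whose expression and clinical sample ids disagree."""
    e, c = set(expr_samples), set(clinical.samples)
    if e != c:
        only_e = sorted(e - c)[:5]
        only_c = sorted(c - e)[:5]
        raise ValueError(
            "expression and clinical sample ids disagree "
            f"(expression-only: {only_e}, clinical-only: {only_c})"
        )
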