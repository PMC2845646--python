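"""Expression time-series processing and pairwise profile correlation.

The processing chain mirrors standard two-channel time-course practice:
raw intensities are expressed as fold change relative to the first
timepoint, log-transformed, and column-standardized so that every
timepoint has mean 0 and SD 1 across genes.  Flat profiles (row SD below a
threshold, 0.50 by default) are then removed, and similarity between two
genes is the Pearson correlation of their processed profiles.

Stage tags (raw -> log_fold -> zscored) are enforced so the chain cannot
be applied out of order, and every operation logs how many genes it
dropped, so record conservation can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, StageError

__all__ = [
    "ExpressionMatrix",
    "CorrelationSet",
    "log_fold_change",
    "zscore_columns",
    "filter_flat",
    "pairwise_correlations",
]

STAGES = ("raw", "log_fold", "zscored")
Pair = tuple[str, str]


@dataclass
class ExpressionMatrix:
    """Gene x timepoint matrix with a processing-stage and assay tag."""

    data: pd.DataFrame
    stage: str
    assay: str
    dropped: dict[str, int] = field(default_factory=dict)
    degenerate_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InputError(f"unknown stage {self.stage!r}")
        if self.assay not in ("TR", "RA"):
            raise InputError(f"unknown assay {self.assay!r}")
        if self.data.index.duplicated().any():
            raise InputError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.data.columns)

    def _require_stage(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise StageError(f"{op} requires stage {stage!r}, matrix is {self.stage!r}")


def log_fold_change(matrix: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Fold change relative to the first timepoint, log-transformed.

    Genes with any missing value, or with a non-positive first-timepoint
    value, are dropped (counts recorded in ``dropped``).  The first column
    becomes identically zero.
    """
    matrix._require_stage("raw", "log_fold_change")
    data = matrix.data
    has_na = data.isna().any(axis=1)
    n_missing = int(has_na.sum())
    data = data[~has_na]
    t1 = data.iloc[:, 0]
    bad_t1 = t1 <= 0
    n_bad = int(bad_t1.sum())
    data = data[~bad_t1]
    if data.empty:
        raise InputError("log_fold_change dropped every gene")
    values = np.log(data.to_numpy(float) / data.iloc[:, 0].to_numpy(float)[:, None])
    values /= np.log(base)
    dropped = dict(matrix.dropped)
    dropped["missing_values"] = dropped.get("missing_values", 0) + n_missing
    dropped["nonpositive_t1"] = dropped.get("nonpositive_t1", 0) + n_bad
    return ExpressionMatrix(
        pd.DataFrame(values, index=data.index, columns=data.columns),
        stage="log_fold", assay=matrix.assay, dropped=dropped,
        degenerate_columns=list(matrix.degenerate_columns),
    )


def zscore_columns(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each timepoint to mean 0, population SD 1 across genes.

    Zero-variance columns (e.g. the all-zero first log-fold column) are
    left unchanged and flagged in ``degenerate_columns``.
    """
    matrix._require_stage("log_fold", "zscore_columns")
    if len(matrix.data) < 2:
        raise InputError("zscore_columns needs at least two genes")
    values = matrix.data.to_numpy(float).copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population SD
    degenerate = [c for c, s in zip(matrix.data.columns, sd) if s == 0]
    keep = sd > 0
    values[:, keep] = (values[:, keep] - mean[keep]) / sd[keep]
    return ExpressionMatrix(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        stage="zscored", assay=matrix.assay, dropped=dict(matrix.dropped),
        degenerate_columns=sorted(set(matrix.degenerate_columns) | set(degenerate)),
    )


def filter_flat(matrix: ExpressionMatrix, sd_min: float = 0.50) -> ExpressionMatrix:
    """Remove genes whose profile SD (population, over all timepoints) < sd_min."""
    matrix._require_stage("zscored", "filter_flat")
    row_sd = matrix.data.to_numpy(float).std(axis=1)
    keep = row_sd >= sd_min
    dropped = dict(matrix.dropped)
    dropped["flat_profile"] = dropped.get("flat_profile", 0) + int((~keep).sum())
    return ExpressionMatrix(
        matrix.data.loc[keep], stage="zscored", assay=matrix.assay,
        dropped=dropped, degenerate_columns=list(matrix.degenerate_columns),
    )


@dataclass
class CorrelationSet:
    """Pearson correlations for unordered gene pairs of one assay."""

    assay: str
    r: dict[Pair, float]
    n_skipped_degenerate: int = 0
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, v) for (a, b), v in sorted(self.r.items())],
            columns=["gene_a", "gene_b", "r"],
        )


def pairwise_correlations(
    matrix: ExpressionMatrix,
    pairs: Iterable[Pair] | None = None,
) -> CorrelationSet:
    """Pearson r over the full timepoint vector for the requested pairs.

    With ``pairs=None`` every unordered pair is computed.  Pairs touching a
    zero-variance profile are skipped (counted); pairs naming an absent
    gene are recorded as per-pair errors and the run continues.
    """
    if matrix.data.shape[1] < 3:
        raise InputError("pairwise correlations need >= 3 timepoints")
    values = matrix.data.to_numpy(float)
    index = {g: i for i, g in enumerate(matrix.data.index)}
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred ** 2).sum(axis=1))

    out: dict[Pair, float] = {}
    skipped = 0
    errors: list[str] = []
    if pairs is None:
        genes = list(matrix.data.index)
        requested = [(genes[i], genes[j]) for i in range(len(genes))
                     for j in range(i + 1, len(genes))]
    else:
        requested = [tuple(sorted(p)) for p in pairs]
    for a, b in requested:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            errors.append(f"gene absent from matrix: {a if ia is None else b}")
            continue
        if norms[ia] == 0 or norms[ib] == 0:
            skipped += 1
            continue
        r = float(np.dot(centred[ia], centred[ib]) / (norms[ia] * norms[ib]))
        out[(a, b)] = max(-1.0, min(1.0, r))
    return CorrelationSet(matrix.assay, out, skipped, errors)
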