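"""TR-to-RA time-delay detection via the column correlation matrix.

mRNA takes time to accumulate after transcription speeds up, so a
transcription-rate (TR) timepoint tends to correlate better with the
*next* abundance (RA) timepoint than with the simultaneous one.  Treating
each of the 2n timepoint columns as a gene-vector over the shared gene
set, the (2n) x (2n) Pearson matrix makes that forward shift visible, and
a per-offset mean of corr(TR_i, RA_{i+k}) turns it into a single
recovered lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .expression import ExpressionMatrix

__all__ = ["DelayMatrix", "column_correlation_matrix", "detect_lag"]


@dataclass
class DelayMatrix:
    """Symmetric Pearson matrix over TR1..TRn, RA1..RAn columns."""

    r: pd.DataFrame
    n_timepoints: int
    n_shared_genes: int

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)

    def tr_ra_block(self) -> pd.DataFrame:
        """The TR-rows x RA-columns quadrant."""
        n = self.n_timepoints
        return self.r.iloc[:n, n:]


def column_correlation_matrix(tr: ExpressionMatrix, ra: ExpressionMatrix) -> DelayMatrix:
    """Correlate every timepoint column with every other over shared genes.

    Zero-variance columns (e.g. an all-zero first log-fold column) yield
    undefined off-diagonal entries, stored as NaN; the diagonal is 1 by
    definition.
    """
    if len(tr.timepoints) != len(ra.timepoints):
        raise InputError("TR and RA must have equal timepoint counts")
    shared = tr.data.index.intersection(ra.data.index)
    if len(shared) < 3:
        raise InputError(f"only {len(shared)} shared genes; need >= 3")
    n = len(tr.timepoints)
    labels = [f"TR{i + 1}" for i in range(n)] + [f"RA{i + 1}" for i in range(n)]
    stacked = np.hstack([
        tr.data.loc[shared].to_numpy(float),
        ra.data.loc[shared].to_numpy(float),
    ])
    centred = stacked - stacked.mean(axis=0, keepdims=True)
    norms = np.sqrt((centred ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norms > 0, centred / np.where(norms > 0, norms, 1.0), np.nan)
        corr = unit.T @ unit
    corr = np.clip(corr, -1.0, 1.0, out=corr, where=~np.isnan(corr))
    np.fill_diagonal(corr, 1.0)
    frame = pd.DataFrame(corr, index=labels, columns=labels)
    return DelayMatrix(frame, n_timepoints=n, n_shared_genes=len(shared))


def detect_lag(matrix: DelayMatrix, max_offset: int) -> tuple[pd.DataFrame, int]:
    """Mean corr(TR_i, RA_{i+k}) per offset k, and the maximizing offset.

    Offsets run over [-max_offset, max_offset]; NaN entries (degenerate
    columns) are excluded from the mean.  Ties go to the smaller \\|k\\|,
    then to the positive sign.
    """
    n = matrix.n_timepoints
    if not 0 <= max_offset < n:
        raise InputError("max_offset must satisfy 0 <= max_offset < n_timepoints")
    block = matrix.tr_ra_block().to_numpy(float)
    rows = []
    for k in range(-max_offset, max_offset + 1):
        vals = [
            block[i, i + k]
            for i in range(n)
            if 0 <= i + k < n and not np.isnan(block[i, i + k])
        ]
        rows.append((k, float(np.mean(vals)) if vals else np.nan, len(vals)))
    table = pd.DataFrame(rows, columns=["offset", "mean_r", "n_valid"])
    valid = table.dropna(subset=["mean_r"])
    if valid.empty:
        raise InputError("no valid offsets (all columns degenerate)")
    best = min(
        valid.itertuples(index=False),
        key=lambda row: (-row.mean_r, abs(row.offset), -np.sign(row.offset)),
    )
    return table, int(best.offset)
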