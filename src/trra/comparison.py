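"""Trend of high-correlation fractions versus minimum co-operon frequency.

The headline comparison: for each assay (TR, RA), restrict the gene pairs
to those whose normalized co-operon frequency is at least f, compute the
fraction of pairwise correlations >= +c and <= -c (c = 0.6 by default,
both inclusive) and their ratio, and follow the three quantities as f
rises.  A more informative assay shows a stronger positive trend of the
high-correlation fraction with co-operon frequency.  The ratio curve is
truncated at the first threshold where the negative count reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cooperon import CoOperonRecord
from .errors import InputError
from .expression import CorrelationSet

__all__ = [
    "ThresholdFractions",
    "TrendCurve",
    "ComparisonSummary",
    "threshold_fractions",
    "trend_vs_cooperon",
    "compare_informativeness",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class ThresholdFractions:
    """Fractions of correlations beyond +/-c and their ratio."""

    frac_pos: float
    frac_neg: float
    ratio: float          # NaN when undefined
    n_pos: int
    n_neg: int
    n_total: int

    @property
    def ratio_defined(self) -> bool:
        return self.n_neg > 0


def threshold_fractions(r_values: Sequence[float], c: float = 0.6) -> ThresholdFractions:
    """Count correlations >= +c and <= -c (inclusive on both sides)."""
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise InputError("empty correlation list")
    n_pos = int((r >= c).sum())
    n_neg = int((r <= -c).sum())
    ratio = n_pos / n_neg if n_neg > 0 else float("nan")
    return ThresholdFractions(
        frac_pos=n_pos / r.size, frac_neg=n_neg / r.size, ratio=ratio,
        n_pos=n_pos, n_neg=n_neg, n_total=int(r.size),
    )


@dataclass
class TrendCurve:
    """Per-threshold fractions and ratio for one assay."""

    assay: str
    c: float
    thresholds: np.ndarray
    n_pairs: np.ndarray
    frac_pos: np.ndarray
    frac_neg: np.ndarray
    ratio: np.ndarray            # NaN from the truncation point onward
    ratio_end: int               # index of the first grid point with n_neg == 0
    dropped_pairs: int = 0       # record pairs lacking a correlation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "n_pairs": self.n_pairs,
            "frac_pos": self.frac_pos, "frac_neg": self.frac_neg,
            "ratio": self.ratio, "assay": self.assay,
        })


def trend_vs_cooperon(
    correlations: Mapping[str, CorrelationSet],
    records: Iterable[CoOperonRecord],
    grid: Sequence[float] | None = None,
    c: float = 0.6,
) -> dict[str, TrendCurve]:
    """Build one TrendCurve per assay over a rising co-operon frequency grid.

    Only record pairs with a correlation in *every* assay are used (the
    dropped count is logged on each curve).  The default grid is the
    ascending set of normalized frequencies observed among those pairs.
    """
    if not correlations:
        raise InputError("no correlation sets supplied")
    records = list(records)
    usable: list[CoOperonRecord] = []
    dropped = 0
    for rec in records:
        if all(rec.pair in cs.r for cs in correlations.values()):
            usable.append(rec)
        else:
            dropped += 1
    if not usable:
        raise InputError("no record pair has correlations in every assay")
    freqs = np.array([rec.normalized_freq for rec in usable])
    if grid is None:
        thresholds = np.unique(freqs)
    else:
        thresholds = np.asarray(list(grid), dtype=float)
        if thresholds.size == 0 or np.any(np.diff(thresholds) < 0):
            raise InputError("grid must be non-empty and ascending")
    if not np.any(freqs >= thresholds[0]):
        raise InputError("no pairs at the lowest grid threshold")

    curves: dict[str, TrendCurve] = {}
    for assay, cs in correlations.items():
        r = np.array([cs.r[rec.pair] for rec in usable])
        n_pairs, frac_pos, frac_neg, ratio = [], [], [], []
        ratio_end = len(thresholds)
        for gi, f in enumerate(thresholds):
            sel = r[freqs >= f]
            if sel.size == 0:
                n_pairs.append(0)
                frac_pos.append(np.nan)
                frac_neg.append(np.nan)
                ratio.append(np.nan)
                ratio_end = min(ratio_end, gi)
                continue
            tf = threshold_fractions(sel, c)
            n_pairs.append(tf.n_total)
            frac_pos.append(tf.frac_pos)
            frac_neg.append(tf.frac_neg)
            if tf.n_neg == 0 and ratio_end == len(thresholds):
                ratio_end = gi
            ratio.append(tf.ratio if gi < ratio_end else np.nan)
        curves[assay] = TrendCurve(
            assay=assay, c=c, thresholds=thresholds,
            n_pairs=np.array(n_pairs), frac_pos=np.array(frac_pos),
            frac_neg=np.array(frac_neg), ratio=np.array(ratio),
            ratio_end=ratio_end, dropped_pairs=dropped,
        )
    return curves


@dataclass(frozen=True)
class ComparisonSummary:
    """How much better one assay tracks co-operon frequency than the other."""

    dominance_count: int      # grid points where TR frac_pos > RA frac_pos
    n_grid: int
    spearman_tr: float
    spearman_ra: float

    @property
    def spearman_diff(self) -> float:
        return self.spearman_tr - self.spearman_ra


def _trend_coefficient(thresholds: np.ndarray, frac: np.ndarray) -> float:
    mask = ~np.isnan(frac)
    f = frac[mask]
    t = thresholds[mask]
    if f.size < 2 or np.all(f == f[0]) or np.all(t == t[0]):
        return 0.0  # no trend detectable in a constant curve
    rho = spearmanr(t, f).statistic
    return float(rho)


def compare_informativeness(tr_curve: TrendCurve, ra_curve: TrendCurve) -> ComparisonSummary:
    """Dominance count and Spearman trend coefficients of TR vs RA curves."""
    if not np.array_equal(tr_curve.thresholds, ra_curve.thresholds):
        raise InputError("curves must share the threshold grid")
    both = ~np.isnan(tr_curve.frac_pos) & ~np.isnan(ra_curve.frac_pos)
    dominance = int((tr_curve.frac_pos[both] > ra_curve.frac_pos[both]).sum())
    return ComparisonSummary(
        dominance_count=dominance,
        n_grid=int(both.sum()),
        spearman_tr=_trend_coefficient(tr_curve.thresholds, tr_curve.frac_pos),
        spearman_ra=_trend_coefficient(ra_curve.thresholds, ra_curve.frac_pos),
    )
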