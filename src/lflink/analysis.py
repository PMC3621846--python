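"""Frequency binning, link-ratio statistics, P/R/F evaluation, and the
absence-probability regression.

Long forms are stratified into 12 occurrence-frequency bins:
[10,49], [50,99], then width-100 bins up to [900,999], and an open
[1000, inf) bin.  The *link ratio* of a bin is the fraction of its LFs
that received a link.  For the regression, bins 1 and 2 (whose ranges
differ in width from the rest) are merged into a single point whose
ratio is their average, and the bins are renumbered x = 0..10.  The
model is that the negative log of the absence probability is linear in
the merged bin index:

    -ln(1 - y) = a*x + b

where y is the per-bin presence (link) probability.  The fit is
ordinary least squares of -ln(1-y) on x (natural log; unweighted unless
per-point weights are given).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BIN_LOWER_BOUNDS",
    "N_BINS",
    "FREQUENCY_THRESHOLD",
    "EvalCounts",
    "BinPoint",
    "RegressionResult",
    "DegenerateCountsError",
    "assign_bin",
    "bin_link_ratios",
    "prf_from_counts",
    "merge_bins_for_regression",
    "fit_absence_regression",
    "presence_probability",
    "evaluate_links",
]

#: Lower bound of each frequency bin, 1-based; bin 12 is open-ended.
BIN_LOWER_BOUNDS: Tuple[int, ...] = (10, 50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000)
N_BINS = 12
FREQUENCY_THRESHOLD = 10


class DegenerateCountsError(ValueError):
    """Precision or recall has a zero denominator."""


@dataclass(frozen=True)
class EvalCounts:
    """Confusion counts from a manual or gold-standard evaluation."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class BinPoint:
    """One merged-bin regression point: index x and link ratio y."""

    x: int
    y: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    slope_stderr: float = float("nan")


def assign_bin(frequency: int) -> int:
    """Bin number (1..12) of an occurrence frequency.

    Frequencies below the threshold of 10 are outside the scheme and
    raise ValueError.

    >>> assign_bin(63)
    2
    """
    if frequency < FREQUENCY_THRESHOLD:
        raise ValueError(
            f"frequency {frequency} is below the binning threshold {FREQUENCY_THRESHOLD}"
        )
    return bisect_right(BIN_LOWER_BOUNDS, frequency)


def bin_link_ratios(outcomes: Iterable[Tuple[int, bool]]) -> pd.DataFrame:
    """Per-bin link counts and ratios.

    *outcomes* is an iterable of ``(frequency, linked)`` pairs, one per
    LF.  Returns a DataFrame indexed by bin 1..12 with columns
    ``n_lfs``, ``n_linked`` and ``ratio``; empty bins get ratio NaN
    (excluded from any downstream regression).
    """
    n_lfs = np.zeros(N_BINS, dtype=int)
    n_linked = np.zeros(N_BINS, dtype=int)
    for freq, linked in outcomes:
        b = assign_bin(freq) - 1
        n_lfs[b] += 1
        if linked:
            n_linked[b] += 1
    with np.errstate(invalid="ignore"):
        ratio = np.where(n_lfs > 0, n_linked / np.maximum(n_lfs, 1), np.nan)
    return pd.DataFrame(
        {"n_lfs": n_lfs, "n_linked": n_linked, "ratio": ratio},
        index=pd.RangeIndex(1, N_BINS + 1, name="bin"),
    )


def prf_from_counts(counts: EvalCounts) -> Dict[str, float]:
    """Precision, recall and F-measure from confusion counts.

    precision = tp/(tp+fp); recall = tp/(tp+fn); f = harmonic mean.
    Raises :class:`DegenerateCountsError` when a denominator is zero.
    """
    if counts.tp + counts.fp == 0:
        raise DegenerateCountsError("precision undefined: tp + fp == 0")
    if counts.tp + counts.fn == 0:
        raise DegenerateCountsError("recall undefined: tp + fn == 0")
    precision = counts.tp / (counts.tp + counts.fp)
    recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f": f}


def merge_bins_for_regression(ratios: Mapping[int, float]) -> List[BinPoint]:
    """Merge bins 1 and 2 (averaging their ratios) and renumber x = 0..10.

    Requires all 12 bins; bins 3..12 map to x = 1..10 unchanged.
    """
    missing = [b for b in range(1, N_BINS + 1) if b not in ratios]
    if missing:
        raise ValueError(f"missing bins for regression merge: {missing}")
    points = [BinPoint(0, (ratios[1] + ratios[2]) / 2.0)]
    points.extend(BinPoint(b - 2, float(ratios[b])) for b in range(3, N_BINS + 1))
    return points


def fit_absence_regression(
    points: Sequence[BinPoint],
    weights: Optional[Sequence[float]] = None,
) -> RegressionResult:
    """OLS of the transformed response -ln(1-y) on the merged bin index x.

    Points with an undefined ratio (NaN, from empty bins) are excluded;
    every remaining y must be strictly below 1 (the transform diverges
    at 1) and at least 3 defined points are required.  When *weights* is given a weighted
    least-squares fit is used instead (e.g. bin populations).  Returns
    the slope, intercept, coefficient of determination and the two-sided
    p-value of the slope's t-test.
    """
    if weights is not None and len(weights) != len(points):
        raise ValueError("weights must match points")
    # Empty bins carry an undefined ratio (NaN); they are excluded here.
    keep = [i for i, p in enumerate(points) if not math.isnan(p.y)]
    points = [points[i] for i in keep]
    if weights is not None:
        weights = [weights[i] for i in keep]
    if len(points) < 3:
        raise ValueError(f"need at least 3 defined points to fit, got {len(points)}")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    if np.any(y >= 1.0):
        raise ValueError("absence transform undefined: some link ratio >= 1")
    z = -np.log1p(-y)
    if np.allclose(z, z[0]):
        # Flat response: zero slope explains nothing beyond the mean.
        return RegressionResult(
            slope=0.0, intercept=float(z[0]), r2=0.0, p_value=1.0, slope_stderr=0.0
        )
    X = sm.add_constant(x)
    model = sm.WLS(z, X, weights=np.asarray(weights, float)) if weights is not None else sm.OLS(z, X)
    res = model.fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        slope_stderr=float(res.bse[1]),
    )


def presence_probability(x: int, a: float = 0.2, b: float = 0.92) -> float:
    """Model presence probability at merged bin x: y = 1 - exp(-(a*x + b))."""
    return 1.0 - math.exp(-(a * x + b))


def evaluate_links(outcomes: Iterable, gold_links: Iterable[Tuple[str, str]]) -> EvalCounts:
    """Confusion counts of link outcomes against a gold (lf_text, uri) set.

    A linked LF whose accepted title URI is in the gold set is a true
    positive; any other accepted link is a false positive; an unlinked LF
    that has a gold title is a false negative.  Unlinked LFs without a
    gold title (true negatives) do not enter precision/recall.
    """
    gold_by_lf: Dict[str, set] = {}
    for lf_text, uri in gold_links:
        gold_by_lf.setdefault(lf_text, set()).add(uri)
    tp = fp = fn = 0
    for o in outcomes:
        gold = gold_by_lf.get(o.lf_text)
        if o.link is not None:
            if gold and o.link.title.resource_uri in gold:
                tp += 1
            else:
                fp += 1
        elif gold:
            fn += 1
    return EvalCounts(tp, fp, fn)
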