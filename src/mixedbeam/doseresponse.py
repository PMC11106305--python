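"""Linear dose-response fitting and metaphase scoring.

Fold-change responses are fitted to Y = 1 + slope * X with the intercept
forced through 1 (the data are normalised to the 0 Gy control), while
aberration frequencies are fitted to Y = intercept + slope * X with a free
intercept because each collection carries its own basal fragment level.

The aberration score of a metaphase is the number of objects (chromosomes
plus fragments) counted in excess of the diploid 46; cells with fewer than
46 objects contribute zero, not a negative score.  Frequencies are
expressed per 100 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .study import DIPLOID_COUNT, MetaphaseRecord


@dataclass(frozen=True)
class LinearFit:
    """One linear dose-response fit (anchored or free intercept)."""

    slope: float
    slope_se: float
    intercept: float
    intercept_fixed: bool
    n_points: int
    residual_variance: float


@dataclass(frozen=True)
class AberrationFrequency:
    """Excess-object (fragment) frequency per 100 cells for one sample."""

    aberrations_per_100_cells: float
    n_metaphases: int


def score_metaphases(object_counts: Iterable[int] | Iterable[MetaphaseRecord]) -> AberrationFrequency:
    """Aberration frequency per 100 cells from per-metaphase object counts.

    Accepts raw integer counts or MetaphaseRecords; order-invariant.
    """
    counts = [c.object_count if isinstance(c, MetaphaseRecord) else int(c) for c in object_counts]
    if not counts:
        raise ValueError("no metaphases to score")
    if any(c < 0 for c in counts):
        raise ValueError("object counts must be non-negative")
    excess = np.maximum(0, np.asarray(counts, dtype=float) - DIPLOID_COUNT)
    return AberrationFrequency(
        aberrations_per_100_cells=float(100.0 * excess.mean()),
        n_metaphases=len(counts),
    )


def fit_anchored(doses: Sequence[float], responses: Sequence[float]) -> LinearFit:
    """Least-squares slope of Y = 1 + slope * X (intercept fixed at 1).

    Closed form: slope = sum x*(y-1) / sum x^2, with the residual variance
    on n - 1 degrees of freedom (one fitted parameter) and
    se(slope) = sqrt(residual_variance / sum x^2).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1-D of equal length")
    if x.size == 0 or not np.any(x > 0):
        raise ValueError("anchored fit needs at least one non-zero dose")
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * (y - 1.0)) / sxx)
    resid = y - (1.0 + slope * x)
    dof = max(x.size - 1, 1)
    resid_var = float(np.sum(resid**2) / dof) if x.size > 1 else 0.0
    return LinearFit(
        slope=slope,
        slope_se=float(np.sqrt(resid_var / sxx)),
        intercept=1.0,
        intercept_fixed=True,
        n_points=int(x.size),
        residual_variance=resid_var,
    )


def fit_free(doses: Sequence[float], responses: Sequence[float]) -> LinearFit:
    """Ordinary least squares Y = intercept + slope * X."""
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1-D of equal length")
    if np.unique(x).size < 2:
        raise ValueError("free fit needs at least two distinct doses")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = x.size - 2
    resid_var = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    se = float(res.stderr) if dof > 0 and np.isfinite(res.stderr) else 0.0
    return LinearFit(
        slope=float(res.slope),
        slope_se=se,
        intercept=float(res.intercept),
        intercept_fixed=False,
        n_points=int(x.size),
        residual_variance=resid_var,
    )
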