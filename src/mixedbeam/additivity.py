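"""Simple effect additivity (SEA), synergy ratios, RBE and dose equivalents.

Under SEA the effect of a mixed beam delivering total dose D with X-ray
share f equals the sum of the single-beam effects at their component doses:
baseline + slope_X * f * D + slope_a * (1 - f) * D, the baseline counted
once.  Because all dose responses here are linear, the expected mixed-beam
(EMB) slope is simply f * slope_X + (1 - f) * slope_a — for the study's 1:1
beam, the arithmetic mean of the component slopes.  Synergy is quantified
as the ratio of the observed mixed-beam slope to the EMB slope; RBE as the
ratio of a test radiation's slope to the X-ray slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class SynergyRatio:
    """Observed/expected mixed-beam slope ratio; undefined when EMB <= 0."""

    slope_mb: float
    slope_emb: float
    ratio: float
    defined: bool


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (the convention of printed summary tables;
    Python's built-in round is half-to-even)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def expected_mixed_slope(slope_xray: float, slope_alpha: float, share_xray: float = 0.5) -> float:
    """SEA expected mixed-beam slope: share * slope_X + (1 - share) * slope_a."""
    if not 0.0 <= share_xray <= 1.0:
        raise ValueError("share_xray must lie in [0, 1]")
    return share_xray * slope_xray + (1.0 - share_xray) * slope_alpha


def synergy_ratio(slope_mb: float, slope_emb: float) -> SynergyRatio:
    """Observed/expected slope ratio; encoded undefined (not raised) when
    the expected slope is non-positive.  The ratio may be negative when the
    observed mixed-beam slope is negative."""
    if slope_emb > 0:
        return SynergyRatio(slope_mb, slope_emb, slope_mb / slope_emb, True)
    return SynergyRatio(slope_mb, slope_emb, float("nan"), False)


def rbe(slope_test: float, slope_reference: float) -> float:
    """Relative biological effectiveness as a ratio of linear slopes,
    with X-rays as the conventional reference."""
    if slope_reference <= 0:
        raise ValueError("reference slope must be positive")
    return slope_test / slope_reference


def dose_to_effect(slope: float, target_effect: float = 10.0) -> float:
    """Dose (Gy) at which the induced effect above background reaches
    `target_effect` (default 10 aberrations per 100 cells)."""
    if slope <= 0:
        raise ValueError("dose to effect requires a positive slope")
    return target_effect / slope


def dose_equivalent(components: list[tuple[float, float]]) -> float:
    """Dose equivalent H (Sv) = sum of dose_i (Gy) x RBE_i over components."""
    if any(d < 0 for d, _ in components):
        raise ValueError("component doses must be non-negative")
    return float(sum(d * w for d, w in components))
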