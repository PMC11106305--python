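"""Effect sizes, t-tests, Sidak adjustment, one-way ANOVA and summaries.

Cohen's d uses the pooled standard deviation (two-sample) or the sample
standard deviation (one-sample vs a reference value), always with n-1
denominators.  Magnitude classes follow the convention small <= 0.5 <
medium <= 0.8 < large < 1.3 <= very large, applied to |d|.  Multiple
comparisons are Sidak-adjusted: p_adj = 1 - (1 - p)^m.

Significance stars follow the four-threshold convention
0.0332 (*), 0.0021 (**), 0.0002 (***), 0.0001 (****); larger adjusted
p-values are reported as "ns".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_THRESHOLDS = (
    (0.0001, "****"),
    (0.0002, "***"),
    (0.0021, "**"),
    (0.0332, "*"),
)


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class EffectSize:
    d: float
    magnitude_class: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    p_adjusted: float | None
    effect: EffectSize | None


def classify_effect(d: float) -> str:
    """Magnitude class of |d|: small (<=0.5), medium (<=0.8), large (<1.3),
    very_large (>=1.3)."""
    a = abs(d)
    if not math.isfinite(a):
        raise ValueError("effect size must be finite")
    if a <= 0.5:
        return "small"
    if a <= 0.8:
        return "medium"
    if a < 1.3:
        return "large"
    return "very_large"


def cohens_d_two_sample(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> EffectSize:
    """|mean1 - mean2| / pooled sd, with the (n-1)-weighted pooled variance.

    For equal group sizes this reduces to |m1 - m2| / sqrt((s1^2 + s2^2)/2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("standard deviations must be >= 0 and not both zero")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    d = abs(mean1 - mean2) / pooled
    return EffectSize(d=d, magnitude_class=classify_effect(d))


def cohens_d_one_sample(values: Sequence[float], reference: float = 1.0) -> EffectSize:
    """|mean(values) - reference| / sample sd (n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    d = abs(float(v.mean()) - reference) / sd
    return EffectSize(d=d, magnitude_class=classify_effect(d))


def t_test_two_sample(
    group1: Sequence[float], group2: Sequence[float], paired: bool = False
) -> TestResult:
    """Two-sided pooled-variance t-test with an attached two-sample d.

    `paired=True` runs the paired variant (groups must be equal length,
    matched by position); d is still the pooled two-sample flavour so the
    reported effect size is comparable across paired/unpaired analyses.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if g1.size != g2.size:
            raise ValueError("paired test needs equal group sizes")
        stat, p = sps.ttest_rel(g1, g2)
        dof = g1.size - 1
    else:
        stat, p = sps.ttest_ind(g1, g2, equal_var=True)
        dof = g1.size + g2.size - 2
    effect = cohens_d_two_sample(
        float(g1.mean()), float(g1.std(ddof=1)), g1.size,
        float(g2.mean()), float(g2.std(ddof=1)), g2.size,
    )
    return TestResult(float(stat), float(dof), float(p), None, effect)


def t_test_one_sample(values: Sequence[float], reference: float = 1.0) -> TestResult:
    """Two-sided one-sample t-test against a reference value.

    A degenerate zero-variance sample cannot support a t statistic; it is
    reported as an exact equality check (p = 1 if the mean equals the
    reference, else p = 0) with an undefined effect size.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if v.std(ddof=1) == 0:
        p = 1.0 if v.mean() == reference else 0.0
        return TestResult(float("inf") if p == 0 else 0.0, float(v.size - 1), p, None, None)
    stat, p = sps.ttest_1samp(v, reference)
    effect = cohens_d_one_sample(v, reference)
    return TestResult(float(stat), float(v.size - 1), float(p), None, effect)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak-adjusted p-value 1 - (1 - p)^m, clamped to [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, max(0.0, 1.0 - (1.0 - p) ** m))


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    statistic: float
    degrees_of_freedom: float
    p_value: float
    p_adjusted: float
    effect: EffectSize
    stars: str


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    comparisons: tuple[PairwiseComparison, ...]


def one_way_anova(
    groups: dict[str, Sequence[float]] | Sequence[Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> AnovaResult:
    """One-way ANOVA with Sidak-adjusted pairwise comparisons.

    The omnibus F is computed from the between/within sum-of-squares
    decomposition; pairwise t statistics reuse the within-group mean square
    (df = N - k) so all contrasts share the ANOVA error estimate.  Each
    contrast carries a Sidak adjustment with m = number of contrasts drawn,
    a two-sample Cohen's d, and significance stars.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs n >= 2")

    all_values = np.concatenate(list(arrays.values()))
    grand_mean = all_values.mean()
    n_total = all_values.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays.values())
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays.values())
    df_between = k - 1
    df_within = n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat, p = (0.0, 1.0) if ss_between == 0 else (float("inf"), 0.0)
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(sps.f.sf(f_stat, df_between, df_within))

    if comparisons is None:
        comparisons = list(itertools.combinations(arrays.keys(), 2))
    m = len(comparisons)
    results = []
    for a_name, b_name in comparisons:
        a, b = arrays[a_name], arrays[b_name]
        se = math.sqrt(ms_within * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            t_stat = 0.0 if a.mean() == b.mean() else float("inf")
            raw_p = 1.0 if t_stat == 0.0 else 0.0
        else:
            t_stat = (a.mean() - b.mean()) / se
            raw_p = float(2.0 * sps.t.sf(abs(t_stat), df_within))
        adj = sidak_adjust(raw_p, m)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            # constant groups: no scale for a standardized difference
            d = 0.0 if a.mean() == b.mean() else math.inf
            effect = EffectSize(d=d, magnitude_class="small" if d == 0 else "very_large")
        else:
            effect = cohens_d_two_sample(
                float(a.mean()), float(a.std(ddof=1)), a.size,
                float(b.mean()), float(b.std(ddof=1)), b.size,
            )
        results.append(
            PairwiseComparison(a_name, b_name, float(t_stat), float(df_within),
                               raw_p, adj, effect, significance_stars(adj))
        )
    return AnovaResult(float(f_stat), df_between, df_within, p, tuple(results))


@dataclass(frozen=True)
class SeasonalSummary:
    donor: str
    season: int
    ratio_mean: float
    ratio_sd: float
    n_ratios: int
    n_undefined: int
    test_vs_one: TestResult


def seasonal_summary(ratios: pd.DataFrame, donor: str, season: int) -> SeasonalSummary:
    """Pool one donor-season's weekly MB:EMB ratios over all endpoints.

    `ratios` needs columns donor, season, ratio, defined.  Undefined
    ratios (non-positive expected slope) are excluded from pooling and
    counted.  The pooled mean is tested against the additivity value 1.
    """
    sub = ratios[(ratios["donor"] == donor) & (ratios["season"] == season)]
    defined = sub[sub["defined"].astype(bool)]
    values = defined["ratio"].to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError(f"donor {donor} season {season}: fewer than 2 defined ratios")
    return SeasonalSummary(
        donor=donor,
        season=int(season),
        ratio_mean=float(values.mean()),
        ratio_sd=float(values.std(ddof=1)),
        n_ratios=int(values.size),
        n_undefined=int(len(sub) - len(defined)),
        test_vs_one=t_test_one_sample(values, 1.0),
    )


#: Heat-table bin edges on the MB:EMB ratio scale; the bins are a display
#: convention (chosen for contrast around the additivity value 1), not an
#: inferential threshold, and are fully configurable.
DEFAULT_RATIO_BINS = (-math.inf, 0.75, 0.9, 1.1, 1.35, 1.75, math.inf)


def ratio_heat_table(
    ratios: pd.DataFrame,
    bin_edges: Sequence[float] = DEFAULT_RATIO_BINS,
) -> pd.DataFrame:
    """Weekly MB:EMB ratio table: rows = endpoint, columns = (season, week).

    Returns a long frame with columns donor, endpoint, season, week, ratio,
    bin (interval label).  Undefined ratios get bin label "undefined".
    """
    edges = list(bin_edges)
    if any(nxt <= prev for prev, nxt in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for r in ratios.itertuples(index=False):
        if bool(r.defined):
            idx = int(np.searchsorted(edges, r.ratio, side="right")) - 1
            idx = min(max(idx, 0), len(edges) - 2)
            label = f"({edges[idx]:g}, {edges[idx + 1]:g}]"
        else:
            label = "undefined"
        rows.append(
            {
                "donor": r.donor,
                "endpoint": r.endpoint,
                "season": r.season,
                "week": r.week,
                "ratio": r.ratio,
                "bin": label,
            }
        )
    return pd.DataFrame(rows, columns=["donor", "endpoint", "season", "week", "ratio", "bin"])
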