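"""Alternative-transcript ratio analysis of net 2^-dCt levels.

For each gene two primer pairs target different transcript variants; the
ratio of their reference-normalised net levels (FDXR PP1:PP2, CDKN1A V1:V4,
MDM2 315:303/304) indexes alternative transcription.  Per sampling
timepoint, irradiated radiation groups average net levels over the 0.5-2 Gy
doses while the control group uses the 0 Gy sample; an "expected mixed
beam" (EMB) group is constructed by applying the SEA fold-change prediction
to the control net level.  The resulting per-timepoint ratios are compared
between radiation groups with a one-way ANOVA and Sidak-adjusted pairwise
contrasts, either over all seasons or within synergy-defined season
subsets.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import AnovaResult, one_way_anova
from .study import DEFAULT_PANEL, PanelConfig

#: Net levels may not be non-positive; the SEA prediction is floored here
#: to keep extreme negative slopes from producing unphysical levels.
NET_LEVEL_FLOOR = 1e-12

RADIATION_GROUPS = ("control", "xray", "alpha", "mixed", "expected_mixed")

Subset = Literal["all", "synergy_seasons", "non_synergy_seasons"]


def mean_net_level(levels: Sequence[float]) -> float:
    """Arithmetic mean net 2^-dCt level over a sample's matching doses."""
    v = np.asarray(levels, dtype=float)
    if v.size == 0:
        raise ValueError("no net levels to average")
    return float(v.mean())


def expected_mixed_net_level(
    control_level: float, slope_xray: float, slope_alpha: float, dose_gy: float
) -> float:
    """SEA-predicted mixed-beam net level at one dose.

    The control net level is scaled by the SEA fold-change prediction
    1 + 0.5 * (slope_X + slope_a) * D for a 1:1 beam, floored at a small
    positive epsilon.
    """
    if control_level <= 0:
        raise ValueError("control net level must be positive")
    fold = 1.0 + 0.5 * (slope_xray + slope_alpha) * dose_gy
    return max(control_level * fold, NET_LEVEL_FLOOR)


def pair_ratio(numerator_level: float, denominator_level: float) -> float:
    """Transcript-variant ratio in the panel's fixed orientation."""
    if numerator_level <= 0 or denominator_level <= 0:
        raise ValueError("net levels must be positive")
    return numerator_level / denominator_level


def build_pair_ratio_records(
    net: pd.DataFrame,
    expression_fits: pd.DataFrame | None = None,
    panel: PanelConfig = DEFAULT_PANEL,
    irradiated_doses: Sequence[float] = (0.5, 1.0, 2.0),
) -> pd.DataFrame:
    """Per (donor, season, week, radiation group, gene pair) variant ratios.

    `net` is the output of qpcr.net_levels.  For the three irradiated
    groups the per-target net level is the mean over `irradiated_doses`;
    the control group uses the 0 Gy level.  When `expression_fits` (long
    frame with donor, season, week, radiation, target/endpoint, slope from
    the anchored fold-change fits) is given, an additional expected_mixed
    group is constructed from the SEA prediction applied to the control
    level at each irradiated dose, then averaged the same way.
    """
    target_col = "target"
    fit_lookup: dict[tuple, float] = {}
    if expression_fits is not None:
        col = "endpoint" if "endpoint" in expression_fits.columns else "target"
        fit_lookup = {
            (r.donor, r.season, r.week, r.radiation, getattr(r, col)): r.slope
            for r in expression_fits.itertuples(index=False)
        }

    rows = []
    for (donor, season, week), block in net.groupby(["donor", "season", "week"]):
        levels: dict[tuple[str, str], float] = {}
        for target, tblock in block.groupby(target_col):
            ctrl = tblock[(tblock["radiation"] == "control") & (tblock["dose_gy"] == 0)]
            if len(ctrl):
                control_level = mean_net_level(ctrl["net_level"].to_numpy())
                levels[("control", target)] = control_level
            else:
                control_level = None
            for rad in ("xray", "alpha", "mixed"):
                sel = tblock[(tblock["radiation"] == rad) & tblock["dose_gy"].isin(irradiated_doses)]
                if len(sel):
                    levels[(rad, target)] = mean_net_level(sel["net_level"].to_numpy())
            sx = fit_lookup.get((donor, season, week, "xray", target))
            sa = fit_lookup.get((donor, season, week, "alpha", target))
            if control_level is not None and sx is not None and sa is not None:
                emb = [
                    expected_mixed_net_level(control_level, sx, sa, d)
                    for d in irradiated_doses
                ]
                levels[("expected_mixed", target)] = mean_net_level(emb)

        for pair_id, num, den in panel.pair_ratio_orientation:
            for group in RADIATION_GROUPS:
                num_level = levels.get((group, num))
                den_level = levels.get((group, den))
                if num_level is None or den_level is None:
                    continue
                rows.append(
                    {
                        "donor": donor,
                        "season": season,
                        "week": week,
                        "group": group,
                        "pair": pair_id,
                        "ratio": pair_ratio(num_level, den_level),
                    }
                )
    return pd.DataFrame(rows, columns=["donor", "season", "week", "group", "pair", "ratio"])


def season_synergy_flags(seasonal: pd.DataFrame) -> dict[tuple[str, int], bool]:
    """(donor, season) -> True when the seasonal mean MB:EMB ratio > 1.

    `seasonal` needs columns donor, season, ratio_mean (one row per
    donor-season, e.g. from the seasonal summaries).
    """
    return {
        (r.donor, int(r.season)): bool(r.ratio_mean > 1.0)
        for r in seasonal.itertuples(index=False)
    }


def _apply_subset(
    records: pd.DataFrame,
    subset: Subset,
    synergy_flags: Mapping[tuple[str, int], bool] | None,
) -> pd.DataFrame:
    if subset == "all":
        return records
    if synergy_flags is None:
        raise ValueError("season subsets require synergy flags")
    want = subset == "synergy_seasons"
    mask = records.apply(
        lambda r: synergy_flags.get((r["donor"], int(r["season"])), False) == want, axis=1
    )
    out = records[mask]
    if out.empty:
        raise ValueError(f"subset {subset!r}: no qualifying seasons")
    return out


def pair_ratio_analysis(
    records: pd.DataFrame,
    subset: Subset = "all",
    synergy_flags: Mapping[tuple[str, int], bool] | None = None,
    log_ratios: bool = False,
) -> dict[str, AnovaResult]:
    """Per gene pair: one-way ANOVA across radiation groups with Sidak
    pairwise contrasts (each radiation vs control plus all radiation-
    radiation contrasts), pooled over donors and the selected seasons.

    Ratios enter untransformed by default (`log_ratios=True` analyses
    log-ratios instead).  Returns {pair id: AnovaResult}.
    """
    sub = _apply_subset(records, subset, synergy_flags)
    results: dict[str, AnovaResult] = {}
    for pair_id, block in sub.groupby("pair"):
        groups = {}
        for group, g in block.groupby("group"):
            vals = g["ratio"].to_numpy(dtype=float)
            if log_ratios:
                vals = np.log(vals)
            if vals.size >= 2:
                groups[str(group)] = vals
        if len(groups) < 2:
            raise ValueError(f"pair {pair_id}: fewer than 2 usable groups in subset {subset!r}")
        names = [g for g in RADIATION_GROUPS if g in groups]
        contrasts = [(a, "control") for a in names if a != "control" and "control" in names]
        contrasts += [
            (a, b)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
            if a != "control" and b != "control"
        ]
        results[str(pair_id)] = one_way_anova(groups, comparisons=contrasts)
    return results


def analysis_to_frame(results: dict[str, AnovaResult], subset: str) -> pd.DataFrame:
    """Flatten pair_ratio_analysis output into one row per contrast."""
    rows = []
    for pair_id, res in results.items():
        for c in res.comparisons:
            rows.append(
                {
                    "pair": pair_id,
                    "subset": subset,
                    "group1": c.group1,
                    "group2": c.group2,
                    "anova_f": res.f_statistic,
                    "anova_p": res.p_value,
                    "t": c.statistic,
                    "df": c.degrees_of_freedom,
                    "p": c.p_value,
                    "p_adj": c.p_adjusted,
                    "d": c.effect.d,
                    "class": c.effect.magnitude_class,
                    "stars": c.stars,
                }
            )
    return pd.DataFrame(rows)
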