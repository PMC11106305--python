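"""Synthetic two-donor mixed-beam studies with known ground truth.

The generator emulates the study design the analysis assumes: 2 donors x
3 seasons x 3 weeks, each collection exposing blood to X-rays, alpha
particles and a 1:1 mixed beam at 0.5/1/2 Gy plus a shared sham (0 Gy)
control, with 50 metaphases scored per dose point and duplicate qPCR
reactions per target.

Per-cell excess-fragment counts are Poisson with mean background +
(slope/100) * dose.  Expression fold changes follow the linear form
1 + slope * dose, converted to Ct values around a fixed reference with
independent Gaussian replicate noise.  Within each (donor, season, week)
the X-ray and alpha slopes carry multiplicative lognormal season and week
effects; the mixed-beam effective slope is theta times the SEA mean of the
perturbed component slopes, so theta = 1 generates exact additivity and the
weekly true MB:EMB ratio equals theta by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .study import (
    CT_COLUMNS,
    GENE_TARGETS,
    METAPHASE_COLUMNS,
    REFERENCE_TARGET,
    ExposureCondition,
    MetaphaseRecord,
    Radiation,
    SampleKey,
)

#: Expression is floored here so extreme negative slopes cannot produce a
#: non-positive fold change (2^-ddCt is strictly positive).
FOLD_FLOOR = 0.05

_DEFAULT_ABERRATION_SLOPES = {"xray": 28.0, "alpha": 78.0}
_DEFAULT_EXPRESSION_SLOPES = {
    "FDXR_PP1": {"xray": 2.0, "alpha": 5.0},
    "FDXR_PP2": {"xray": 1.5, "alpha": 4.0},
    "CDKN1A_V1": {"xray": 1.0, "alpha": 2.5},
    "CDKN1A_V4": {"xray": 0.8, "alpha": 2.0},
    "MDM2_303_304": {"xray": 0.5, "alpha": 1.2},
    "MDM2_315": {"xray": 0.4, "alpha": 1.0},
}
_DEFAULT_CONTROL_DELTA_CT = {
    "FDXR_PP1": 12.0,
    "FDXR_PP2": 13.0,
    "CDKN1A_V1": 10.0,
    "CDKN1A_V4": 14.0,
    "MDM2_303_304": 11.0,
    "MDM2_315": 15.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults encode the study conditions."""

    seed: int = 0
    donors: int = 2
    seasons: int = 3
    weeks_per_season: int = 3
    doses: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    metaphases_per_dose: int = 50
    ct_replicates: int = 2
    aberration_background: float = 0.02
    aberration_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ABERRATION_SLOPES)
    )
    expression_slopes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_EXPRESSION_SLOPES.items()}
    )
    interaction_theta: float = 1.0
    season_effect_sd: float = 0.20
    week_effect_sd: float = 0.25
    ct_replicate_sd: float = 0.15
    reference_ct: float = 15.0
    #: "poisson" draws per-cell excess counts; "expected" distributes the
    #: integer-rounded expected total excess evenly over the cells, making
    #: the sample frequency exact whenever mean * n_cells is an integer
    #: (the noiseless limit used for parameter-recovery checks).
    aberration_sampling: str = "poisson"
    control_delta_ct: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTROL_DELTA_CT)
    )

    def __post_init__(self) -> None:
        if self.interaction_theta <= 0:
            raise ValueError("interaction_theta must be positive")
        if min(self.season_effect_sd, self.week_effect_sd, self.ct_replicate_sd) < 0:
            raise ValueError("all standard deviations must be >= 0")
        if 0.0 not in self.doses:
            raise ValueError("doses must include the 0 Gy control")
        if self.aberration_sampling not in ("poisson", "expected"):
            raise ValueError("aberration_sampling must be 'poisson' or 'expected'")
        if self.donors < 1 or self.seasons < 1 or self.weeks_per_season < 1:
            raise ValueError("donors, seasons and weeks_per_season must be >= 1")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: raw tables plus the generating truth."""

    ct: pd.DataFrame
    metaphases: pd.DataFrame
    truth: pd.DataFrame  # donor, season, week, radiation, endpoint, true_slope
    config: SyntheticConfig


def _poisson_mean(background: float, slope_per100: float, dose: float) -> float:
    mean = background + (slope_per100 / 100.0) * dose
    if mean < 0:
        warnings.warn(
            f"negative aberration mean {mean:.4g} clamped to 0 "
            "(interaction/effect draws pushed the slope negative)",
            stacklevel=3,
        )
        mean = 0.0
    return mean


def _excess_counts(
    mean: float, n_cells: int, rng: np.random.Generator, sampling: str
) -> np.ndarray:
    if sampling == "poisson":
        return rng.poisson(mean, size=n_cells)
    total = int(round(mean * n_cells))
    base, rem = divmod(total, n_cells)
    counts = np.full(n_cells, base, dtype=np.int64)
    counts[:rem] += 1
    return counts


def simulate_metaphases(
    condition: ExposureCondition,
    effective_slope: float,
    background: float,
    n_cells: int,
    rng: np.random.Generator,
    sampling: str = "poisson",
) -> list[MetaphaseRecord]:
    """Per-cell excess counts ~ Poisson(background + slope/100 * dose),
    reported as object counts of 46 + excess."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    mean = _poisson_mean(background, effective_slope, condition.dose_gy)
    draws = _excess_counts(mean, n_cells, rng, sampling)
    key = SampleKey(donor="d1", season=1, week=1, condition=condition)
    return [MetaphaseRecord(sample=key, object_count=int(46 + d)) for d in draws]


def expression_delta_ct(control_delta_ct: float, effective_slope: float, dose: float) -> float:
    """Noise-free dCt implied by the linear fold-change model."""
    fold = max(1.0 + effective_slope * dose, FOLD_FLOOR)
    return control_delta_ct - math.log2(fold)


def simulate_ct(
    condition: ExposureCondition,
    target: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    effective_slope: float | None = None,
) -> pd.DataFrame:
    """Replicate Ct rows (target + reference) for one sample and target."""
    if effective_slope is None:
        slopes = config.expression_slopes[target]
        if condition.radiation is Radiation.CONTROL:
            effective_slope = 0.0
        elif condition.radiation is Radiation.MIXED:
            effective_slope = config.interaction_theta * 0.5 * (slopes["xray"] + slopes["alpha"])
        else:
            effective_slope = slopes[condition.radiation.value]
    dct = expression_delta_ct(config.control_delta_ct[target], effective_slope, condition.dose_gy)
    rows = []
    for rep in range(1, config.ct_replicates + 1):
        for tgt, base in ((target, config.reference_ct + dct), (REFERENCE_TARGET, config.reference_ct)):
            rows.append(
                {
                    "donor": "d1",
                    "season": 1,
                    "week": 1,
                    "radiation": condition.radiation.value,
                    "dose_gy": condition.dose_gy,
                    "target": tgt,
                    "replicate": rep,
                    "ct": base + rng.normal(0.0, config.ct_replicate_sd),
                }
            )
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def _block_conditions(doses: Sequence[float]) -> list[tuple[str, float]]:
    nonzero = [d for d in doses if d > 0]
    conds = [("control", 0.0)]
    for rad in ("xray", "alpha", "mixed"):
        conds += [(rad, d) for d in nonzero]
    return conds


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full factorial study with ground-truth slopes.

    Output is a pure function of the config (seed included): fixed
    iteration order over donors, seasons, weeks, endpoints and doses.
    """
    rng = np.random.default_rng(config.seed)
    theta = config.interaction_theta
    endpoints = ["ABER", *GENE_TARGETS]
    conds = _block_conditions(config.doses)
    nonzero_doses = [d for d in config.doses if d > 0]

    meta_cols: dict[str, list] = {c: [] for c in METAPHASE_COLUMNS}
    ct_cols: dict[str, list] = {c: [] for c in CT_COLUMNS}
    truth_rows: list[dict] = []

    for donor_i in range(1, config.donors + 1):
        donor = f"d{donor_i}"
        for season in range(1, config.seasons + 1):
            # One lognormal season factor per endpoint x component radiation.
            season_fac = {
                (ep, rad): float(np.exp(rng.normal(0.0, config.season_effect_sd)))
                for ep in endpoints
                for rad in ("xray", "alpha")
            }
            for week in range(1, config.weeks_per_season + 1):
                week_fac = {
                    (ep, rad): float(np.exp(rng.normal(0.0, config.week_effect_sd)))
                    for ep in endpoints
                    for rad in ("xray", "alpha")
                }
                eff: dict[tuple[str, str], float] = {}
                for ep in endpoints:
                    base = (
                        config.aberration_slopes
                        if ep == "ABER"
                        else config.expression_slopes[ep]
                    )
                    sx = base["xray"] * season_fac[(ep, "xray")] * week_fac[(ep, "xray")]
                    sa = base["alpha"] * season_fac[(ep, "alpha")] * week_fac[(ep, "alpha")]
                    eff[(ep, "xray")] = sx
                    eff[(ep, "alpha")] = sa
                    eff[(ep, "mixed")] = theta * 0.5 * (sx + sa)
                    eff[(ep, "control")] = 0.0
                    for rad in ("xray", "alpha", "mixed"):
                        truth_rows.append(
                            {
                                "donor": donor,
                                "season": season,
                                "week": week,
                                "radiation": rad,
                                "endpoint": ep,
                                "true_slope": eff[(ep, rad)],
                            }
                        )

                # Metaphases: one Poisson vector per sample of the block.
                for rad, dose in conds:
                    mean = _poisson_mean(
                        config.aberration_background, eff[("ABER", rad)], dose
                    )
                    draws = _excess_counts(
                        mean, config.metaphases_per_dose, rng, config.aberration_sampling
                    )
                    n = draws.size
                    meta_cols["donor"] += [donor] * n
                    meta_cols["season"] += [season] * n
                    meta_cols["week"] += [week] * n
                    meta_cols["radiation"] += [rad] * n
                    meta_cols["dose_gy"] += [dose] * n
                    meta_cols["object_count"] += list(46 + draws)

                # qPCR: per sample, one shared reference series plus one
                # series per gene target (the reference is measured once
                # per sample, as on a real plate).
                for rad, dose in conds:
                    nrep = config.ct_replicates
                    ref_cts = config.reference_ct + rng.normal(0.0, config.ct_replicate_sd, nrep)
                    for rep in range(1, nrep + 1):
                        ct_cols["donor"].append(donor)
                        ct_cols["season"].append(season)
                        ct_cols["week"].append(week)
                        ct_cols["radiation"].append(rad)
                        ct_cols["dose_gy"].append(dose)
                        ct_cols["target"].append(REFERENCE_TARGET)
                        ct_cols["replicate"].append(rep)
                        ct_cols["ct"].append(float(ref_cts[rep - 1]))
                    for ep in GENE_TARGETS:
                        dct = expression_delta_ct(
                            config.control_delta_ct[ep], eff[(ep, rad)], dose
                        )
                        tgt_cts = (
                            config.reference_ct
                            + dct
                            + rng.normal(0.0, config.ct_replicate_sd, nrep)
                        )
                        for rep in range(1, nrep + 1):
                            ct_cols["donor"].append(donor)
                            ct_cols["season"].append(season)
                            ct_cols["week"].append(week)
                            ct_cols["radiation"].append(rad)
                            ct_cols["dose_gy"].append(dose)
                            ct_cols["target"].append(ep)
                            ct_cols["replicate"].append(rep)
                            ct_cols["ct"].append(float(tgt_cts[rep - 1]))

    truth = pd.DataFrame(truth_rows)
    truth["theta"] = theta
    return SyntheticStudy(
        ct=pd.DataFrame(ct_cols, columns=CT_COLUMNS),
        metaphases=pd.DataFrame(meta_cols, columns=METAPHASE_COLUMNS),
        truth=truth,
        config=config,
    )
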