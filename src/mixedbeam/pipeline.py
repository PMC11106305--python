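"""End-to-end orchestration: raw tables -> fits -> synergy/RBE -> reports.

Weekly fits are the replicate unit throughout: every (donor, season, week)
block yields one dose-response slope per radiation and endpoint, and all
downstream summaries (RBE, dose-to-effect, synergy ratios, seasonal means)
are statistics over those weekly values, not over pooled raw points.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import qpcr, transcripts
from .additivity import dose_to_effect, expected_mixed_slope, rbe, round_half_away, synergy_ratio
from .simulate import SyntheticConfig, simulate_study
from .stats import (
    DEFAULT_RATIO_BINS,
    ratio_heat_table,
    seasonal_summary,
    t_test_two_sample,
)
from .study import DIPLOID_COUNT

log = logging.getLogger("mixedbeam")

BLOCK = ["donor", "season", "week"]
FIT_COLUMNS = BLOCK + ["radiation", "endpoint", "slope", "slope_se", "intercept", "n_points"]


def aberration_frequencies(metaphases: pd.DataFrame) -> pd.DataFrame:
    """Per-sample aberration frequency per 100 cells from raw counts.

    Group-wise form of score_metaphases: 100 x mean excess over 46.
    """
    if (metaphases["object_count"] < 0).any():
        raise ValueError("object counts must be non-negative")
    excess = 100.0 * (metaphases["object_count"] - DIPLOID_COUNT).clip(lower=0)
    agg = (
        metaphases.assign(excess=excess)
        .groupby(BLOCK + ["radiation", "dose_gy"], sort=True)["excess"]
        .agg(aberrations_per_100_cells="mean", n_metaphases="size")
        .reset_index()
    )
    return agg


def _with_shared_control(points: pd.DataFrame, value_col: str, extra_keys: list[str]) -> pd.DataFrame:
    """Replicate each block's 0 Gy control point into every radiation's
    point set (the sham exposure is the shared zero-dose point)."""
    ctrl = points[(points["radiation"] == "control") & (points["dose_gy"] == 0)]
    rad = points[points["radiation"] != "control"]
    rads = rad[BLOCK + extra_keys + ["radiation"]].drop_duplicates()
    ctrl_rep = rads.merge(
        ctrl.drop(columns=["radiation"]), on=BLOCK + extra_keys, how="inner"
    )
    return pd.concat([rad, ctrl_rep], ignore_index=True)[
        BLOCK + extra_keys + ["radiation", "dose_gy", value_col]
    ]


def aberration_fits(metaphases: pd.DataFrame) -> pd.DataFrame:
    """Free-intercept weekly fit per radiation, sharing the block control.

    Each (donor, season, week, radiation) uses that radiation's dose points
    plus the block's sham (0 Gy) control as the zero-dose point, unweighted
    by metaphase count.  Computed with the OLS normal equations group-wise;
    identical to fit_free applied per group.
    """
    freq = aberration_frequencies(metaphases)
    if freq.empty:
        return pd.DataFrame(columns=FIT_COLUMNS)
    pts = _with_shared_control(freq, "aberrations_per_100_cells", [])
    y = pts["aberrations_per_100_cells"]
    x = pts["dose_gy"]
    agg = (
        pts.assign(x=x, y=y, xx=x * x, xy=x * y, yy=y * y)
        .groupby(BLOCK + ["radiation"], sort=True)[["x", "y", "xx", "xy", "yy"]]
        .agg(n=("x", "size"), sx=("x", "sum"), sy=("y", "sum"),
             sxx=("xx", "sum"), sxy=("xy", "sum"), syy=("yy", "sum"))
        .reset_index()
    )
    n = agg["n"]
    sxx_c = agg["sxx"] - agg["sx"] ** 2 / n  # centred sums
    sxy_c = agg["sxy"] - agg["sx"] * agg["sy"] / n
    syy_c = agg["syy"] - agg["sy"] ** 2 / n
    slope = sxy_c / sxx_c
    intercept = agg["sy"] / n - slope * agg["sx"] / n
    sse = (syy_c - slope * sxy_c).clip(lower=0.0)
    dof = (n - 2).clip(lower=1)
    resid_var = np.where(n > 2, sse / dof, 0.0)
    out = pd.DataFrame(
        {
            "donor": agg["donor"],
            "season": agg["season"],
            "week": agg["week"],
            "radiation": agg["radiation"],
            "endpoint": "ABER",
            "slope": slope,
            "slope_se": np.sqrt(resid_var / sxx_c),
            "intercept": intercept,
            "n_points": n.astype(int),
        }
    )
    return out[FIT_COLUMNS]


def expression_fits(ct: pd.DataFrame) -> pd.DataFrame:
    """Anchored (through-1) weekly fold-change fit per radiation and target.

    The block's control contributes the exact (0 Gy, fold 1) point; the
    anchored slope is then determined by the 0.5-2 Gy fold changes.
    Closed form sum x (y - 1) / sum x^2 group-wise; identical to
    fit_anchored applied per group.
    """
    folds = qpcr.fold_changes(ct)
    if folds.empty:
        return pd.DataFrame(columns=FIT_COLUMNS)
    pts = _with_shared_control(folds, "fold", ["target"])
    x = pts["dose_gy"]
    ym1 = pts["fold"] - 1.0
    agg = (
        pts.assign(xx=x * x, xy=x * ym1, yy=ym1 * ym1)
        .groupby(BLOCK + ["target", "radiation"], sort=True)[["xx", "xy", "yy"]]
        .agg(n=("xx", "size"), sxx=("xx", "sum"), sxy=("xy", "sum"), syy=("yy", "sum"))
        .reset_index()
    )
    slope = agg["sxy"] / agg["sxx"]
    sse = (agg["syy"] - slope * agg["sxy"]).clip(lower=0.0)
    dof = (agg["n"] - 1).clip(lower=1)
    resid_var = np.where(agg["n"] > 1, sse / dof, 0.0)
    out = pd.DataFrame(
        {
            "donor": agg["donor"],
            "season": agg["season"],
            "week": agg["week"],
            "radiation": agg["radiation"],
            "endpoint": agg["target"],
            "slope": slope,
            "slope_se": np.sqrt(resid_var / agg["sxx"]),
            "intercept": 1.0,
            "n_points": agg["n"].astype(int),
        }
    )
    return out[FIT_COLUMNS]


def weekly_synergy(fits: pd.DataFrame, share_xray: float = 0.5) -> pd.DataFrame:
    """Per (donor, season, week, endpoint): EMB slope and MB:EMB ratio."""
    wide = fits.pivot_table(
        index=BLOCK + ["endpoint"], columns="radiation", values="slope"
    ).reset_index()
    rows = []
    for r in wide.itertuples(index=False):
        sx, sa, smb = getattr(r, "xray", np.nan), getattr(r, "alpha", np.nan), getattr(r, "mixed", np.nan)
        if np.isnan(sx) or np.isnan(sa) or np.isnan(smb):
            continue
        emb = expected_mixed_slope(sx, sa, share_xray)
        sr = synergy_ratio(smb, emb)
        rows.append(
            {
                "donor": r.donor,
                "season": r.season,
                "week": r.week,
                "endpoint": r.endpoint,
                "slope_xray": sx,
                "slope_alpha": sa,
                "slope_mb": smb,
                "slope_emb": emb,
                "ratio": sr.ratio,
                "defined": sr.defined,
            }
        )
    return pd.DataFrame(rows)


def pooled_synergy_estimates(synergy: pd.DataFrame) -> pd.DataFrame:
    """Two labelled pooled MB:EMB estimators, per donor and overall.

    mean_of_weekly_ratios averages the weekly observed/expected ratios
    (the descriptive statistic of the weekly heat table); it carries a
    small upward bias of order Var(EMB)/EMB^2 because the noisy expected
    slope sits in the denominator of every week.  ratio_of_mean_slopes
    divides the weekly-mean MB slope by the weekly-mean EMB slope per
    endpoint (then averages endpoints), which is the consistent estimator
    of a shared multiplicative interaction factor and is the one used for
    parameter recovery.
    """
    rows = []
    scopes = [("all", synergy)] + [(d, g) for d, g in synergy.groupby("donor")]
    for scope, sub in scopes:
        defined = sub[sub["defined"].astype(bool)]
        per_endpoint = []
        for _, g in defined.groupby("endpoint"):
            emb_mean = g["slope_emb"].mean()
            if emb_mean > 0:
                per_endpoint.append(g["slope_mb"].mean() / emb_mean)
        rows.append(
            {
                "scope": scope,
                "mean_of_weekly_ratios": float(defined["ratio"].mean()),
                "ratio_of_mean_slopes": float(np.mean(per_endpoint)) if per_endpoint else np.nan,
                "n_weekly_ratios": int(len(defined)),
            }
        )
    return pd.DataFrame(rows)


def table1(aber_fits: pd.DataFrame, target_effect: float = 10.0) -> pd.DataFrame:
    """Slope, dose-to-effect and RBE summaries over weekly aberration fits.

    Weekly RBE pairs each radiation's slope with the same week's X-ray
    slope; means and sds are over the weekly values, per donor and pooled.
    Weeks where a quantity is undefined (non-positive slope) are dropped
    from that quantity's summary and counted.
    """
    wide = aber_fits[aber_fits["endpoint"] == "ABER"].pivot_table(
        index=BLOCK, columns="radiation", values="slope"
    ).reset_index()
    weekly = []
    for r in wide.itertuples(index=False):
        for rad in ("xray", "alpha", "mixed"):
            slope = getattr(r, rad, np.nan)
            if np.isnan(slope):
                continue
            sx = getattr(r, "xray", np.nan)
            weekly.append(
                {
                    "donor": r.donor,
                    "season": r.season,
                    "week": r.week,
                    "radiation": rad,
                    "slope": slope,
                    "dose10": dose_to_effect(slope, target_effect) if slope > 0 else np.nan,
                    "rbe": rbe(slope, sx) if sx > 0 else np.nan,
                }
            )
    weekly = pd.DataFrame(weekly)
    rows = []
    scopes = [(d, g) for d, g in weekly.groupby("donor")] + [("pooled", weekly)]
    for scope, sub in scopes:
        for rad in ("xray", "alpha", "mixed"):
            g = sub[sub["radiation"] == rad]
            if g.empty:
                continue
            rows.append(
                {
                    "donor": scope,
                    "radiation": rad,
                    "slope_mean": g["slope"].mean(),
                    "slope_sd": g["slope"].std(ddof=1),
                    "dose10_mean": g["dose10"].mean(),
                    "dose10_sd": g["dose10"].std(ddof=1),
                    "rbe_mean": g["rbe"].mean(),
                    "rbe_sd": g["rbe"].std(ddof=1),
                    "n_weeks": int(len(g)),
                }
            )
    return pd.DataFrame(rows)


def mb_vs_emb_tests(synergy: pd.DataFrame) -> pd.DataFrame:
    """Weekly MB vs EMB slope comparison per donor and endpoint
    (two-sample pooled t with Cohen's d, the figure-caption statistic)."""
    rows = []
    for (donor, endpoint), g in synergy.groupby(["donor", "endpoint"]):
        if len(g) < 2:
            continue
        res = t_test_two_sample(g["slope_mb"].to_numpy(), g["slope_emb"].to_numpy())
        rows.append(
            {
                "donor": donor,
                "endpoint": endpoint,
                "mb_mean": g["slope_mb"].mean(),
                "emb_mean": g["slope_emb"].mean(),
                "t": res.statistic,
                "df": res.degrees_of_freedom,
                "p": res.p_value,
                "d": res.effect.d,
                "class": res.effect.magnitude_class,
                "n_weeks": int(len(g)),
            }
        )
    return pd.DataFrame(rows)


def seasonal_summaries(synergy: pd.DataFrame) -> pd.DataFrame:
    """Fig-3B-style per donor-season pooled ratio summaries."""
    rows = []
    for (donor, season), _ in synergy.groupby(["donor", "season"]):
        s = seasonal_summary(synergy, donor, int(season))
        rows.append(
            {
                "donor": s.donor,
                "season": s.season,
                "ratio_mean": s.ratio_mean,
                "ratio_sd": s.ratio_sd,
                "n_ratios": s.n_ratios,
                "n_undefined": s.n_undefined,
                "t_vs_1": s.test_vs_one.statistic,
                "p_vs_1": s.test_vs_one.p_value,
                "d_vs_1": s.test_vs_one.effect.d if s.test_vs_one.effect else np.nan,
                "class": s.test_vs_one.effect.magnitude_class if s.test_vs_one.effect else "",
                "synergy": s.ratio_mean > 1.0,
            }
        )
    return pd.DataFrame(rows)


def pooled_synergy_from_study(ct: pd.DataFrame, metaphases: pd.DataFrame) -> pd.Series:
    """Both pooled MB:EMB estimators for one study's raw tables."""
    fits = pd.concat(
        [aberration_fits(metaphases), expression_fits(ct)], ignore_index=True
    )
    pooled = pooled_synergy_estimates(weekly_synergy(fits))
    return pooled[pooled["scope"] == "all"].iloc[0]


def interaction_recovery_sweep(
    theta: float, n_replicates: int, base_seed: int, **config_overrides
) -> pd.DataFrame:
    """Estimate the mixed-beam interaction factor over replicate studies.

    Simulates `n_replicates` independent studies with the given theta
    (defaults otherwise) and runs the full raw-tables -> fits -> synergy
    pipeline on each.  Returns one row per replicate with both pooled
    estimators; their mean +/- Monte-Carlo error is the recovery check.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    rows = []
    for seed in seeds:
        cfg = SyntheticConfig(seed=int(seed), interaction_theta=theta, **config_overrides)
        study = simulate_study(cfg)
        est = pooled_synergy_from_study(study.ct, study.metaphases)
        rows.append(
            {
                "seed": int(seed),
                "theta": theta,
                "mean_of_weekly_ratios": est["mean_of_weekly_ratios"],
                "ratio_of_mean_slopes": est["ratio_of_mean_slopes"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """One reproducible run: paths plus the knobs of every stage."""

    out_dir: str = "results"
    ct_table: str | None = None
    metaphase_table: str | None = None
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    heat_bins: tuple[float, ...] = DEFAULT_RATIO_BINS
    rounding_decimals: int = 2
    target_effect: float = 10.0
    share_xray: float = 0.5

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["heat_bins"] = [float(b) for b in self.heat_bins]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "heat_bins" in d:
            d["heat_bins"] = tuple(float(b) for b in d["heat_bins"])
        return cls(**d)


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic study and write its raw + truth tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(seed=config.seed, **config.synthetic)
    log.info("simulating study: seed=%d theta=%g", syn.seed, syn.interaction_theta)
    study = simulate_study(syn)
    paths = {
        "ct_table": out / "ct_table.csv",
        "metaphase_table": out / "metaphase_table.csv",
        "truth": out / "truth.csv",
    }
    study.ct.to_csv(paths["ct_table"], index=False)
    study.metaphases.to_csv(paths["metaphase_table"], index=False)
    study.truth.to_csv(paths["truth"], index=False)
    config.ct_table = str(paths["ct_table"])
    config.metaphase_table = str(paths["metaphase_table"])
    return paths


def run_analyze(config: RunConfig) -> dict[str, Path]:
    """Run every analysis stage the input tables support.

    Aberration-only input skips the expression outputs (logged, not an
    error); synergy and seasonal outputs pool whatever endpoints exist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    fits_frames = []
    if config.metaphase_table:
        metaphases = pd.read_csv(config.metaphase_table)
        log.info("metaphase table: %d rows", len(metaphases))
        aber = aberration_fits(metaphases)
        fits_frames.append(aber)
        t1 = table1(aber, config.target_effect)
        for c in t1.columns:
            if c.endswith(("_mean", "_sd")):
                t1[c] = t1[c].map(lambda v: round_half_away(v, config.rounding_decimals) if pd.notna(v) else v)
        written["table1"] = out / "table1.csv"
        t1.to_csv(written["table1"], index=False)
    else:
        log.info("no metaphase table: skipping aberration outputs")

    net = None
    if config.ct_table:
        ct = pd.read_csv(config.ct_table)
        log.info("ct table: %d rows", len(ct))
        expr = expression_fits(ct)
        fits_frames.append(expr)
        net = qpcr.net_levels(ct)
        written["net_levels"] = out / "net_levels.csv"
        net.to_csv(written["net_levels"], index=False)
        folds = qpcr.fold_changes(ct)
        written["fold_changes"] = out / "fold_changes.csv"
        folds.to_csv(written["fold_changes"], index=False)
    else:
        expr = pd.DataFrame(columns=FIT_COLUMNS)
        log.info("no ct table: skipping expression outputs")

    if not fits_frames:
        raise ValueError("no input tables configured")
    fits = pd.concat(fits_frames, ignore_index=True)
    written["fits"] = out / "fits.csv"
    fits.to_csv(written["fits"], index=False)

    synergy = weekly_synergy(fits, config.share_xray)
    written["synergy_weekly"] = out / "synergy_weekly.csv"
    synergy.to_csv(written["synergy_weekly"], index=False)

    heat = ratio_heat_table(synergy, config.heat_bins)
    written["heat_table"] = out / "heat_table.csv"
    heat.to_csv(written["heat_table"], index=False)

    seasonal = seasonal_summaries(synergy)
    written["seasonal_summary"] = out / "seasonal_summary.csv"
    seasonal.to_csv(written["seasonal_summary"], index=False)

    pooled = pooled_synergy_estimates(synergy)
    written["pooled_synergy"] = out / "pooled_synergy.csv"
    pooled.to_csv(written["pooled_synergy"], index=False)

    tests = mb_vs_emb_tests(synergy)
    written["mb_vs_emb_tests"] = out / "mb_vs_emb_tests.csv"
    tests.to_csv(written["mb_vs_emb_tests"], index=False)

    if net is not None and not expr.empty:
        ratios = transcripts.build_pair_ratio_records(net, expr)
        written["pair_ratios"] = out / "pair_ratios.csv"
        ratios.to_csv(written["pair_ratios"], index=False)
        flags = transcripts.season_synergy_flags(seasonal)
        frames = [transcripts.analysis_to_frame(transcripts.pair_ratio_analysis(ratios, "all"), "all")]
        for subset in ("synergy_seasons", "non_synergy_seasons"):
            try:
                res = transcripts.pair_ratio_analysis(ratios, subset, flags)
            except ValueError as exc:
                log.info("subset %s skipped: %s", subset, exc)
                continue
            frames.append(transcripts.analysis_to_frame(res, subset))
        written["pair_ratio_tests"] = out / "pair_ratio_tests.csv"
        pd.concat(frames, ignore_index=True).to_csv(written["pair_ratio_tests"], index=False)

    manifest = {k: str(v) for k, v in written.items()}
    (out / "analyze_manifest.json").write_text(json.dumps(manifest, indent=2))
    return written


def run_report(config: RunConfig) -> str:
    """Render a plain-text summary from a completed analyze run."""
    out = Path(config.out_dir)
    manifest_path = out / "analyze_manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing {manifest_path}: run analyze first")
    manifest = json.loads(manifest_path.read_text())
    nd = config.rounding_decimals
    lines = ["Mixed-beam synergy analysis", "=" * 27, ""]

    def need(key: str) -> Path:
        p = Path(manifest.get(key, ""))
        if not p.exists():
            raise FileNotFoundError(f"missing analyze output for {key!r}")
        return p

    if "table1" in manifest:
        t1 = pd.read_csv(need("table1"))
        lines.append("Aberration slopes, dose to reach 10 aberrations/100 cells, RBE")
        lines.append("(mean +/- sd over weekly fits)")
        for r in t1.itertuples(index=False):
            lines.append(
                f"  {r.donor:>6} {r.radiation:>5}: slope {r.slope_mean} +/- {r.slope_sd}  "
                f"dose10 {r.dose10_mean} +/- {r.dose10_sd}  RBE {r.rbe_mean} +/- {r.rbe_sd}"
            )
        lines.append("")
    if "pooled_synergy" in manifest:
        pooled = pd.read_csv(need("pooled_synergy"))
        lines.append("Pooled MB:EMB synergy estimates")
        for r in pooled.itertuples(index=False):
            lines.append(
                f"  {r.scope:>6}: mean of weekly ratios {round_half_away(r.mean_of_weekly_ratios, nd)}"
                f", ratio of mean slopes {round_half_away(r.ratio_of_mean_slopes, nd)}"
                f" (n={r.n_weekly_ratios})"
            )
        lines.append("")
    if "seasonal_summary" in manifest:
        seas = pd.read_csv(need("seasonal_summary"))
        lines.append("Seasonal mean ratios vs additivity (1.0)")
        for r in seas.to_dict("records"):
            lines.append(
                f"  {r['donor']} season {r['season']}: {round_half_away(r['ratio_mean'], nd)} "
                f"+/- {round_half_away(r['ratio_sd'], nd)} "
                f"(p={r['p_vs_1']:.3g}, d={r['d_vs_1']:.2f}, {r['class']})"
            )
        lines.append("")
    text = "\n".join(lines)
    (out / "report.txt").write_text(text)
    return text
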