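"""Determinism, moment checks and parameter recovery of the generator."""

import numpy as np
import pandas as pd
import pytest

from mixedbeam import pipeline
from mixedbeam.simulate import (
    SyntheticConfig,
    expression_delta_ct,
    simulate_ct,
    simulate_metaphases,
    simulate_study,
)
from mixedbeam.study import ExposureCondition, Radiation


class TestConfig:
    def test_defaults_encode_study_design(self):
        cfg = SyntheticConfig()
        assert (cfg.donors, cfg.seasons, cfg.weeks_per_season) == (2, 3, 3)
        assert cfg.doses == (0.0, 0.5, 1.0, 2.0)
        assert cfg.metaphases_per_dose == 50
        assert cfg.ct_replicates == 2

    @pytest.mark.parametrize(
        "kwargs",
        [{"interaction_theta": 0.0}, {"season_effect_sd": -0.1},
         {"doses": (0.5, 1.0)}, {"weeks_per_season": 0},
         {"aberration_sampling": "exact"}],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestSimulateMetaphases:
    def test_no_signal_gives_all_diploid(self):
        rng = np.random.default_rng(0)
        recs = simulate_metaphases(
            ExposureCondition(Radiation.XRAY, 1.0), 0.0, 0.0, 20, rng
        )
        assert all(r.object_count == 46 for r in recs)

    def test_poisson_moment_check(self):
        rng = np.random.default_rng(1)
        recs = simulate_metaphases(
            ExposureCondition(Radiation.ALPHA, 1.0), 78.0, 0.0, 50_000, rng
        )
        freq = 100 * np.mean([r.object_count - 46 for r in recs])
        assert freq == pytest.approx(78.0, abs=3 * np.sqrt(78 / 500))

    def test_fixed_seed_reproducible(self):
        cond = ExposureCondition(Radiation.MIXED, 2.0)
        a = simulate_metaphases(cond, 50.0, 0.02, 100, np.random.default_rng(5))
        b = simulate_metaphases(cond, 50.0, 0.02, 100, np.random.default_rng(5))
        assert a == b

    def test_negative_mean_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            recs = simulate_metaphases(
                ExposureCondition(Radiation.MIXED, 2.0), -80.0, 0.02, 50,
                np.random.default_rng(2),
            )
        assert all(r.object_count == 46 for r in recs)


class TestSimulateCt:
    def test_dose_zero_gives_control_delta_ct(self):
        cfg = SyntheticConfig(ct_replicate_sd=0.0)
        df = simulate_ct(ExposureCondition(Radiation.CONTROL, 0.0), "FDXR_PP1",
                         cfg, np.random.default_rng(0))
        by_target = df.groupby("target")["ct"].mean()
        dct = by_target["FDXR_PP1"] - by_target["REF_18S"]
        assert dct == pytest.approx(cfg.control_delta_ct["FDXR_PP1"])

    def test_slope_one_dose_two_shifts_delta_ct_by_log2_three(self):
        assert expression_delta_ct(12.0, 1.0, 2.0) == pytest.approx(12.0 - np.log2(3.0))

    def test_noiseless_fold_recovery(self):
        cfg = SyntheticConfig(ct_replicate_sd=0.0)
        cond = ExposureCondition(Radiation.XRAY, 2.0)
        df = simulate_ct(cond, "CDKN1A_V1", cfg, np.random.default_rng(0))
        by_target = df.groupby("target")["ct"].mean()
        dct = by_target["CDKN1A_V1"] - by_target["REF_18S"]
        fold = 2.0 ** (cfg.control_delta_ct["CDKN1A_V1"] - dct)
        true_slope = cfg.expression_slopes["CDKN1A_V1"]["xray"]
        assert fold == pytest.approx(1 + true_slope * 2.0, rel=1e-12)

    def test_fold_floor_applied(self):
        assert expression_delta_ct(12.0, -3.0, 2.0) == pytest.approx(12.0 - np.log2(0.05))


class TestSimulateStudy:
    def test_identical_seeds_identical_tables(self):
        a = simulate_study(SyntheticConfig(seed=9))
        b = simulate_study(SyntheticConfig(seed=9))
        pd.testing.assert_frame_equal(a.ct, b.ct)
        pd.testing.assert_frame_equal(a.metaphases, b.metaphases)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = simulate_study(SyntheticConfig(seed=9))
        b = simulate_study(SyntheticConfig(seed=10))
        assert not a.ct["ct"].equals(b.ct["ct"])

    def test_design_shape(self, demo_study):
        meta, ct = demo_study.metaphases, demo_study.ct
        assert len(meta) == 2 * 3 * 3 * 10 * 50  # blocks x samples x cells
        assert len(ct) == 2 * 3 * 3 * 10 * 7 * 2  # blocks x samples x targets x reps
        assert set(meta["radiation"]) == {"control", "xray", "alpha", "mixed"}

    def test_truth_mixed_slope_is_theta_times_sea(self):
        st = simulate_study(SyntheticConfig(seed=4, interaction_theta=1.5))
        wide = st.truth.pivot_table(
            index=["donor", "season", "week", "endpoint"],
            columns="radiation", values="true_slope",
        )
        np.testing.assert_allclose(
            wide["mixed"], 1.5 * 0.5 * (wide["xray"] + wide["alpha"]), rtol=1e-12
        )

    def test_noiseless_pipeline_recovers_all_slopes(self):
        cfg = SyntheticConfig(
            seed=1, season_effect_sd=0.0, week_effect_sd=0.0, ct_replicate_sd=0.0,
            aberration_sampling="expected", metaphases_per_dose=200,
        )
        st = simulate_study(cfg)
        fits = pd.concat(
            [pipeline.aberration_fits(st.metaphases), pipeline.expression_fits(st.ct)],
            ignore_index=True,
        )
        merged = fits.merge(st.truth, on=["donor", "season", "week", "radiation", "endpoint"])
        rel = np.abs(merged["slope"] - merged["true_slope"]) / merged["true_slope"].abs()
        assert len(merged) == len(fits)
        assert rel.max() <= 1e-6
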