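"""Figure-background modulation statistics and population tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gestaltfbm.fbm_stats import (compare_areas, default_fbm_window,
                                  fbm_population, fbm_rf_correlation,
                                  fbm_site, fbm_texture_vs_gabor_window,
                                  shape_anova, weighted_paired_t)
from gestaltfbm.synthetic_data import (SimConfig, SiteModel,
                                       simulate_mua_dataset)
from gestaltfbm.ephys_preproc import baseline_correct, normalize_to_peak


class TestFBMSite:
    def test_identical_data_gives_exact_zero(self, rng):
        v = rng.normal(0, 1, 50)
        r = fbm_site(v, v)
        assert r.fbm_value == 0.0
        assert r.classification == "ns"

    def test_power_for_planted_enhancement(self):
        hits = 0
        for seed in range(20):
            rg = np.random.default_rng(seed)
            r = fbm_site(rg.normal(0.1, 0.2, 200), rg.normal(0.0, 0.2, 200))
            hits += r.classification == "enhanced"
        assert hits >= 19

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fbm_site([0.1], [0.2, 0.3])

    def test_window_convention(self):
        assert default_fbm_window("Bo", "V1", 200) == (100.0, 240.0)
        assert default_fbm_window("Da", "V1", 300) == (100.0, 340.0)
        assert default_fbm_window("Bo", "V4", 200) == (50.0, 240.0)


class TestWeightedPopulation:
    def test_uniform_weights_match_classical_paired_t(self, rng):
        v = rng.normal(0.05, 0.1, 24)
        monkeys = ["Bo"] * 12 + ["Du"] * 12
        w = weighted_paired_t(v, monkeys)
        t_ref, p_ref = stats.ttest_1samp(v, 0.0)
        assert w["t"] == pytest.approx(t_ref, abs=1e-12)
        assert w["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_equal_animal_contribution(self):
        v = np.r_[np.zeros(100), np.full(10, 0.2)]
        monkeys = ["Bo"] * 100 + ["Du"] * 10
        w = weighted_paired_t(v, monkeys)
        assert w["mean"] == pytest.approx(0.1)

    def test_null_f_test(self, rng):
        df = pd.DataFrame({
            "cue": np.repeat(["a", "b", "c"], 20),
            "fbm": np.zeros(60),
            "monkey": "Bo",
            "classification": "ns",
        })
        out = fbm_population(df)
        assert out["cue_effect"]["F"] == pytest.approx(0.0, abs=1e-9)
        assert out["single_monkey"]

    def test_cue_effect_detected(self, rng):
        fbm = np.r_[rng.normal(0.0, 0.02, 30), rng.normal(0.2, 0.02, 30)]
        df = pd.DataFrame({"cue": np.repeat(["sym", "all"], 30),
                           "fbm": fbm, "monkey": "Bo"})
        out = fbm_population(df)
        assert out["cue_effect"]["p"] < 1e-6


class TestCompareAreas:
    @staticmethod
    def _table(n, k, cue="closure"):
        cls = ["enhanced"] * k + ["ns"] * (n - k)
        return pd.DataFrame({"cue": cue, "classification": cls,
                             "fbm": np.linspace(0, 0.1, n)})

    def test_identical_proportions_give_zero_chi2(self):
        out = compare_areas(self._table(60, 30), self._table(60, 30))
        assert out.loc["closure", "chi2"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_textbook_pearson_statistic(self):
        v1, v4 = self._table(111, 15), self._table(75, 40)
        out = compare_areas(v1, v4)
        table = np.array([[15, 96], [40, 35]])
        n = table.sum()
        row, col = table.sum(1), table.sum(0)
        expected = np.outer(row, col) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert out.loc["closure", "chi2"] == pytest.approx(chi2)

    def test_missing_area_data_reported(self):
        out = compare_areas(self._table(20, 5, cue="closure"),
                            self._table(20, 5, cue="symmetry"))
        assert out.loc["symmetry", "note"] == "missing_area_data"
        assert np.isnan(out.loc["symmetry", "chi2"])


class TestShapeAnova:
    def test_planted_figure_shape_offset(self, rng):
        n = 180
        fg = np.repeat(["figure", "ground"], n // 2)
        shapes = np.tile(np.repeat([0, 1, 2], n // 6), 2)
        v = rng.normal(0, 0.1, n)
        v[(fg == "figure") & (shapes == 1)] += 0.3
        r = shape_anova(v, fg, shapes)
        assert r.figure_selective and r.p_figure < 1e-4
        assert not r.ground_selective

    def test_zero_between_group_variance(self):
        v = np.array([1.0, 1.0, 1.0, 1.0])
        r = shape_anova(v, ["figure"] * 4, [0, 0, 1, 1])
        assert r.f_figure == 0.0

    def test_single_shape_yields_nan(self):
        r = shape_anova([1, 2, 3, 4], ["figure"] * 4, [0, 0, 0, 0])
        assert np.isnan(r.f_figure)

    def test_type_i_error_calibrated(self):
        hits = 0
        n_sim = 400
        for seed in range(n_sim):
            rg = np.random.default_rng(seed)
            v = rg.normal(0, 1, 60)
            r = shape_anova(v, ["figure"] * 60,
                            np.repeat([0, 1, 2], 20))
            hits += r.p_figure < 0.05
        assert 0.02 < hits / n_sim < 0.08


class TestFBMRFCorrelation:
    def test_exact_anticorrelation(self):
        fwhm = np.linspace(2, 8, 10)
        out = fbm_rf_correlation(0.3 - 0.02 * fwhm, fwhm)
        assert out["r"] == pytest.approx(-1.0)

    def test_constant_fbm_warns(self):
        with pytest.warns(UserWarning):
            out = fbm_rf_correlation(np.ones(10), np.linspace(2, 8, 10))
        assert np.isnan(out["r"])

    def test_negative_slope_recovered(self):
        signs = 0
        for seed in range(20):
            rg = np.random.default_rng(seed)
            fwhm = rg.uniform(2, 9, 40)
            fbm = 0.25 - 0.02 * fwhm + rg.normal(0, 0.02, 40)
            out = fbm_rf_correlation(fbm, fwhm)
            signs += out["r"] < 0 and out["p"] < 0.05
        assert signs >= 19

    def test_small_rf_subgroup_comparison(self, rng):
        fwhm = np.r_[rng.uniform(2, 3.9, 19), rng.uniform(4.1, 9, 30)]
        fbm = np.where(fwhm < 4, 0.15, 0.05) + rng.normal(0, 0.02, 49)
        out = fbm_rf_correlation(fbm, fwhm)
        assert out["n_small"] == 19
        assert out["t_small_vs_large"] > 0


class TestWindowCorrelation:
    @staticmethod
    def _dataset(timecourse, seed=0, n_sites=8):
        sites = [SiteModel(site_id=f"s{i}",
                           fbm_amplitude=0.04 + 0.01 * i,
                           fbm_timecourse=timecourse, noise_sd=0.05)
                 for i in range(n_sites)]
        onset = 300 if timecourse == "transient_reversing" else 200
        cfg = SimConfig(seed=seed, design="constant_stimuli",
                        cues=("all_cues",), gabor_onset_ms=onset,
                        n_trials_per_site_condition=40, n_crf_trials=20)
        ds = simulate_mua_dataset(sites, cfg)
        return normalize_to_peak(baseline_correct(ds))

    def test_sustained_sites_positive_in_both_windows(self):
        out = fbm_texture_vs_gabor_window(self._dataset("sustained"))
        t = out["site_table"]
        assert (t["fbm_texture"] > 0).all()
        assert (t["fbm_gabor"] > 0).all()
        assert out["r"] > 0

    def test_reversing_sites_flip_sign_in_gabor_window(self):
        out = fbm_texture_vs_gabor_window(
            self._dataset("transient_reversing"))
        t = out["site_table"]
        assert (t["fbm_texture"] > 0).all()
        assert (t["fbm_gabor"] < 0).all()
        # amplitude scaling preserves a positive across-site correlation
        # of the *generated* modulation strengths only up to sign; the
        # generated pattern has texture and Gabor FBM proportional, so
        # |r| is large
        assert abs(out["r"]) > 0.5

    def test_zero_fbm_sites_near_zero(self):
        sites = [SiteModel(site_id=f"s{i}", fbm_amplitude=0.0,
                           noise_sd=0.05) for i in range(5)]
        cfg = SimConfig(seed=2, design="constant_stimuli",
                        cues=("all_cues",),
                        n_trials_per_site_condition=40, n_crf_trials=20)
        ds = normalize_to_peak(baseline_correct(
            simulate_mua_dataset(sites, cfg)))
        out = fbm_texture_vs_gabor_window(ds)
        assert np.abs(out["site_table"][["fbm_texture", "fbm_gabor"]]
                      .to_numpy()).max() < 0.02
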