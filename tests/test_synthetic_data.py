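"""Generative models: observers, closed-loop sessions, MUA cohorts."""

import numpy as np
import pytest

from gestaltfbm.ephys_preproc import baseline_correct, normalize_to_peak
from gestaltfbm.fbm_stats import window_means
from gestaltfbm.psychophysics import delta_pc, estimate_cdt
from gestaltfbm.synthetic_data import (CONSTANT_LEVELS, ObserverModel,
                                       SimConfig, SiteModel, TrialRecord,
                                       make_cohort, simulate_choice,
                                       simulate_mua_dataset,
                                       simulate_rf_responses,
                                       simulate_session)


class TestObserver:
    def test_symmetric_midpoint(self):
        obs = ObserverModel(gamma_true=0.0, lambda_true=0.0)
        trial = TrialRecord(test_contrast=30.0)
        assert obs.p_choose_test(trial) == pytest.approx(0.5)

    def test_lapse_caps_asymptote(self):
        obs = ObserverModel(gamma_true=0.0, lambda_true=0.4)
        trial = TrialRecord(test_contrast=1e6)
        assert obs.p_choose_test(trial) == pytest.approx(1 - 0.4)

    def test_total_response_bias_overrides_contrast(self, rng):
        obs = ObserverModel(response_bias=1.0, biased_side="lower")
        low = TrialRecord(test_contrast=10.0, test_position="lower")
        up = TrialRecord(test_contrast=60.0, test_position="upper")
        assert all(simulate_choice(obs, low, rng)[0] for _ in range(20))
        assert not any(simulate_choice(obs, up, rng)[0] for _ in range(20))

    def test_constraint_on_lapse(self):
        with pytest.raises(ValueError):
            ObserverModel(lambda_true=0.5)

    def test_figure_bias_shifts_perception_antisymmetrically(self):
        obs = ObserverModel(figure_bias=2.0)
        assert obs.perceived(30.0, "figure") == 31.0
        assert obs.perceived(30.0, "ground") == 29.0
        assert obs.perceived(30.0, "ambiguous") == 30.0


class TestSessions:
    def test_determinism(self):
        obs = ObserverModel(beta_true=1.0)
        cfg = SimConfig(seed=5, design="staircase_2d1u")
        a = simulate_session(obs, cfg)
        b = simulate_session(obs, cfg)
        assert a.equals(b)

    def test_constant_design_uses_fixed_levels(self):
        obs = ObserverModel()
        cfg = SimConfig(seed=1, design="constant_stimuli",
                        n_trials_per_condition=200)
        ses = simulate_session(obs, cfg)
        assert set(np.round(ses["test_contrast"].unique(), 6)) <= set(
            CONSTANT_LEVELS)
        assert len(CONSTANT_LEVELS) == 31
        assert min(CONSTANT_LEVELS) == 10.0 and max(CONSTANT_LEVELS) == 60.0

    def test_staircase_converges_near_707_point(self):
        # ideal observer: CDTs should bracket the reference by the
        # 70.7%-correct offset logit(sqrt(0.5)) / beta
        obs = ObserverModel(beta_true=2.0, gamma_true=0.0, lambda_true=0.0)
        asc, des = [], []
        for seed in range(40):
            ses = simulate_session(obs, SimConfig(
                seed=seed, design="staircase_2d1u", cues=("all_cues",)))
            sub = ses[(ses["cue"] == "all_cues")
                      & (ses["condition"] == "figure")]
            pair = estimate_cdt(sub)
            asc.append(pair.cdt_asc)
            des.append(pair.cdt_des)
        assert np.mean(asc) < 30.0 < np.mean(des)
        assert np.mean(asc) == pytest.approx(30.0, abs=2.0)
        mean_dpc = np.mean([delta_pc(type(
            "P", (), {"cdt_asc": a, "cdt_des": d,
                      "reference_contrast": 30.0})()) for a, d in
            zip(asc, des)])
        assert abs(mean_dpc) < 0.5

    def test_staircase_recovers_figure_bias(self):
        obs = ObserverModel(beta_true=2.0, gamma_true=0.0, lambda_true=0.0,
                            figure_bias=2.0)
        diffs = []
        for seed in range(40):
            ses = simulate_session(obs, SimConfig(
                seed=100 + seed, design="staircase_2d1u",
                cues=("all_cues",)))
            d = {}
            for cond in ("figure", "ground"):
                sub = ses[(ses["cue"] == "all_cues")
                          & (ses["condition"] == cond)]
                d[cond] = delta_pc(estimate_cdt(sub))
            diffs.append(d["figure"] - d["ground"])
        assert np.mean(diffs) == pytest.approx(2.0, abs=0.8)

    def test_quest_design_attaches_estimates(self):
        obs = ObserverModel(beta_true=0.5)
        ses = simulate_session(obs, SimConfig(seed=2, design="quest",
                                              cues=("all_cues",),
                                              n_quest_trials=60))
        assert ("all_cues", "figure") in ses.attrs["quest_estimates"]


@pytest.fixture(scope="module")
def null_dataset():
    sites = [SiteModel(site_id=f"s{i}", fbm_amplitude=0.0,
                       noise_sd=0.1) for i in range(6)]
    cfg = SimConfig(seed=3, design="constant_stimuli",
                    cues=("all_cues",), n_trials_per_site_condition=40,
                    n_crf_trials=60)
    return simulate_mua_dataset(sites, cfg)


class TestMUASimulation:

    def test_zero_fbm_amplitude_gives_null_difference(self, null_dataset):
        ds = normalize_to_peak(baseline_correct(null_dataset))
        diffs = []
        for site in ds.sites:
            m = window_means(site, ds.time_ms, (50, 240))
            fg = site.trials["figground"]
            diffs.append(m[(fg == "figure").to_numpy()].mean()
                         - m[(fg == "ground").to_numpy()].mean())
        assert abs(np.mean(diffs)) < 0.01

    def test_gabor_response_monotone_in_contrast(self):
        site = SiteModel(site_id="s", noise_sd=0.02)
        cfg = SimConfig(seed=4, design="constant_stimuli",
                        cues=("all_cues",), n_trials_per_site_condition=5,
                        n_crf_trials=300)
        ds = simulate_mua_dataset([site], cfg)
        s = ds.sites[0]
        m = window_means(s, ds.time_ms, (240, 340))
        c = s.trials["gabor_contrast"].to_numpy()
        amb = (s.trials["figground"] == "ambiguous").to_numpy()
        means = [m[amb & (np.abs(c - v) < 0.02)].mean()
                 for v in (0.1, 0.3, 0.6)]
        assert means[0] < means[1] < means[2]

    def test_transient_reversing_sign_pattern(self):
        site = SiteModel(site_id="s", fbm_amplitude=0.1,
                         fbm_timecourse="transient_reversing",
                         noise_sd=0.02)
        cfg = SimConfig(seed=5, design="constant_stimuli",
                        cues=("all_cues",), gabor_onset_ms=300,
                        n_trials_per_site_condition=60, n_crf_trials=20)
        ds = simulate_mua_dataset([site], cfg)
        s = ds.sites[0]
        fg = s.trials["figground"]
        sel_f = (fg == "figure").to_numpy()
        sel_g = (fg == "ground").to_numpy()
        tex = window_means(s, ds.time_ms, (100, 240))
        gab = window_means(s, ds.time_ms, (340, 440))
        assert tex[sel_f].mean() - tex[sel_g].mean() > 0
        assert gab[sel_f].mean() - gab[sel_g].mean() < 0

    def test_ground_truth_travels_with_data(self, null_dataset):
        gt = null_dataset.ground_truth
        assert gt["sites"]["s0"]["fbm_amplitude"] == 0.0
        assert gt["config"]["seed"] == 3

    def test_cohort_determinism(self):
        a = make_cohort(4, seed=9)
        b = make_cohort(4, seed=9)
        assert a == b


class TestRFSimulation:
    def test_grid_ground_truth_shapes(self):
        g = simulate_rf_responses((-3, -4), 1.5, protocol="grid",
                                  noise_sd=0.05, seed=1)
        assert g.responses.shape == (21, 21, 5)
        assert g.ground_truth["center"] == (-3, -4)

    def test_bar_positions_follow_speed(self):
        b = simulate_rf_responses((-3, -4), 1.0, protocol="bar_sweep",
                                  noise_sd=0.0)
        pos = b.positions["right"]
        t = b.time_ms
        sel = t >= 0
        v = np.gradient(pos[sel], t[sel] / 1000.0)
        assert np.nanmedian(v) == pytest.approx(15.75, rel=1e-6)
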