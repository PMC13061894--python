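"""Staircase, QUEST, CDT/perceived-contrast estimators, psychometric fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gestaltfbm.exceptions import EstimationError
from gestaltfbm.psychophysics import (CDTPair, PsychometricModel, Quest,
                                      QuestConfig, StaircaseState,
                                      bootstrap_pc_pvalue, delta_pc,
                                      estimate_cdt, figureness, run_quest,
                                      staircase_step)


class TestStaircase:
    def test_two_correct_step_down_and_counter_reset(self):
        s = StaircaseState(current_contrast=34.0, consecutive_correct=1)
        s2 = staircase_step(s, True)
        assert s2.current_contrast == 32.0       # 2% step pre-reversal
        assert s2.consecutive_correct == 0

    def test_single_correct_no_move(self):
        s = StaircaseState(current_contrast=34.0)
        s2 = staircase_step(s, True)
        assert s2.current_contrast == 34.0
        assert s2.consecutive_correct == 1

    def test_error_moves_away_from_reference(self):
        s = StaircaseState(current_contrast=26.0)   # below reference
        assert staircase_step(s, False).current_contrast == 24.0
        s = StaircaseState(current_contrast=34.0)
        assert staircase_step(s, False).current_contrast == 36.0

    def test_all_errors_pin_at_bound(self):
        s = StaircaseState(current_contrast=34.0)
        for _ in range(30):
            s = staircase_step(s, False)
        assert s.current_contrast == 38.0

    def test_step_schedule_follows_reversals(self):
        s = StaircaseState(current_contrast=38.0)
        assert s.step_size == 2.0
        # down, down (same direction), then an error reverses
        s = staircase_step(staircase_step(s, True), True)      # -> 36
        s = staircase_step(staircase_step(s, True), True)      # -> 34
        assert s.n_reversals == 0
        s = staircase_step(s, False)                           # -> 36, flip
        assert s.n_reversals == 1 and s.step_size == 1.0
        s = staircase_step(staircase_step(s, True), True)      # -> 35, flip
        assert s.n_reversals == 2 and s.step_size == 0.5

    def test_pinned_moves_are_not_direction_events(self):
        s = StaircaseState(current_contrast=38.0, direction="up")
        s2 = staircase_step(s, False)        # forced beyond bound: no change
        assert s2.current_contrast == 38.0
        assert s2.n_reversals == 0
        assert s2.direction == "up"


class TestCDT:
    @staticmethod
    def _session(asc, des, easy_rows=0):
        rows = []
        for d, vals in (("ascending", asc), ("descending", des)):
            for v in vals:
                rows.append({"staircase_id": d[:3], "direction": d,
                             "test_contrast": v, "is_easy": False,
                             "aborted": False})
        for _ in range(easy_rows):
            rows.insert(2, {"staircase_id": "asc", "direction": "ascending",
                            "test_contrast": 38.0, "is_easy": True,
                            "aborted": False})
        return pd.DataFrame(rows)

    def test_last_three_mean(self):
        ses = self._session([25, 26, 28, 28.5, 28], [36, 33, 31, 31, 31])
        pair = estimate_cdt(ses)
        assert pair.cdt_asc == pytest.approx((28 + 28.5 + 28) / 3)

    def test_easy_trials_excluded(self):
        a = estimate_cdt(self._session([25, 28, 28.5, 28], [33, 31, 31, 31]))
        b = estimate_cdt(self._session([25, 28, 28.5, 28], [33, 31, 31, 31],
                                       easy_rows=4))
        assert a == b

    def test_too_few_trials_raises(self):
        with pytest.raises(EstimationError):
            estimate_cdt(self._session([28, 28], [31, 31, 31]))


class TestDeltaPC:
    def test_null_and_geometric_mean(self):
        assert delta_pc(CDTPair(30, 30)) == 0.0
        assert delta_pc(CDTPair(25, 36)) == pytest.approx(0.0)
        assert delta_pc(CDTPair(28, 28)) == pytest.approx(2.0)

    def test_nonpositive_cdt_rejected(self):
        with pytest.raises(ValueError):
            delta_pc(CDTPair(-1.0, 30.0))

    @settings(deadline=None, max_examples=50)
    @given(a=st.floats(5, 60), d=st.floats(5, 60))
    def test_swap_invariance(self, a, d):
        assert delta_pc(CDTPair(a, d)) == pytest.approx(
            delta_pc(CDTPair(d, a)))


class TestQuest:
    @staticmethod
    def _observer(alpha, beta=0.5, lapse=0.02, seed=0):
        rng = np.random.default_rng(seed)

        def p(x):
            return 0.5 + (0.5 - lapse) * expit(beta * (x - alpha))

        return lambda x: bool(rng.random() < p(x)), p

    def test_converges_to_criterion_contrast(self):
        # observer whose 75%-point sits at 33%: mean estimate within 1%
        lapse, beta = 0.02, 0.5
        q = (0.75 - 0.5) / (0.5 - lapse)
        alpha = 33.0 - np.log(q / (1 - q)) / beta
        est = []
        for seed in range(100):
            obs, _ = self._observer(alpha, beta, lapse, seed=seed)
            est.append(run_quest(obs, QuestConfig(), seed=seed)["threshold"])
        assert np.mean(est) == pytest.approx(33.0, abs=1.0)

    def test_random_observer_flags_divergence(self):
        rng = np.random.default_rng(0)
        res = run_quest(lambda x: bool(rng.random() < 0.5),
                        QuestConfig(), seed=1)
        assert res["diverged"]

    def test_easy_trial_fraction(self):
        obs, _ = self._observer(30.0, seed=2)
        res = run_quest(obs, QuestConfig(n_trials=400), seed=2)
        frac = res["trials"]["is_easy"].mean()
        assert frac == pytest.approx(0.15, abs=0.05)
        easy = res["trials"].loc[res["trials"]["is_easy"], "test_contrast"]
        assert set(easy.unique()) <= {10.0, 50.0}

    def test_criterion_incompatible_with_lapse(self):
        with pytest.raises(ValueError):
            Quest(QuestConfig(criterion=0.99, assumed_lapse=0.02))


def _psychometric_trials(rng, alphas, beta=0.8, gamma=0.02, lam=0.02,
                         n_per=1000, levels=None):
    levels = np.linspace(10, 60, 26) if levels is None else levels
    frames = []
    for cond, a in alphas.items():
        x = rng.choice(levels, size=n_per)
        p = gamma + (1 - gamma - lam) * expit(beta * (x - a))
        frames.append(pd.DataFrame({
            "test_contrast": x, "chose_test": rng.random(n_per) < p,
            "cue": "all_cues", "condition": cond}))
    return pd.concat(frames, ignore_index=True)


class TestPsychometricFit:
    def test_parameter_recovery(self, rng):
        df = _psychometric_trials(rng, {"figure": 30.0, "ground": 28.0})
        fit = PsychometricModel(df, condition_cols=("cue", "condition")).fit()
        assert fit.alpha[("all_cues", "figure")] == pytest.approx(30.0,
                                                                  abs=1.0)
        assert fit.delta_pc(("all_cues", "figure"),
                            ("all_cues", "ground")) == pytest.approx(
            2.0, abs=1.0)

    def test_identical_conditions_give_zero_shift(self, rng):
        df = _psychometric_trials(rng, {"figure": 29.0, "ground": 29.0})
        fit = PsychometricModel(df, condition_cols=("cue", "condition")).fit()
        assert abs(fit.delta_pc(("all_cues", "figure"),
                                ("all_cues", "ground"))) < 1.0

    def test_gamma_outside_constraint_rejected(self, rng):
        df = _psychometric_trials(rng, {"a": 30.0, "b": 28.0}, n_per=100)
        model = PsychometricModel(df, condition_cols=("condition",))
        with pytest.raises(ValueError):
            model.fit(fix_gamma=0.5)

    def test_released_slope_never_decreases_loglik(self, rng):
        df = _psychometric_trials(rng, {"a": 30.0, "b": 28.0}, n_per=400)
        model = PsychometricModel(df, condition_cols=("condition",))
        shared = model.fit(share_slope=True)
        free = model.fit(share_slope=False)
        assert free.loglik >= shared.loglik - 1e-6


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        df = _psychometric_trials(rng, {"figure": 30.0, "ground": 30.0},
                                  n_per=300)
        fit = PsychometricModel(df, condition_cols=("cue", "condition")).fit()
        a = bootstrap_pc_pvalue(fit, n_boot=100, seed=42)
        b = bootstrap_pc_pvalue(fit, n_boot=100, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_power_with_large_effect(self, rng):
        df = _psychometric_trials(rng, {"figure": 31.5, "ground": 28.5},
                                  n_per=1500)
        fit = PsychometricModel(df, condition_cols=("cue", "condition")).fit()
        res = bootstrap_pc_pvalue(fit, n_boot=200, seed=0)
        assert res.loc["all_cues", "p_value"] < 0.05


class TestFigureness:
    @staticmethod
    def _trials(p_match, n_subjects=6, n=200, seed=0, cue="convexity"):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            for i in range(n):
                cued = "figure" if i % 2 == 0 else "background"
                match = rng.random() < p_match
                resp = cued if match else (
                    "background" if cued == "figure" else "figure")
                rows.append({"subject": s, "cue": cue, "cued": cued,
                             "response": resp})
        return pd.DataFrame(rows)

    def test_perfect_responder_scores_100(self):
        res = figureness(self._trials(1.0))
        assert res.percent_figure_correct["convexity"] == 100.0
        assert res.p_values["convexity"] < 0.05

    def test_random_responder_is_chance_and_ns(self):
        res = figureness(self._trials(0.5, n_subjects=8, n=400))
        assert res.percent_figure_correct["convexity"] == pytest.approx(
            50.0, abs=3.0)
        assert res.p_values["convexity"] > 0.05

    def test_single_subject_skips_test_with_warning(self):
        with pytest.warns(UserWarning):
            res = figureness(self._trials(0.9, n_subjects=1))
        assert np.isnan(res.p_values["convexity"])
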