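"""Generative models for behavior and neural data with known ground truth.

Every simulator here is the generative counterpart of an analysis stage
elsewhere in the package, so the full chain can be exercised and
validated without recorded data:

* :class:`ObserverModel` -- a parametric 2AFC contrast-discrimination
  observer whose perceived contrast is shifted by ``figure_bias`` on
  figure vs ground regions (the behavioral effect the analysis chain
  estimates);
* :func:`simulate_session` -- closed-loop behavioral sessions in which
  the staircase / QUEST engines choose contrasts and the observer
  answers (staircase, QUEST and constant-stimuli designs);
* :func:`simulate_mua_dataset` -- trial-wise MUA envelopes with a
  texture-onset transient, cue-dependent figure-background modulation
  (sustained or transient-reversing time course), Gabor-evoked
  transients governed by a Naka-Rushton contrast-response function,
  additive noise and slow baseline drift;
* :func:`simulate_rf_responses` -- bar-sweep and grid-flash mapping
  responses from known Gaussian receptive fields.

All outputs are exactly reproducible from (config, seed), and each
simulator stores its ground-truth parameters next to the data so
recovery tests never rely on hard-coded numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from gestaltfbm.contrast_link import NakaRushton
from gestaltfbm.ephys_preproc import MUADataset, SiteRecording, MUA_RATE_HZ
from gestaltfbm.psychophysics import (QuestConfig, Quest, StaircaseState,
                                      staircase_step)

__all__ = [
    "ObserverModel", "SiteModel", "SimConfig", "TrialRecord",
    "simulate_choice", "simulate_session", "simulate_mua_dataset",
    "simulate_rf_responses", "BarSweepData", "GridData",
    "FigurenessResponder", "simulate_figureness_trials", "make_cohort",
    "CONSTANT_LEVELS",
]

#: the fixed contrast set of the constant-stimuli design: 31 values, 10-60%
CONSTANT_LEVELS = tuple(np.round(np.linspace(10.0, 60.0, 31), 6))

CUES = ("symmetry", "closure", "convexity", "all_cues")


# --------------------------------------------------------------------------
# Behavioral observer


@dataclass(frozen=True)
class ObserverModel:
    """Parametric 2AFC observer with a figure-ground perceived-contrast bias.

    The probability of choosing the test Gabor as higher in contrast is

        psi(d) = gamma + (1 - gamma - lambda) / (1 + exp(-beta * d))

    where ``d`` is the difference in *perceived* contrast (%), and the
    perceived contrast of a Gabor on a figure region is shifted by
    ``+figure_bias/2`` and on a ground region by ``-figure_bias/2``
    (ambiguous regions are unshifted), so the fitted threshold
    difference ``alpha_fig - alpha_bg`` recovers ``figure_bias``.
    ``response_bias`` is the probability of choosing the Gabor on
    ``biased_side`` regardless of contrast.
    """

    alpha_true: float = 30.0          # threshold of p_correct(x), % contrast
    beta_true: float = 0.5            # per % contrast
    gamma_true: float = 0.02
    lambda_true: float = 0.02
    figure_bias: float = 0.0          # delta_true, % contrast (signed)
    response_bias: float = 0.0
    biased_side: str = "lower"

    def __post_init__(self):
        for name in ("gamma_true", "lambda_true"):
            v = getattr(self, name)
            if not 0 <= v <= 0.4:
                raise ValueError(f"{name} must lie in [0, 0.4]")

    def perceived(self, contrast: float, region: str) -> float:
        shift = {"figure": +0.5, "ground": -0.5}.get(region, 0.0)
        return contrast + shift * self.figure_bias

    def p_choose_test(self, trial: "TrialRecord") -> float:
        d = (self.perceived(trial.test_contrast, trial.test_region)
             - self.perceived(trial.reference_contrast, trial.ref_region))
        core = self.gamma_true + (1 - self.gamma_true - self.lambda_true) \
            * expit(self.beta_true * d)
        if self.response_bias > 0:
            bias_on_test = trial.test_position == self.biased_side
            core = ((1 - self.response_bias) * core
                    + self.response_bias * (1.0 if bias_on_test else 0.0))
        return float(np.clip(core, 0.0, 1.0))

    def p_correct(self, x: float) -> float:
        """Threshold-style accuracy function (2AFC guess rate 0.5)."""
        return float(0.5 + (0.5 - self.lambda_true)
                     * expit(self.beta_true * (x - self.alpha_true)))


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC contrast-discrimination trial."""

    test_contrast: float
    reference_contrast: float = 30.0
    test_region: str = "ambiguous"     # region under the test Gabor
    ref_region: str = "ambiguous"
    test_position: str = "lower"       # spatial side of the test Gabor
    cue: str = "all_cues"
    is_easy: bool = False


def simulate_choice(observer: ObserverModel, trial: TrialRecord,
                    rng: np.random.Generator):
    """Draw the observer's choice; returns ``(chose_test, correct)``.

    Correctness is defined against physical contrast; with equal
    physical contrasts either choice counts as correct with
    probability one half.
    """
    chose_test = bool(rng.random() < observer.p_choose_test(trial))
    dc = trial.test_contrast - trial.reference_contrast
    if dc == 0:
        correct = bool(rng.random() < 0.5)
    else:
        correct = chose_test == (dc > 0)
    return chose_test, correct


# --------------------------------------------------------------------------
# Session simulation (closed loop with the adaptive engines)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the behavioral/neural simulators.

    Defaults mirror the experimental designs: the human staircase runs
    on test contrasts bounded to 22-38% with 10% easy trials at 22 or
    38%; QUEST spans 10-50% with 15% easy trials at 10 or 50%; the
    constant-stimuli design draws from 31 fixed values between 10 and
    60%.  The Gabor appears 200 ms (or 300 ms) after texture onset and
    MUA is sampled at 763 Hz.
    """

    seed: int = 0
    design: str = "staircase_2d1u"     # staircase_2d1u | quest | constant_stimuli
    cues: tuple = ("all_cues",)
    reference_contrast: float = 30.0
    # staircase design
    n_staircase_trials: int = 30
    n_staircase_repeats: int = 1
    staircase_bounds: tuple = (22.0, 38.0)
    staircase_easy_fraction: float = 0.10
    staircase_easy_values: tuple = (22.0, 38.0)
    # quest design
    quest: QuestConfig = QuestConfig()
    n_quest_trials: int = 100
    # constant-stimuli design
    constant_levels: tuple = CONSTANT_LEVELS
    n_trials_per_condition: int = 100
    # neural simulation
    gabor_onset_ms: int = 200
    sample_rate_hz: float = MUA_RATE_HZ
    epoch_ms: tuple = (-300.0, 600.0)
    n_trials_per_site_condition: int = 40
    n_crf_trials: int = 200            # ambiguous-strip trials for CRF fits


def _gestalt_gabor(design: str) -> str:
    """Which Gabor sits on the figure-background strip, per design.

    In the human staircase experiment the variable-contrast *test*
    Gabor is on the Gestalt strip; in the monkey designs the constant
    *reference* Gabor is, while the test varies on the ambiguous strip.
    """
    return "test" if design == "staircase_2d1u" else "reference"


def _make_trial(config, cue, figground, test_contrast, is_easy,
                test_position="lower"):
    if _gestalt_gabor(config.design) == "test":
        test_region, ref_region = figground, "ambiguous"
    else:
        test_region, ref_region = "ambiguous", figground
    return TrialRecord(test_contrast=test_contrast,
                       reference_contrast=config.reference_contrast,
                       test_region=test_region, ref_region=ref_region,
                       test_position=test_position, cue=cue,
                       is_easy=is_easy)


def _session_row(i, trial, sc_id, direction, chose_test, correct):
    return {"trial": i, "cue": trial.cue, "condition": trial.test_region
            if trial.test_region != "ambiguous" else trial.ref_region,
            "staircase_id": sc_id, "direction": direction,
            "test_contrast": trial.test_contrast,
            "reference_contrast": trial.reference_contrast,
            "test_position": trial.test_position,
            "chose_test": chose_test, "correct": correct,
            "is_easy": trial.is_easy, "aborted": False}


def simulate_session(observer: ObserverModel,
                     config: SimConfig) -> pd.DataFrame:
    """Simulate one behavioral session in closed loop with the engines.

    The adaptive engines choose the test contrasts; the observer
    answers.  Returns an ordered trial table; for the QUEST design the
    per-condition threshold estimates are attached as
    ``df.attrs['quest_estimates']``.  Reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    conditions = [(cue, fg) for cue in config.cues
                  for fg in ("figure", "ground")]
    rows = []

    if config.design == "staircase_2d1u":
        pool = []
        for cue, fg in conditions:
            for rep in range(config.n_staircase_repeats):
                for direction, start, sign in (
                        ("ascending", config.staircase_bounds[0], +1),
                        ("descending", config.staircase_bounds[1], -1)):
                    state = StaircaseState(
                        current_contrast=start, step_sign_on_correct=sign,
                        bounds=config.staircase_bounds)
                    pool.append({"id": f"{cue}|{fg}|{direction}|{rep}",
                                 "cue": cue, "fg": fg,
                                 "direction": direction, "state": state,
                                 "remaining": config.n_staircase_trials})
        i = 0
        while any(s["remaining"] > 0 for s in pool):
            live = [s for s in pool if s["remaining"] > 0]
            sc = live[rng.integers(len(live))]
            if rng.random() < config.staircase_easy_fraction:
                x = float(rng.choice(config.staircase_easy_values))
                trial = _make_trial(config, sc["cue"], sc["fg"], x, True)
                chose, correct = simulate_choice(observer, trial, rng)
                rows.append(_session_row(i, trial, sc["id"],
                                         sc["direction"], chose, correct))
            else:
                x = sc["state"].current_contrast
                trial = _make_trial(config, sc["cue"], sc["fg"], x, False)
                chose, correct = simulate_choice(observer, trial, rng)
                rows.append(_session_row(i, trial, sc["id"],
                                         sc["direction"], chose, correct))
                sc["state"] = staircase_step(sc["state"], correct)
                sc["remaining"] -= 1
            i += 1
        df = pd.DataFrame(rows)

    elif config.design == "quest":
        estimates = {}
        i = 0
        for cue, fg in conditions:
            q = Quest(config.quest)
            for _ in range(config.n_quest_trials):
                easy = rng.random() < config.quest.easy_fraction
                x = (float(rng.choice(config.quest.easy_values)) if easy
                     else q.next_contrast())
                trial = _make_trial(config, cue, fg, x, easy)
                chose, correct = simulate_choice(observer, trial, rng)
                q.update(x, correct)
                rows.append(_session_row(i, trial, f"{cue}|{fg}|quest",
                                         "quest", chose, correct))
                i += 1
            estimates[(cue, fg)] = {"threshold": q.threshold_estimate(),
                                    "diverged": q.diverged()}
        df = pd.DataFrame(rows)
        df.attrs["quest_estimates"] = estimates

    elif config.design == "constant_stimuli":
        i = 0
        levels = np.asarray(config.constant_levels, float)
        for cue, fg in conditions:
            xs = rng.choice(levels, size=config.n_trials_per_condition)
            for x in xs:
                trial = _make_trial(config, cue, fg, float(x), False)
                chose, correct = simulate_choice(observer, trial, rng)
                rows.append(_session_row(i, trial, f"{cue}|{fg}|const",
                                         "constant", chose, correct))
                i += 1
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown design {config.design!r}")

    df.attrs["seed"] = config.seed
    df.attrs["design"] = config.design
    return df


# --------------------------------------------------------------------------
# Figure/background report task (Experiment-1 style)


@dataclass(frozen=True)
class FigurenessResponder:
    """Generative responder for the figure/background report task.

    ``p_match`` maps a cue to the probability that the response matches
    the cued role (figure when a figure is cued, background when a
    background is cued).  For cues not listed -- notably ambiguous
    strips -- the responder ignores the stimulus and answers 'figure'
    with probability ``p_figure_default``, which produces chance-level
    (50%) figureness scores.
    """

    p_match: dict = field(default_factory=dict)
    p_figure_default: float = 0.5


def simulate_figureness_trials(responder: FigurenessResponder, *,
                               n_subjects: int = 10,
                               n_trials_per_cue: int = 128,
                               cues=("symmetry", "closure", "convexity",
                                     "all_cues", "ambiguous"),
                               subject_sd: float = 0.03,
                               seed: int = 0) -> pd.DataFrame:
    """Simulate the figure/background report task.

    Figures and backgrounds are cued equally often.  Per-subject match
    probabilities are jittered by ``subject_sd`` around the responder's
    values to give realistic between-subject variability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for cue in cues:
            p = responder.p_match.get(cue)
            if p is not None:
                p = float(np.clip(p + rng.normal(0, subject_sd), 0, 1))
            for i in range(n_trials_per_cue):
                cued = "figure" if i % 2 == 0 else "background"
                if p is None:
                    resp = ("figure"
                            if rng.random() < responder.p_figure_default
                            else "background")
                else:
                    match = rng.random() < p
                    resp = cued if match else (
                        "background" if cued == "figure" else "figure")
                rows.append({"subject": f"s{s:02d}", "cue": cue,
                             "cued": cued, "response": resp})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Neural simulation


@dataclass(frozen=True)
class SiteModel:
    """Generative parameters of one recording site.

    ``fbm_amplitude`` (normalized units) is added to figure trials with
    the time course selected by ``fbm_timecourse``: ``sustained``
    (rises ~100 ms after texture onset and persists through the Gabor
    epoch) or ``transient_reversing`` (positive transient peaking
    ~140 ms that reverses sign before the Gabor appears -- the pattern
    where figures end up *reducing* the Gabor response).  Gabor-evoked
    transients have amplitude ``crf(contrast)``.  ``snr_true`` sets the
    across-trial baseline drift so that the day-level SNR statistic
    (peak / SD of baseline) lands near that value.
    """

    site_id: str
    monkey: str = "Bo"
    area: str = "V4"
    array_id: str = "arr0"
    rf_center: tuple = (-3.0, -4.0)
    rf_sigma: float = 1.5              # d.v.a., isotropic
    fbm_amplitude: float = 0.15        # n.u.
    fbm_timecourse: str = "sustained"
    crf: NakaRushton = NakaRushton(b=0.1, a=0.5, c50=0.3, n=2.0)
    noise_sd: float = 0.10             # n.u., per sample
    ar1: float = 0.0
    gain: float = 1.0                  # raw units per n.u.
    baseline: float = 0.5              # raw offset
    drift_sd: float = 0.0              # stationary SD of baseline drift, n.u.
    snr_true: float | None = None
    days: int = 1
    day_snr: dict | None = None        # optional per-day SNR override


def _alpha_kernel(t, tau):
    """Normalized alpha function: peaks at t = tau with value 1."""
    u = np.clip(t, 0, None) / tau
    return u * np.exp(1.0 - u)


def _fbm_timecourse(t, kind):
    """Figure-background modulation time course, peak-normalized.

    ``sustained``: sigmoidal rise at ~100 ms, persists.
    ``transient_reversing``: difference-of-exponentials transient
    (onset 100 ms, rise 25 ms, decay 70 ms) minus a slower sustained
    component, so the modulation is positive in the texture window and
    negative by the time the Gabor appears.
    """
    if kind == "sustained":
        return expit((t - 110.0) / 18.0)
    if kind == "transient_reversing":
        tau_r, tau_d, onset = 25.0, 70.0, 100.0
        u = np.clip(t - onset, 0, None)
        doe = np.exp(-u / tau_d) - np.exp(-u / tau_r)
        doe[t <= onset] = 0.0
        t_pk = np.log(tau_d / tau_r) * tau_d * tau_r / (tau_d - tau_r)
        pk = np.exp(-t_pk / tau_d) - np.exp(-t_pk / tau_r)
        return 1.8 * doe / pk - 0.9 * expit((t - 220.0) / 50.0)
    raise ValueError(f"unknown fbm_timecourse {kind!r}")


def _site_trace_components(t, site: SiteModel, gabor_onset):
    onset = _alpha_kernel(t, 45.0) + 0.2 * expit((t - 60.0) / 25.0)
    fbm = _fbm_timecourse(t, site.fbm_timecourse)
    gabor = _alpha_kernel(t - gabor_onset - 10.0, 50.0)
    return onset, fbm, gabor


def _site_trials(site: SiteModel, config: SimConfig, rng):
    """Trial metadata table for one site: Gestalt trials + CRF trials."""
    recs = []
    for cue in config.cues:
        for fg in ("figure", "ground"):
            for _ in range(config.n_trials_per_site_condition):
                recs.append({"cue": cue, "figground": fg,
                             "gabor_contrast": config.reference_contrast / 100,
                             "shape": int(rng.integers(3))})
    levels = np.asarray(config.constant_levels, float) / 100.0
    for _ in range(config.n_crf_trials):
        recs.append({"cue": "ambiguous", "figground": "ambiguous",
                     "gabor_contrast": float(rng.choice(levels)),
                     "shape": int(rng.integers(3))})
    df = pd.DataFrame(recs)
    df = df.sample(frac=1.0, random_state=rng.integers(2 ** 31)
                   ).reset_index(drop=True)
    n = len(df)
    df["day"] = np.sort(np.arange(n) % site.days)
    df["well_centered"] = True
    df["gabor_onset_ms"] = config.gabor_onset_ms
    return df


def simulate_mua_dataset(sites, config: SimConfig) -> MUADataset:
    """Simulate raw MUA envelopes for a cohort of sites.

    Each trial's trace is ``gain * (baseline + onset-transient +
    fbm-term + crf(contrast) * gabor-transient) + drift + noise``; the
    FBM term is added on figure trials only, so the figure-minus-ground
    difference in any window equals ``fbm_amplitude`` times the mean
    time course in that window.  Ground truth (site parameters and
    config) is stored on the returned dataset.
    """
    rng = np.random.default_rng(config.seed)
    dt = 1000.0 / config.sample_rate_hz
    t = np.arange(config.epoch_ms[0], config.epoch_ms[1], dt)
    if config.gabor_onset_ms + 140.0 > config.epoch_ms[1]:
        raise ValueError("Gabor analysis window exceeds the epoch")
    recordings = []
    for site in sites:
        trials = _site_trials(site, config, rng)
        onset, fbm, gabor = _site_trace_components(
            t, site, float(config.gabor_onset_ms))
        n_trials = len(trials)
        contrasts = trials["gabor_contrast"].to_numpy()
        is_fig = (trials["figground"] == "figure").to_numpy()
        sig = (site.baseline + onset[None, :]
               + np.where(is_fig, site.fbm_amplitude, 0.0)[:, None]
               * fbm[None, :]
               + site.crf(contrasts)[:, None] * gabor[None, :])
        noise = rng.normal(0.0, site.noise_sd, size=(n_trials, t.size))
        if site.ar1 > 0:
            from scipy.signal import lfilter
            noise = lfilter([np.sqrt(1 - site.ar1 ** 2)], [1, -site.ar1],
                            noise, axis=1)
        days = trials["day"].to_numpy()
        drift = np.zeros(n_trials)
        if site.drift_sd > 0:
            # slow across-trial drift (OU process): removable by the
            # robust-lowess baseline correction
            rho = 0.97
            step = np.sqrt(1 - rho ** 2)
            e = rng.normal(0, 1, n_trials)
            w = np.empty(n_trials)
            w[0] = e[0]
            for i in range(1, n_trials):
                w[i] = rho * w[i - 1] + step * e[i]
            drift = site.drift_sd * w
        if site.snr_true is not None or site.day_snr:
            # trial-to-trial baseline jitter (white, hence untouched by
            # baseline smoothing) calibrated so the day-level SNR
            # statistic (peak ~1.1 n.u. / SD of baseline) lands near
            # snr_true, with day_snr overriding single days
            for d in np.unique(days):
                snr_d = site.snr_true
                if site.day_snr and int(d) in site.day_snr:
                    snr_d = site.day_snr[int(d)]
                if snr_d is None:
                    continue
                sel = days == d
                drift[sel] += rng.normal(0.0, 1.1 / snr_d, sel.sum())
        data = site.gain * (sig + noise) + drift[:, None]
        recordings.append(SiteRecording(
            site_id=site.site_id, data=data, trials=trials,
            monkey=site.monkey, area=site.area, array_id=site.array_id,
            meta={"region_center": tuple(site.rf_center)}))
    gt = {"sites": {s.site_id: asdict(s) for s in sites},
          "config": asdict(config)}
    return MUADataset(sites=recordings, time_ms=t,
                      sample_rate=config.sample_rate_hz,
                      ground_truth=gt,
                      meta={"gabor_onset_ms": config.gabor_onset_ms})


def make_cohort(n_sites: int, *, monkey: str = "Bo", area: str = "V4",
                fbm_amplitude: float = 0.05,
                fbm_timecourse: str = "sustained",
                noise_sd: float = 0.10, seed: int = 0,
                array_id: str | None = None,
                rf_center=(-3.0, -4.0), **site_kw) -> list:
    """Build a cohort of :class:`SiteModel` with mild parameter jitter.

    Contrast-response parameters, FBM amplitudes and RF sizes vary
    across sites around the given values, as they do across recording
    sites of one array.
    """
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n_sites):
        crf = NakaRushton(
            b=float(np.clip(0.10 + rng.normal(0, 0.02), 0.0, 0.5)),
            a=float(np.clip(0.50 + rng.normal(0, 0.08), 0.1, 2.0)),
            c50=float(np.clip(0.30 + rng.normal(0, 0.05), 0.05, 0.9)),
            n=float(np.clip(2.0 + rng.normal(0, 0.3), 0.8, 4.0)))
        amp = float(fbm_amplitude * np.clip(rng.normal(1.0, 0.25), 0.2, 2.0))
        sites.append(SiteModel(
            site_id=f"{monkey}_{area}_{i:03d}", monkey=monkey, area=area,
            array_id=array_id or f"{monkey}_{area}_arr",
            rf_center=rf_center,
            rf_sigma=float(np.clip(rng.normal(1.8, 0.5), 0.6, 4.0)),
            fbm_amplitude=amp, fbm_timecourse=fbm_timecourse,
            crf=crf, noise_sd=noise_sd, **site_kw))
    return sites


# --------------------------------------------------------------------------
# RF-mapping simulation


@dataclass
class BarSweepData:
    """Simulated drifting-bar responses in the four cardinal directions."""

    time_ms: np.ndarray
    sweeps: dict                      # direction -> (trials, time)
    positions: dict                   # direction -> bar coordinate per sample
    baseline_mask: np.ndarray
    speed_deg_per_s: float
    ground_truth: dict = field(default_factory=dict)


@dataclass
class GridData:
    """Simulated grid-flash responses on a 21 x 21 grid of 1-deg squares."""

    xs: np.ndarray
    ys: np.ndarray
    responses: np.ndarray             # (n_y, n_x, n_reps)
    ground_truth: dict = field(default_factory=dict)

    @property
    def mean_grid(self) -> np.ndarray:
        return self.responses.mean(axis=2)


def simulate_rf_responses(rf_center=(-3.0, -4.0), rf_sigma=(1.5, 1.5), *,
                          protocol: str = "grid", amplitude: float = 1.0,
                          offset: float = 0.1, noise_sd: float = 0.0,
                          n_trials: int = 8, seed: int = 0,
                          speed_deg_per_s: float = 15.75,
                          sample_rate_hz: float = 200.0,
                          sweep_range=(-12.0, 12.0),
                          grid_x=None, grid_y=None, n_reps: int = 5):
    """Simulate RF-mapping responses from a known Gaussian RF.

    ``protocol='bar_sweep'`` yields per-direction response time courses
    (bar speed 15.75 deg/s, 4 cardinal directions, with a 100-ms
    pre-stimulus baseline); ``protocol='grid'`` yields responses to a
    21 x 21 grid of 1 x 1-deg squares.  Gaussian noise of ``noise_sd``
    is added; ground truth is attached to the returned object.
    """
    rng = np.random.default_rng(seed)
    sx, sy = (rf_sigma, rf_sigma) if np.isscalar(rf_sigma) else rf_sigma
    gt = {"center": tuple(rf_center), "sigma": (sx, sy),
          "amplitude": amplitude, "offset": offset, "noise_sd": noise_sd,
          "seed": seed}

    if protocol == "bar_sweep":
        lo, hi = sweep_range
        sweep_dur_ms = (hi - lo) / speed_deg_per_s * 1000.0
        dt = 1000.0 / sample_rate_hz
        time_ms = np.arange(-100.0, sweep_dur_ms, dt)
        baseline_mask = time_ms < 0
        sweeps, positions = {}, {}
        for direction, axis, sign in (("right", 0, +1), ("left", 0, -1),
                                      ("up", 1, +1), ("down", 1, -1)):
            start = lo if sign > 0 else hi
            pos = start + sign * speed_deg_per_s * (time_ms / 1000.0)
            pos[baseline_mask] = np.nan
            center = rf_center[axis]
            sigma = (sx, sy)[axis]
            clean = np.where(baseline_mask, 0.0,
                             amplitude * np.exp(
                                 -0.5 * ((np.nan_to_num(pos) - center)
                                         / sigma) ** 2)) + offset
            data = clean[None, :] + rng.normal(
                0, noise_sd, size=(n_trials, time_ms.size))
            sweeps[direction] = data
            positions[direction] = pos
        return BarSweepData(time_ms=time_ms, sweeps=sweeps,
                            positions=positions,
                            baseline_mask=baseline_mask,
                            speed_deg_per_s=speed_deg_per_s,
                            ground_truth=gt)

    if protocol == "grid":
        xs = np.arange(-10.0, 11.0) if grid_x is None else np.asarray(grid_x)
        ys = np.arange(-21.0, 0.0) if grid_y is None else np.asarray(grid_y)
        X, Y = np.meshgrid(xs, ys)
        clean = offset + amplitude * np.exp(
            -0.5 * (((X - rf_center[0]) / sx) ** 2
                    + ((Y - rf_center[1]) / sy) ** 2))
        responses = (clean[:, :, None]
                     + rng.normal(0, noise_sd,
                                  size=clean.shape + (n_reps,)))
        return GridData(xs=xs, ys=ys, responses=responses, ground_truth=gt)

    raise ValueError(f"unknown protocol {protocol!r}")
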