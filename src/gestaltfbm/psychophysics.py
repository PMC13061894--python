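"""Adaptive psychophysics and perceived-contrast estimation.

This module implements the behavioral analysis chain of the
figure-ground contrast-judgement experiments:

* a 2-down/1-up staircase engine with the reversal-dependent step
  schedule (2%, 1%, 0.5%) and contrast bounds of the human experiment;
* the contrast-discrimination-threshold (CDT) estimator (mean test
  contrast of the last 3 non-easy trials of a staircase) and the
  geometric-mean perceived-contrast difference
  ``dPC = reference - sqrt(CDT_asc * CDT_des)``, which accounts for
  Weber's law;
* a grid-based QUEST engine that places every trial at the current
  Bayesian threshold estimate for a 75%-correct criterion;
* a joint maximum-likelihood psychometric fit
  ``psi(x) = gamma + (1 - gamma - lambda) / (1 + exp(-beta (x - alpha)))``
  with slope, guess rate and lapse rate shared across conditions
  (parallel shifts only) and gamma, lambda constrained to [0, 0.4];
* the binomial bootstrap null for the fitted perceived-contrast
  difference ``alpha_fig - alpha_bg``;
* the Experiment-1 "figureness" score with right-sided Wilcoxon tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from gestaltfbm.exceptions import EstimationError

__all__ = [
    "StaircaseState", "staircase_step", "CDTPair", "estimate_cdt", "delta_pc",
    "QuestConfig", "Quest", "run_quest",
    "PsychometricModel", "PsychometricResults", "bootstrap_pc_pvalue",
    "FigurenessResult", "figureness",
]


# --------------------------------------------------------------------------
# 2-down/1-up staircase


@dataclass(frozen=True)
class StaircaseState:
    """State of a 2-down/1-up staircase on the test-Gabor contrast (%).

    The adaptive rule acts on the contrast *difference* between test
    and reference: two consecutive correct responses shrink the
    difference (the test contrast moves toward ``reference_contrast``),
    one error grows it.  ``step_sign_on_correct`` records the
    staircase's polarity for the degenerate case of a test contrast
    exactly at the reference: -1 for a descending staircase (contrast
    then decreases after two correct responses, as when starting from
    the upper bound) and +1 for an ascending one.  Step size follows
    the reversal schedule: 2% until the first reversal, 1% until the
    second, 0.5% afterwards.
    """

    current_contrast: float
    reference_contrast: float = 30.0
    step_sign_on_correct: int = -1
    consecutive_correct: int = 0
    n_reversals: int = 0
    direction: str = "none"              # last actual contrast movement
    bounds: tuple[float, float] = (22.0, 38.0)
    step_schedule: tuple[float, ...] = (2.0, 1.0, 0.5)
    history: tuple = ()

    @property
    def step_size(self) -> float:
        i = min(self.n_reversals, len(self.step_schedule) - 1)
        return self.step_schedule[i]


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    The test contrast moves toward the reference after two consecutive
    correct responses and away from it after one error; it is clipped
    to the staircase bounds.  A reversal is counted when the direction
    of an *actual* contrast change flips; a forced move beyond a bound
    that produces no contrast change is not a direction event.
    """
    cc = state.consecutive_correct
    side = np.sign(state.current_contrast - state.reference_contrast)
    if side == 0:
        side = -state.step_sign_on_correct
    move = 0.0
    if correct:
        cc += 1
        if cc >= 2:
            move = -side * state.step_size       # toward the reference
            cc = 0
    else:
        move = side * state.step_size            # away from the reference
        cc = 0
    new_contrast = float(np.clip(state.current_contrast + move, *state.bounds))
    actual = new_contrast - state.current_contrast
    direction = state.direction
    n_rev = state.n_reversals
    if actual != 0.0:
        new_dir = "down" if actual < 0 else "up"
        if direction != "none" and new_dir != direction:
            n_rev += 1
        direction = new_dir
    return replace(state, current_contrast=new_contrast,
                   consecutive_correct=cc, n_reversals=n_rev,
                   direction=direction,
                   history=state.history + ((state.current_contrast, bool(correct)),))


# --------------------------------------------------------------------------
# CDT and the geometric-mean perceived-contrast difference


@dataclass(frozen=True)
class CDTPair:
    """Contrast discrimination thresholds of an ascending/descending pair."""

    cdt_asc: float
    cdt_des: float
    reference_contrast: float = 30.0


def estimate_cdt(session: pd.DataFrame, *, reference_contrast: float = 30.0,
                 last_n: int = 3) -> CDTPair:
    """Estimate the CDT pair from a session table of one condition.

    The CDT of each staircase is the mean test contrast of its last
    ``last_n`` trials; easy trials and aborted trials are excluded
    first.  Staircases are identified by the ``staircase_id`` column and
    their polarity by ``direction`` ('ascending'/'descending'); multiple
    staircases of the same polarity (session repeats) are averaged with
    equal weights.
    """
    df = session
    if "is_easy" in df:
        df = df[~df["is_easy"].astype(bool)]
    if "aborted" in df:
        df = df[~df["aborted"].astype(bool)]
    cdts = {"ascending": [], "descending": []}
    for (sc_id, direction), grp in df.groupby(["staircase_id", "direction"],
                                              sort=False):
        if len(grp) < last_n:
            raise EstimationError(
                f"staircase {sc_id!r} has fewer than {last_n} usable trials")
        cdts[direction].append(grp["test_contrast"].to_numpy()[-last_n:].mean())
    if not cdts["ascending"] or not cdts["descending"]:
        raise EstimationError(
            "session must contain both an ascending and a descending staircase")
    return CDTPair(cdt_asc=float(np.mean(cdts["ascending"])),
                   cdt_des=float(np.mean(cdts["descending"])),
                   reference_contrast=reference_contrast)


def delta_pc(cdts: CDTPair) -> float:
    """Perceived-contrast shift: reference - geometric mean of the CDTs."""
    if cdts.cdt_asc <= 0 or cdts.cdt_des <= 0:
        raise ValueError("CDT values must be positive")
    return float(cdts.reference_contrast
                 - np.sqrt(cdts.cdt_asc * cdts.cdt_des))


# --------------------------------------------------------------------------
# QUEST


@dataclass(frozen=True)
class QuestConfig:
    """Parameters of the Bayesian adaptive procedure.

    The assumed psychometric family is a logistic in linear contrast
    with a 2AFC guess rate; the engine places each trial at the contrast
    where the assumed function, evaluated at the posterior-mean
    threshold, reaches ``criterion`` (default 75% correct).
    """

    n_trials: int = 100
    contrast_range: tuple[float, float] = (10.0, 50.0)
    easy_fraction: float = 0.15
    easy_values: tuple[float, float] = (10.0, 50.0)
    criterion: float = 0.75
    assumed_slope: float = 0.5           # per % contrast
    guess_rate: float = 0.5
    assumed_lapse: float = 0.02
    prior_mean: float = 30.0
    prior_sd: float = 10.0
    grid_margin: float = 5.0
    grid_step: float = 0.05


class Quest:
    """Grid-based QUEST posterior over the psychometric threshold."""

    def __init__(self, config: QuestConfig = QuestConfig()):
        self.config = c = config
        lo = c.contrast_range[0] - c.grid_margin
        hi = c.contrast_range[1] + c.grid_margin
        self.grid = np.arange(lo, hi + c.grid_step / 2, c.grid_step)
        self._logp = -0.5 * ((self.grid - c.prior_mean) / c.prior_sd) ** 2
        q = (c.criterion - c.guess_rate) / (1 - c.guess_rate - c.assumed_lapse)
        if not 0 < q < 1:
            raise ValueError("criterion incompatible with guess/lapse rates")
        #: contrast offset from the threshold parameter to the
        #: criterion-level contrast of the assumed function
        self.criterion_offset = float(np.log(q / (1 - q)) / c.assumed_slope)

    def _psi(self, x: float) -> np.ndarray:
        c = self.config
        return c.guess_rate + (1 - c.guess_rate - c.assumed_lapse) * expit(
            c.assumed_slope * (x - self.grid))

    def update(self, contrast: float, correct: bool) -> None:
        p = np.clip(self._psi(contrast), 1e-12, 1 - 1e-12)
        self._logp += np.log(p if correct else 1 - p)

    @property
    def posterior(self) -> np.ndarray:
        w = np.exp(self._logp - self._logp.max())
        return w / w.sum()

    def posterior_mean_sd(self) -> tuple[float, float]:
        w = self.posterior
        m = float(np.sum(w * self.grid))
        sd = float(np.sqrt(np.sum(w * (self.grid - m) ** 2)))
        return m, sd

    def threshold_estimate(self) -> float:
        """Current Bayesian estimate of the criterion-level contrast."""
        return self.posterior_mean_sd()[0] + self.criterion_offset

    def next_contrast(self) -> float:
        return float(np.clip(self.threshold_estimate(),
                             *self.config.contrast_range))

    def diverged(self) -> bool:
        """Posterior mass concentrated at the edge of the contrast range."""
        m, _ = self.posterior_mean_sd()
        lo, hi = self.config.contrast_range
        w = self.posterior
        edge_mass = float(w[self.grid <= lo].sum() + w[self.grid >= hi].sum())
        return bool(m <= lo or m >= hi or edge_mass > 0.5)


def run_quest(observer, config: QuestConfig = QuestConfig(), *,
              seed: int | None = None) -> dict:
    """Run a QUEST session against an ``observer`` callable.

    ``observer(test_contrast) -> bool`` must return the trial's
    correctness.  A fraction ``easy_fraction`` of trials is presented at
    the easy contrast values; all trials update the posterior.  Returns
    the final threshold estimate (criterion-level contrast), a posterior
    summary, the trial table and a divergence flag (posterior mass at
    the range edge is flagged, never silently accepted).
    """
    rng = np.random.default_rng(seed)
    q = Quest(config)
    rows = []
    for t in range(config.n_trials):
        easy = rng.random() < config.easy_fraction
        x = (float(rng.choice(config.easy_values)) if easy
             else q.next_contrast())
        correct = bool(observer(x))
        q.update(x, correct)
        rows.append((t, x, correct, easy))
    mean, sd = q.posterior_mean_sd()
    return {
        "threshold": q.threshold_estimate(),
        "posterior_mean": mean,
        "posterior_sd": sd,
        "diverged": q.diverged(),
        "trials": pd.DataFrame(rows, columns=["trial", "test_contrast",
                                              "correct", "is_easy"]),
    }


# --------------------------------------------------------------------------
# Constrained joint psychometric fit


def _bin_trials(x, response, n_bins, bin_range):
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    k = np.bincount(idx, weights=response, minlength=n_bins)
    n = np.bincount(idx, minlength=n_bins)
    xm = np.bincount(idx, weights=x, minlength=n_bins)
    keep = n > 0                      # empty bins are skipped
    return xm[keep] / n[keep], k[keep], n[keep]


class PsychometricModel:
    """Joint logistic psychometric model across stimulus conditions.

    The model is built from a trial table and bins test contrasts into
    ``n_bins`` bins over ``bin_range`` (defaults: 29 bins over 0-60%
    contrast).  ``x_col`` selects the stimulus variable -- the test
    contrast for perceived-contrast fits, or a signed contrast
    difference for threshold-style fits.  The response column must be
    binary (1 = "chose test" / correct).

    Fitting maximizes the joint binomial likelihood with the slope,
    guess rate and lapse rate shared across conditions and a separate
    threshold ``alpha`` per condition, so conditions differ only by
    parallel shifts along the contrast axis.
    """

    GAMMA_BOUNDS = (0.0, 0.4)
    LAMBDA_BOUNDS = (0.0, 0.4)

    def __init__(self, trials: pd.DataFrame, *, x_col: str = "test_contrast",
                 response_col: str = "chose_test",
                 condition_cols=("condition",),
                 n_bins: int = 29, bin_range=(0.0, 60.0)):
        self.condition_cols = tuple(condition_cols)
        self.n_bins = n_bins
        self.bin_range = tuple(bin_range)
        xs, ks, ns, cidx = [], [], [], []
        self.conditions = []
        for key, grp in trials.groupby(list(self.condition_cols), sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            xm, k, n = _bin_trials(grp[x_col].to_numpy(float),
                                   grp[response_col].to_numpy(float),
                                   n_bins, self.bin_range)
            self.conditions.append(tuple(key))
            xs.append(xm)
            ks.append(k)
            ns.append(n)
            cidx.append(np.full(xm.size, len(self.conditions) - 1))
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions for a joint fit")
        self.x = np.concatenate(xs)
        self.k = np.concatenate(ks)
        self.n = np.concatenate(ns)
        self.cond_idx = np.concatenate(cidx).astype(int)

    @classmethod
    def from_counts(cls, x, k, n, condition):
        """Build a model directly from per-level binomial counts."""
        obj = cls.__new__(cls)
        x = np.asarray(x, float)
        condition = np.asarray(condition)
        obj.condition_cols = ("condition",)
        obj.n_bins = None
        obj.bin_range = (float(x.min()), float(x.max()))
        obj.conditions = [(c,) for c in pd.unique(condition)]
        cmap = {c: i for i, (c,) in enumerate(obj.conditions)}
        obj.x = x
        obj.k = np.asarray(k, float)
        obj.n = np.asarray(n, float)
        obj.cond_idx = np.asarray([cmap[c] for c in condition], int)
        return obj

    # -- likelihood -------------------------------------------------------
    def _unpack(self, theta, share_slope):
        C = len(self.conditions)
        alphas = theta[:C]
        if share_slope:
            beta = np.full(C, theta[C])
            gamma, lam = theta[C + 1], theta[C + 2]
        else:
            beta = theta[C:2 * C]
            gamma, lam = theta[2 * C], theta[2 * C + 1]
        return alphas, beta, gamma, lam

    def _nll_grad(self, theta, share_slope=True):
        C = len(self.conditions)
        alphas, beta, gamma, lam = self._unpack(theta, share_slope)
        a = alphas[self.cond_idx]
        b = beta[self.cond_idx]
        L = expit(b * (self.x - a))
        psi = np.clip(gamma + (1 - gamma - lam) * L, 1e-10, 1 - 1e-10)
        nll = -np.sum(self.k * np.log(psi) + (self.n - self.k) * np.log(1 - psi))
        g_psi = self.k / psi - (self.n - self.k) / (1 - psi)
        w = (1 - gamma - lam) * L * (1 - L)
        grad = np.zeros_like(theta)
        np.add.at(grad, self.cond_idx, g_psi * w * b)          # d/d alpha
        if share_slope:
            grad[C] = -np.sum(g_psi * w * (self.x - a))
            grad[C + 1] = -np.sum(g_psi * (1 - L))
            grad[C + 2] = np.sum(g_psi * L)
        else:
            np.add.at(grad, C + self.cond_idx, -g_psi * w * (self.x - a))
            grad[2 * C] = -np.sum(g_psi * (1 - L))
            grad[2 * C + 1] = np.sum(g_psi * L)
        return nll, grad

    def _start(self, beta0):
        C = len(self.conditions)
        alphas = np.empty(C)
        for c in range(C):
            m = self.cond_idx == c
            p = self.k[m] / self.n[m]
            target = 0.5 * (p.min() + p.max())
            alphas[c] = self.x[m][np.argmin(np.abs(p - target))]
        return alphas

    def fit(self, *, share_slope: bool = True, fix_gamma: float | None = None,
            fix_lambda: float | None = None,
            beta_starts=(0.15, 0.5, 1.5), start=None) -> "PsychometricResults":
        """Maximum-likelihood fit (L-BFGS-B with analytic gradient).

        ``fix_gamma``/``fix_lambda`` pin the guess/lapse rate; values
        outside the [0, 0.4] constraint are rejected.
        """
        for name, v, bds in (("gamma", fix_gamma, self.GAMMA_BOUNDS),
                             ("lambda", fix_lambda, self.LAMBDA_BOUNDS)):
            if v is not None and not bds[0] <= v <= bds[1]:
                raise ValueError(
                    f"{name} must lie within {bds}; got {v}")
        C = len(self.conditions)
        span = self.bin_range[1] - self.bin_range[0] or 1.0
        alo, ahi = (self.bin_range[0] - 2 * span, self.bin_range[1] + 2 * span)
        nb = C if not share_slope else 1
        bounds = ([(alo, ahi)] * C + [(1e-4, 50.0)] * nb
                  + [self.GAMMA_BOUNDS if fix_gamma is None
                     else (fix_gamma, fix_gamma)]
                  + [self.LAMBDA_BOUNDS if fix_lambda is None
                     else (fix_lambda, fix_lambda)])
        best = None
        starts = []
        if start is not None:
            starts.append(np.asarray(start, float))
        for b0 in beta_starts:
            th0 = np.concatenate([self._start(b0), np.full(nb, b0),
                                  [0.02, 0.02]])
            if fix_gamma is not None:
                th0[-2] = fix_gamma
            if fix_lambda is not None:
                th0[-1] = fix_lambda
            starts.append(th0)
        for th0 in starts:
            res = optimize.minimize(
                self._nll_grad, th0, args=(share_slope,), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200, "ftol": 1e-11})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        return PsychometricResults(self, best.x, -best.fun,
                                   bool(best.success), share_slope)


class PsychometricResults:
    """Results of a joint psychometric fit."""

    def __init__(self, model, theta, loglik, converged, share_slope):
        self.model = model
        self.theta = np.asarray(theta, float)
        self.loglik = float(loglik)
        self.converged = converged
        self.share_slope = share_slope
        alphas, beta, gamma, lam = model._unpack(self.theta, share_slope)
        names = [c[0] if len(c) == 1 else c for c in model.conditions]
        self.alpha = pd.Series(alphas, index=names, name="alpha")
        self.beta = pd.Series(beta, index=names, name="beta")
        self.gamma = float(gamma)
        self.lambda_ = float(lam)

    def predict(self, x, condition):
        i = [c[0] if len(c) == 1 else c
             for c in self.model.conditions].index(condition)
        return (self.gamma + (1 - self.gamma - self.lambda_)
                * expit(self.beta.iloc[i] * (np.asarray(x, float)
                                             - self.alpha.iloc[i])))

    def delta_pc(self, cond_fig, cond_bg) -> float:
        """Perceived-contrast difference ``alpha_fig - alpha_bg``."""
        return float(self.alpha[cond_fig] - self.alpha[cond_bg])

    def summary(self) -> str:
        lines = ["Joint psychometric fit (logistic, shared slope/asymptotes)",
                 f"  log-likelihood: {self.loglik:.3f}   "
                 f"converged: {self.converged}",
                 f"  beta (slope):  {self.beta.iloc[0]:.4f} per % contrast"
                 if self.share_slope else
                 "  per-condition slopes: "
                 + ", ".join(f"{b:.4f}" for b in self.beta),
                 f"  gamma (guess): {self.gamma:.4f}   "
                 f"lambda (lapse): {self.lambda_:.4f}",
                 "  alpha (threshold / PSE, % contrast):"]
        for name, a in self.alpha.items():
            lines.append(f"    {name}: {a:.3f}")
        return "\n".join(lines)


def bootstrap_pc_pvalue(results: PsychometricResults, *, n_boot: int = 1000,
                        seed: int | None = None,
                        pair=("figure", "ground"),
                        max_failure_rate: float = 0.05) -> pd.DataFrame:
    """Binomial bootstrap null for the fitted perceived-contrast difference.

    Model conditions must be ``(cue, figure/ground)`` pairs.  For every
    bootstrap replicate and contrast bin, surrogate correct-counts for
    the two members of each cue's pair are drawn from a binomial whose
    success probability is the pooled probability of a correct response
    across the pair (the null of no figure-ground difference), keeping
    the original trial counts.  The full model is refit per replicate
    and the two-tailed p-value per cue is the proportion of unsigned
    null differences at least as large as the observed one.  The
    smallest attainable p is ``1 / n_boot``.
    """
    model = results.model
    if len(model.condition_cols) != 2:
        raise ValueError("bootstrap requires (cue, figure/ground) conditions")
    rng = np.random.default_rng(seed)
    cues = sorted({c[0] for c in model.conditions})
    pairs = {}
    for cue in cues:
        try:
            i_f = model.conditions.index((cue, pair[0]))
            i_b = model.conditions.index((cue, pair[1]))
        except ValueError:
            continue
        m_f = np.where(model.cond_idx == i_f)[0]
        m_b = np.where(model.cond_idx == i_b)[0]
        # align bins of the two conditions on the bin value
        common = np.intersect1d(np.round(model.x[m_f], 9),
                                np.round(model.x[m_b], 9))
        sel_f = m_f[np.isin(np.round(model.x[m_f], 9), common)]
        sel_b = m_b[np.isin(np.round(model.x[m_b], 9), common)]
        pairs[cue] = (i_f, i_b, sel_f, sel_b)

    observed = {cue: results.theta[i_f] - results.theta[i_b]
                for cue, (i_f, i_b, *_rest) in pairs.items()}
    null_counts = {cue: 0 for cue in pairs}
    n_used = 0
    n_failed = 0
    k0 = model.k.copy()
    share = results.share_slope
    C = len(model.conditions)
    nb = 1 if share else C
    span = model.bin_range[1] - model.bin_range[0] or 1.0
    bounds = ([(model.bin_range[0] - 2 * span,
                model.bin_range[1] + 2 * span)] * C
              + [(1e-4, 50.0)] * nb
              + [model.GAMMA_BOUNDS, model.LAMBDA_BOUNDS])
    pooled = {cue: ((k0[sel_f] + k0[sel_b])
                    / (model.n[sel_f] + model.n[sel_b]))
              for cue, (_f, _b, sel_f, sel_b) in pairs.items()}
    try:
        for _ in range(n_boot):
            model.k = k0.copy()
            for cue, (_if, _ib, sel_f, sel_b) in pairs.items():
                p_pool = pooled[cue]
                model.k[sel_f] = rng.binomial(
                    model.n[sel_f].astype(int), p_pool)
                model.k[sel_b] = rng.binomial(
                    model.n[sel_b].astype(int), p_pool)
            res = optimize.minimize(
                model._nll_grad, results.theta, args=(share,), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 150, "ftol": 1e-10})
            if not res.success:
                n_failed += 1
                continue
            n_used += 1
            for cue, (i_f, i_b, *_rest) in pairs.items():
                d = res.x[i_f] - res.x[i_b]
                if abs(d) >= abs(observed[cue]) - 1e-12:
                    null_counts[cue] += 1
    finally:
        model.k = k0
    if n_failed > max_failure_rate * n_boot:
        raise EstimationError(
            f"{n_failed}/{n_boot} bootstrap refits failed")
    rows = [{"cue": cue, "observed_delta_pc": float(observed[cue]),
             "p_value": null_counts[cue] / n_used if n_used else np.nan,
             "n_boot": n_used, "n_failed": n_failed}
            for cue in pairs]
    return pd.DataFrame(rows).set_index("cue")


# --------------------------------------------------------------------------
# Figureness (Experiment 1)


@dataclass
class FigurenessResult:
    """Per-cue figureness scores and their population tests."""

    scores: pd.DataFrame            # rows: subject x cue, percent correct
    percent_figure_correct: pd.Series
    p_values: pd.Series             # Bonferroni-corrected, right-sided
    n_subjects: int
    bonferroni_family: int


def figureness(trials: pd.DataFrame, *, chance: float = 50.0,
               bonferroni_family: int | None = None) -> FigurenessResult:
    """Score how reliably a cue induces the intended figure-ground percept.

    ``trials`` must have columns ``subject``, ``cue``, ``cued``
    ('figure'/'background': which role was presented at the probed
    location) and ``response`` ('figure'/'background').  The per-subject
    score is the percentage of trials on which the response matched the
    cued role; 50% is chance.  Per cue, subjects' scores are tested
    against chance with a right-sided Wilcoxon signed-rank test,
    Bonferroni-corrected over the cue family.
    """
    df = trials.copy()
    df["hit"] = (df["response"] == df["cued"]).astype(float)
    scores = (df.groupby(["subject", "cue"], sort=True)["hit"]
              .mean().mul(100.0).rename("score").reset_index())
    per_cue = scores.groupby("cue")["score"].mean()
    n_subjects = scores["subject"].nunique()
    family = bonferroni_family or scores["cue"].nunique()
    pvals = {}
    for cue, grp in scores.groupby("cue"):
        vals = grp["score"].to_numpy() - chance
        if len(vals) < 2:
            warnings.warn(
                f"cue {cue!r}: fewer than 2 subjects, Wilcoxon test skipped",
                stacklevel=2)
            pvals[cue] = np.nan
            continue
        if np.allclose(vals, 0):
            pvals[cue] = 1.0
            continue
        stat = stats.wilcoxon(vals, alternative="greater")
        pvals[cue] = min(1.0, stat.pvalue * family)
    return FigurenessResult(
        scores=scores,
        percent_figure_correct=per_cue,
        p_values=pd.Series(pvals, name="p_bonferroni"),
        n_subjects=n_subjects,
        bonferroni_family=family,
    )
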