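"""Figure-background modulation (FBM) statistics.

FBM is the difference between the neural response to a texture region
when it is a perceptual figure vs when it is background, with identical
stimulation of the receptive field.  This module computes FBM per site
(window-averaged figure-minus-ground difference with an independent
samples t-test and a two-one-tailed-test classification), population
statistics in which each animal contributes equally (inverse
site-count weighting), V1-vs-V4 comparisons of the classification
proportions, a within-category shape-selectivity ANOVA, and the
correlations of FBM with RF size and between analysis windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gestaltfbm.ephys_preproc import MUADataset, window_mask

__all__ = [
    "FBMSiteResult", "fbm_site", "default_fbm_window", "window_means",
    "fbm_dataset", "fbm_population", "compare_areas",
    "ShapeSelectivityResult", "shape_anova",
    "fbm_rf_correlation", "fbm_texture_vs_gabor_window",
    "weighted_paired_t",
]


# --------------------------------------------------------------------------
# Site-level FBM


@dataclass(frozen=True)
class FBMSiteResult:
    """Window-averaged FBM of one site with its classification."""

    fbm_value: float                  # mean figure - mean ground, n.u.
    t_statistic: float
    p_two_sided: float
    classification: str               # enhanced | suppressed | ns
    window_ms: tuple
    n_figure: int
    n_ground: int
    site_id: str | None = None
    cue: str | None = None


def default_fbm_window(monkey: str, area: str,
                       gabor_onset_ms: float) -> tuple[float, float]:
    """Texture-window convention: V1 starts at 100 ms, V4 at 50 ms
    (FBM arises earlier in V4); the window ends 40 ms after the Gabor
    appears (240 ms for a 200-ms onset, 340 ms for a 300-ms onset)."""
    start = 50.0 if area.upper() == "V4" else 100.0
    return (start, float(gabor_onset_ms) + 40.0)


def fbm_site(figure_values, ground_values, *, window_ms=(np.nan, np.nan),
             alpha: float = 0.05, site_id=None, cue=None) -> FBMSiteResult:
    """Independent-samples t-test of figure vs ground window responses.

    Classification uses two single-tailed tests at ``alpha``:
    *enhanced* if figure responses are significantly higher,
    *suppressed* if significantly lower, otherwise *ns*.
    """
    f = np.asarray(figure_values, float)
    g = np.asarray(ground_values, float)
    if f.size < 2 or g.size < 2:
        raise ValueError("need at least 2 trials per group")
    t, p = stats.ttest_ind(f, g, equal_var=True)
    p_enh = stats.ttest_ind(f, g, equal_var=True,
                            alternative="greater").pvalue
    p_sup = stats.ttest_ind(f, g, equal_var=True,
                            alternative="less").pvalue
    if p_enh < alpha:
        cls = "enhanced"
    elif p_sup < alpha:
        cls = "suppressed"
    else:
        cls = "ns"
    return FBMSiteResult(fbm_value=float(f.mean() - g.mean()),
                         t_statistic=float(t), p_two_sided=float(p),
                         classification=cls, window_ms=tuple(window_ms),
                         n_figure=f.size, n_ground=g.size,
                         site_id=site_id, cue=cue)


def window_means(site, time_ms, window) -> np.ndarray:
    """Per-trial mean response in a closed [start, end] ms window."""
    return site.data[:, window_mask(time_ms, window)].mean(axis=1)


def fbm_dataset(dataset: MUADataset, *, window=None,
                cues=None, alpha: float = 0.05) -> pd.DataFrame:
    """Site x cue FBM table for a (normalized) MUA dataset.

    ``window`` defaults to the per-monkey/area convention of
    :func:`default_fbm_window` using the dataset's Gabor onset.
    """
    rows = []
    onset = dataset.meta.get("gabor_onset_ms", 200.0)
    for site in dataset.sites:
        win = window or default_fbm_window(site.monkey, site.area, onset)
        tr = site.trials
        site_cues = cues or [c for c in tr["cue"].unique()
                             if c != "ambiguous"]
        for cue in site_cues:
            sel_f = (tr["cue"] == cue) & (tr["figground"] == "figure")
            sel_g = (tr["cue"] == cue) & (tr["figground"] == "ground")
            if sel_f.sum() < 2 or sel_g.sum() < 2:
                continue
            m = window_means(site, dataset.time_ms, win)
            r = fbm_site(m[sel_f.to_numpy()], m[sel_g.to_numpy()],
                         window_ms=win, alpha=alpha,
                         site_id=site.site_id, cue=cue)
            rows.append({"site_id": site.site_id, "monkey": site.monkey,
                         "area": site.area, "array_id": site.array_id,
                         "cue": cue, "fbm": r.fbm_value,
                         "t": r.t_statistic, "p": r.p_two_sided,
                         "classification": r.classification,
                         "window_start_ms": win[0], "window_end_ms": win[1]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Population statistics with equal-animal weighting


def _monkey_weights(monkeys) -> np.ndarray:
    """Inverse site-count weights, normalized to sum to the site count."""
    monkeys = np.asarray(monkeys)
    counts = pd.Series(monkeys).value_counts()
    w = np.array([1.0 / counts[m] for m in monkeys])
    return w * monkeys.size / w.sum()


def weighted_paired_t(values, monkeys):
    """Paired t-test of per-site differences with equal-animal weights.

    Weights are the inverse of each monkey's site count, normalized to
    sum to the number of sites; the statistic uses the weighted mean
    and weighted variance with ``df = n_sites - 1``.  With uniform
    weights this reproduces the classical paired t-test exactly.
    """
    v = np.asarray(values, float)
    w = _monkey_weights(monkeys)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 sites")
    m = float(np.sum(w * v) / n)
    s2 = float(np.sum(w * (v - m) ** 2) / (n - 1))
    if s2 == 0.0:
        t = 0.0 if m == 0.0 else np.sign(m) * np.inf
    else:
        t = m / np.sqrt(s2 / n)
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return {"mean": m, "t": float(t), "p": float(p), "df": n - 1,
            "weights": w}


def fbm_population(site_table: pd.DataFrame, *, cue=None) -> dict:
    """Population FBM tests: per-cue weighted t and a cue-effect F-test.

    ``site_table`` is the output of :func:`fbm_dataset`.  Per cue, the
    figure-minus-ground values are tested against zero with
    :func:`weighted_paired_t`; the effect of cue on FBM magnitude is
    tested with a weighted one-way linear model (WLS F-test).  With a
    single monkey the weights are uniform and the tests reduce to their
    classical forms (noted in the output).
    """
    import statsmodels.api as sm

    df = site_table if cue is None else site_table[site_table["cue"] == cue]
    single_monkey = df["monkey"].nunique() == 1
    per_cue = {}
    for c, grp in df.groupby("cue"):
        r = weighted_paired_t(grp["fbm"].to_numpy(), grp["monkey"])
        per_cue[c] = {"weighted_mean_fbm": r["mean"], "t": r["t"],
                      "p": r["p"], "df": r["df"], "n_sites": len(grp)}
    out = {"per_cue": per_cue, "single_monkey": single_monkey}
    if df["cue"].nunique() >= 2:
        w = _monkey_weights(df["monkey"])
        X = pd.get_dummies(df["cue"], drop_first=True).astype(float)
        X = sm.add_constant(X)
        res = sm.WLS(df["fbm"].to_numpy(float), X, weights=w).fit()
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            F, p = float(res.fvalue), float(res.f_pvalue)
        if not np.isfinite(F):            # degenerate zero-variance input
            F, p = 0.0, 1.0
        out["cue_effect"] = {"F": F, "p": p,
                             "df_model": int(res.df_model),
                             "df_resid": int(res.df_resid)}
    return out


def compare_areas(v1_table: pd.DataFrame, v4_table: pd.DataFrame, *,
                  target_class: str = "enhanced") -> pd.DataFrame:
    """Compare FBM between areas per cue.

    For each cue, a 2 x 2 Pearson chi-square (1 df, no continuity
    correction) tests whether the proportion of ``target_class`` sites
    differs between V1 and V4, and an independent-samples t-test
    compares the FBM magnitudes.  Sparse tables (expected count < 1)
    fall back to Fisher's exact test with a warning.
    """
    rows = []
    cues = sorted(set(v1_table["cue"]) | set(v4_table["cue"]))
    for cue in cues:
        a = v1_table[v1_table["cue"] == cue]
        b = v4_table[v4_table["cue"] == cue]
        if a.empty or b.empty:
            rows.append({"cue": cue, "chi2": np.nan, "p_chi2": np.nan,
                         "note": "missing_area_data"})
            continue
        k1 = int((a["classification"] == target_class).sum())
        k4 = int((b["classification"] == target_class).sum())
        table = np.array([[k1, len(a) - k1], [k4, len(b) - k4]])
        note = ""
        if table.sum() and (stats.contingency.expected_freq(table) < 1).any():
            warnings.warn("expected cell count < 1; using Fisher's exact "
                          "test", stacklevel=2)
            chi2 = np.nan
            p = float(stats.fisher_exact(table)[1])
            note = "fisher_exact"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        t, p_t = stats.ttest_ind(a["fbm"], b["fbm"], equal_var=True)
        rows.append({"cue": cue,
                     "prop_v1": k1 / len(a), "prop_v4": k4 / len(b),
                     "n_v1": len(a), "n_v4": len(b),
                     "chi2": float(chi2) if np.isfinite(chi2) else np.nan,
                     "p_chi2": float(p), "t_fbm": float(t),
                     "p_t_fbm": float(p_t), "note": note})
    return pd.DataFrame(rows).set_index("cue")


# --------------------------------------------------------------------------
# Shape selectivity


@dataclass(frozen=True)
class ShapeSelectivityResult:
    """One-way ANOVAs over shapes, separately for figures and grounds."""

    f_figure: float
    p_figure: float
    f_ground: float
    p_ground: float
    figure_selective: bool
    ground_selective: bool
    site_id: str | None = None


def shape_anova(window_values, figground, shapes, *, alpha: float = 0.05,
                site_id=None) -> ShapeSelectivityResult:
    """Within-category shape ANOVA, isolating shape tuning from FBM.

    One-way fixed-effects ANOVAs are run over the shape identity of
    figure trials and, separately, of ground trials (disjoint trial
    sets).  A category with fewer than 2 shapes (or < 2 trials per
    shape) yields NaN for that category.
    """
    v = np.asarray(window_values, float)
    fg = np.asarray(figground)
    sh = np.asarray(shapes)

    def one(category):
        sel = fg == category
        groups = [v[sel & (sh == s)] for s in np.unique(sh[sel])]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            return np.nan, np.nan
        if all(np.ptp(g) == 0 for g in groups) and \
                np.ptp([g.mean() for g in groups]) == 0:
            return 0.0, 1.0
        f, p = stats.f_oneway(*groups)
        return float(f), float(p)

    ff, pf = one("figure")
    fg_, pg = one("ground")
    return ShapeSelectivityResult(
        f_figure=ff, p_figure=pf, f_ground=fg_, p_ground=pg,
        figure_selective=bool(pf < alpha) if np.isfinite(pf) else False,
        ground_selective=bool(pg < alpha) if np.isfinite(pg) else False,
        site_id=site_id)


# --------------------------------------------------------------------------
# FBM vs RF size / window correlations


def fbm_rf_correlation(fbm_values, rf_fwhm, *,
                       small_rf_threshold: float = 4.0) -> dict:
    """Pearson correlation of site FBM with RF size (FWHM).

    Also compares FBM between sites with small (FWHM < threshold) and
    large RFs with an independent-samples t-test.  Degenerate inputs
    (n < 3 or zero variance) yield NaN with a warning.
    """
    f = np.asarray(fbm_values, float)
    s = np.asarray(rf_fwhm, float)
    out = {"n": f.size, "small_rf_threshold": small_rf_threshold}
    if f.size < 3:
        out.update(r=np.nan, p=np.nan, note="too_few_sites")
        return out
    if np.ptp(f) == 0 or np.ptp(s) == 0:
        warnings.warn("zero variance in FBM or RF size; correlation "
                      "undefined", stacklevel=2)
        out.update(r=np.nan, p=np.nan, note="zero_variance")
        return out
    r, p = stats.pearsonr(f, s)
    out.update(r=float(r), p=float(p), note="")
    small = s < small_rf_threshold
    if small.sum() >= 2 and (~small).sum() >= 2:
        t, pt = stats.ttest_ind(f[small], f[~small], equal_var=True)
        out.update(n_small=int(small.sum()), t_small_vs_large=float(t),
                   p_small_vs_large=float(pt))
    return out


def fbm_texture_vs_gabor_window(dataset: MUADataset, *,
                                texture_window=None,
                                gabor_window=None,
                                cue=None) -> dict:
    """FBM in the texture window vs the Gabor window, across sites.

    The Gabor window defaults to 40-140 ms after Gabor onset.  Returns
    the per-site pairs and their across-site Pearson correlation.  A
    texture window reaching beyond 40 ms after Gabor onset (into the
    Gabor-evoked transient) triggers a configuration warning.
    """
    onset = dataset.meta.get("gabor_onset_ms", 200.0)
    gw = gabor_window or (onset + 40.0, onset + 140.0)
    rows = []
    for site in dataset.sites:
        tw = texture_window or default_fbm_window(site.monkey, site.area,
                                                  onset)
        if tw[1] > onset + 40.0:
            warnings.warn("texture window extends into the Gabor-evoked "
                          "transient", stacklevel=2)
        tr = site.trials
        site_cues = ([cue] if cue else
                     [c for c in tr["cue"].unique() if c != "ambiguous"])
        sel_f = tr["cue"].isin(site_cues) & (tr["figground"] == "figure")
        sel_g = tr["cue"].isin(site_cues) & (tr["figground"] == "ground")
        if sel_f.sum() < 2 or sel_g.sum() < 2:
            continue
        mt = window_means(site, dataset.time_ms, tw)
        mg = window_means(site, dataset.time_ms, gw)
        rows.append({"site_id": site.site_id, "monkey": site.monkey,
                     "fbm_texture": float(mt[sel_f.to_numpy()].mean()
                                          - mt[sel_g.to_numpy()].mean()),
                     "fbm_gabor": float(mg[sel_f.to_numpy()].mean()
                                        - mg[sel_g.to_numpy()].mean())})
    table = pd.DataFrame(rows)
    out = {"site_table": table}
    if len(table) >= 3 and table["fbm_texture"].std() > 0 \
            and table["fbm_gabor"].std() > 0:
        r, p = stats.pearsonr(table["fbm_texture"], table["fbm_gabor"])
        out.update(r=float(r), p=float(p))
    else:
        out.update(r=np.nan, p=np.nan)
    return out
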