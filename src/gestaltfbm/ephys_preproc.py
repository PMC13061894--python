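"""MUA envelope extraction, baseline correction, normalization and QC.

The multi-unit activity (MUA) envelope is obtained from broadband
extracellular recordings by band-pass filtering (500-5000 Hz), full-wave
rectification, 200-Hz low-pass filtering and resampling to 763 Hz,
followed by a 50-Hz notch and a 5th-order 40-Hz Butterworth low-pass.
Trials are then baseline-corrected with a robust locally-weighted
estimate of the across-trial baseline drift, normalized to the peak of
the mean visual transient (30-100 ms), and screened by signal-to-noise
and receptive-field-centering criteria.

All offline filters are applied forward-backward (zero phase) so that
response-latency statistics downstream are not distorted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SiteRecording", "MUADataset", "SiteQCReport", "QCConfig",
    "mua_from_broadband", "baseline_correct", "normalize_to_peak",
    "qc_filter", "smoothed_mean", "window_mask",
]

MUA_RATE_HZ = 24414.0625 / 32          # 763.0 Hz (TDT rate family)


# --------------------------------------------------------------------------
# Containers


@dataclass
class SiteRecording:
    """Trials x time MUA of one recording site, with trial metadata.

    ``trials`` has one row per trial; recognised columns include
    ``cue``, ``figground`` ('figure'/'ground'/'ambiguous'), ``shape``
    (region identity index), ``gabor_contrast`` (fraction),
    ``gabor_onset_ms``, ``day`` and ``well_centered``.
    """

    site_id: str
    data: np.ndarray                   # (n_trials, n_samples)
    trials: pd.DataFrame
    monkey: str = "Bo"
    area: str = "V1"
    array_id: str = "arr0"
    meta: dict = field(default_factory=dict)

    def copy(self) -> "SiteRecording":
        return SiteRecording(self.site_id, self.data.copy(),
                             self.trials.copy(), self.monkey, self.area,
                             self.array_id, dict(self.meta))


@dataclass
class MUADataset:
    """A collection of site recordings on a common time axis.

    ``time_ms`` is relative to texture onset.  ``state`` flags record
    the preprocessing stage; they are monotone (a dataset is never
    un-normalized).  Analysis windows are closed intervals
    ``[start, end]``, inclusive of both edge samples.
    """

    sites: list
    time_ms: np.ndarray
    sample_rate: float = MUA_RATE_HZ
    state: dict = field(default_factory=lambda: {
        "baseline_corrected": False, "normalized": False})
    ground_truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def copy(self) -> "MUADataset":
        return MUADataset([s.copy() for s in self.sites],
                          self.time_ms.copy(), self.sample_rate,
                          dict(self.state), dict(self.ground_truth),
                          dict(self.meta))

    def site(self, site_id: str) -> SiteRecording:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)


def window_mask(time_ms: np.ndarray, window) -> np.ndarray:
    """Boolean mask for a closed [start, end] window in ms."""
    lo, hi = window
    return (time_ms >= lo) & (time_ms <= hi)


def smoothed_mean(data: np.ndarray, n_samples: int = 20) -> np.ndarray:
    """Mean trace across trials, smoothed with a locally-weighted window.

    Local linear regression with tricube weights over ``n_samples``
    points (the classic lowess smoother used on mean MUA traces).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    m = np.asarray(data, float).mean(axis=0)
    frac = min(1.0, n_samples / m.size)
    t = np.arange(m.size, dtype=float)
    return lowess(m, t, frac=frac, it=0, return_sorted=False)


# --------------------------------------------------------------------------
# Broadband -> MUA envelope


def mua_from_broadband(broadband: np.ndarray, fs: float = 24414.0625, *,
                       notch: bool = True, notch_freq: float = 50.0,
                       notch_q: float = 10.0) -> tuple[np.ndarray, float]:
    """Convert a broadband signal to the 763-Hz MUA envelope.

    Pipeline order: band-pass 500-5000 Hz (4th-order Butterworth) ->
    full-wave rectification -> low-pass 200 Hz -> decimation by 32 to
    763 Hz -> 50-Hz notch -> 5th-order Butterworth low-pass at 40 Hz.
    All filters are zero phase.  Returns ``(envelope, out_rate)``.
    """
    x = np.asarray(broadband, float)
    if np.any(~np.isfinite(x)):
        raise ValueError("broadband signal contains NaN/Inf")
    if fs < 2 * 5000:
        raise ValueError("input sample rate must be at least 10 kHz")
    if x.shape[-1] < int(0.05 * fs):
        raise ValueError("signal too short for stable filter edges")

    sos_bp = signal.butter(4, [500, 5000], btype="bandpass", fs=fs,
                           output="sos")
    y = signal.sosfiltfilt(sos_bp, x, axis=-1)
    y = np.abs(y)                                   # full-wave rectification
    sos_lp = signal.butter(4, 200, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos_lp, y, axis=-1)
    y = y[..., ::32]                                # anti-aliased decimation
    out_fs = fs / 32
    if notch:
        b, a = signal.iirnotch(notch_freq, notch_q, fs=out_fs)
        y = signal.filtfilt(b, a, y, axis=-1)
    sos_40 = signal.butter(5, 40, btype="low", fs=out_fs, output="sos")
    y = signal.sosfiltfilt(sos_40, y, axis=-1)
    return y, out_fs


# --------------------------------------------------------------------------
# Baseline correction and normalization


def _robust_trend(values: np.ndarray, span: float = 0.3, it: int = 5):
    """Robust lowess trend across the trial sequence (30% span)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    t = np.arange(values.size, dtype=float)
    return lowess(values, t, frac=span, it=it, return_sorted=False)


def baseline_correct(dataset: MUADataset, *,
                     baseline_window=(-100.0, 0.0),
                     span: float = 0.3,
                     min_trials: int = 10) -> MUADataset:
    """Subtract a robust smoothed across-trial baseline estimate.

    Per site, the mean activity in the baseline window (-100-0 ms) is
    computed per trial, smoothed across the trial sequence with a
    robust locally-weighted regression (``span`` of the data per
    window, bisquare-iterated), and the smoothed estimate is subtracted
    from each trial's entire trace.  This removes slow drifts while
    being insensitive to single outlier trials.  With fewer than
    ``min_trials`` trials the smoother degenerates and a per-trial mean
    subtraction is applied instead (with a warning).
    """
    mask = window_mask(dataset.time_ms, baseline_window)
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    out = dataset.copy()
    for site in out.sites:
        base = site.data[:, mask].mean(axis=1)
        if base.size < min_trials:
            warnings.warn(
                f"site {site.site_id}: fewer than {min_trials} trials; "
                "falling back to per-trial baseline subtraction",
                stacklevel=2)
            trend = base
        else:
            trend = _robust_trend(base, span=span)
        site.data = site.data - trend[:, None]
    out.state["baseline_corrected"] = True
    return out


def _peak_estimate(site: SiteRecording, time_ms, *,
                   peak_window=(30.0, 100.0), smooth_samples: int = 20):
    """Peak of the moving-averaged mean response of well-centered trials."""
    wc = site.trials.get("well_centered")
    sel = (np.ones(len(site.trials), bool) if wc is None
           else wc.to_numpy(bool))
    if not sel.any():
        return np.nan
    m = site.data[sel].mean(axis=0)
    kernel = np.ones(smooth_samples) / smooth_samples
    sm = np.convolve(m, kernel, mode="same")
    pw = window_mask(time_ms, peak_window)
    return float(sm[pw].max())


def normalize_to_peak(dataset: MUADataset, *,
                      peak_window=(30.0, 100.0),
                      smooth_samples: int = 20) -> MUADataset:
    """Normalize every trial by the site's peak visual transient.

    The peak is the maximum, within 30-100 ms, of the mean response
    across well-centered trials smoothed with a ``smooth_samples``-point
    moving average.  After normalization activity is in normalized
    units (n.u.): 1 equals the peak response.  Sites with a non-positive
    peak are excluded with reason code ``nonpositive_peak``.  The
    operation is idempotent.
    """
    out = dataset.copy()
    kept = []
    excluded = dict(out.meta.get("excluded_sites", {}))
    for site in out.sites:
        peak = _peak_estimate(site, out.time_ms, peak_window=peak_window,
                              smooth_samples=smooth_samples)
        if not np.isfinite(peak) or peak <= 0:
            excluded[site.site_id] = "nonpositive_peak"
            continue
        site.data = site.data / peak
        site.meta["normalization_peak"] = peak
        kept.append(site)
    out.sites = kept
    out.meta["excluded_sites"] = excluded
    out.state["normalized"] = True
    return out


# --------------------------------------------------------------------------
# Site / day quality control


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the site/day inclusion chain."""

    day_snr_min: float = 0.5
    day_correlation_min: float = 0.85
    site_snr_min: float = 1.0
    rf_offset_max_x: float = 1.0       # d.v.a.
    rf_offset_max_y: float = 2.0       # d.v.a.
    baseline_window: tuple = (-100.0, 0.0)
    peak_window: tuple = (30.0, 100.0)
    smooth_samples: int = 20


@dataclass
class SiteQCReport:
    """Day- and site-level inclusion decisions with reason codes."""

    day_table: pd.DataFrame          # site, day, snr, correlation, included, reason
    site_table: pd.DataFrame         # site, overall_snr, rf offsets, included, reason
    config: QCConfig = field(default_factory=QCConfig)


def _day_snr(site, day_sel, time_ms, cfg: QCConfig):
    sub = SiteRecording(site.site_id, site.data[day_sel],
                        site.trials.loc[day_sel].reset_index(drop=True))
    peak = _peak_estimate(sub, time_ms, peak_window=cfg.peak_window,
                          smooth_samples=cfg.smooth_samples)
    bmask = window_mask(time_ms, cfg.baseline_window)
    base_sd = float(site.data[day_sel][:, bmask].mean(axis=1).std(ddof=1))
    return peak / base_sd if base_sd > 0 else np.inf


def qc_filter(dataset: MUADataset, rf_table: pd.DataFrame | None = None, *,
              region_centers: dict | None = None,
              config: QCConfig = QCConfig()):
    """Apply the day- and site-level inclusion chain.

    Per site and recording day, the SNR (peak of the smoothed mean
    well-centered response divided by the across-trial SD of the
    baseline) must reach ``day_snr_min`` and the day's mean
    well-centered response must correlate with the across-day average
    above ``day_correlation_min``.  Sites are then included if their
    overall SNR (across surviving days) exceeds ``site_snr_min`` and,
    when an RF table is given, the RF center is within 1 d.v.a. of the
    region center horizontally and 2 d.v.a. vertically.

    ``rf_table`` needs columns ``site_id``, ``x``, ``y``;
    ``region_centers`` maps site_id -> (x, y) of the probed region
    (defaults to the dataset-level ``meta['region_center']``).

    Returns ``(SiteQCReport, filtered MUADataset)``.
    """
    cfg = config
    time_ms = dataset.time_ms
    rf_lookup = {}
    if rf_table is not None:
        rf_lookup = {str(r.site_id): (float(r.x), float(r.y))
                     for r in rf_table.itertuples()}
    day_rows, site_rows = [], []
    out = dataset.copy()
    kept_sites = []
    for site in out.sites:
        days = (site.trials["day"].to_numpy()
                if "day" in site.trials else np.zeros(len(site.trials), int))
        uniq = np.unique(days)
        wc = site.trials.get("well_centered")
        wc = (np.ones(len(site.trials), bool) if wc is None
              else wc.to_numpy(bool))
        day_means = {d: site.data[(days == d) & wc].mean(axis=0)
                     for d in uniq}
        snr_pass = {}
        for d in uniq:
            snr = _day_snr(site, days == d, time_ms, cfg)
            ok = snr >= cfg.day_snr_min
            snr_pass[d] = (snr, ok)
        surviving = [d for d in uniq if snr_pass[d][1]]
        corr_pass = {}
        for d in uniq:
            others = [day_means[o] for o in surviving if o != d]
            if not others or not snr_pass[d][1]:
                corr = np.nan
                ok = snr_pass[d][1]
            else:
                ref = np.mean(others, axis=0)
                corr = float(np.corrcoef(day_means[d], ref)[0, 1])
                ok = corr > cfg.day_correlation_min
            corr_pass[d] = (corr, ok)
        included_days = [d for d in uniq
                         if snr_pass[d][1] and corr_pass[d][1]]
        for d in uniq:
            reason = ("" if d in included_days else
                      ("low_snr" if not snr_pass[d][1] else "outlier_day"))
            day_rows.append({"site_id": site.site_id, "day": int(d),
                             "snr": snr_pass[d][0],
                             "correlation": corr_pass[d][0],
                             "included": d in included_days,
                             "reason": reason})

        reasons = []
        if not included_days:
            reasons.append("no_usable_days")
            overall_snr = np.nan
        else:
            sel = np.isin(days, included_days)
            overall_snr = _day_snr(site, sel, time_ms, cfg)
            if overall_snr <= cfg.site_snr_min:
                reasons.append("low_overall_snr")
        dx = dy = np.nan
        if rf_table is not None:
            if site.site_id not in rf_lookup:
                reasons.append("missing_rf")
            else:
                center = None
                if region_centers and site.site_id in region_centers:
                    center = region_centers[site.site_id]
                elif "region_center" in dataset.meta:
                    center = dataset.meta["region_center"]
                elif "region_center" in site.meta:
                    center = site.meta["region_center"]
                if center is None:
                    reasons.append("missing_region_center")
                else:
                    rx, ry = rf_lookup[site.site_id]
                    dx, dy = rx - center[0], ry - center[1]
                    if abs(dx) > cfg.rf_offset_max_x:
                        reasons.append("rf_offset_x")
                    if abs(dy) > cfg.rf_offset_max_y:
                        reasons.append("rf_offset_y")
        included = not reasons
        site_rows.append({"site_id": site.site_id,
                          "overall_snr": overall_snr,
                          "included_days": list(map(int, included_days)),
                          "rf_offset_x": dx, "rf_offset_y": dy,
                          "included": included,
                          "reason": ";".join(reasons)})
        if included:
            sel = np.isin(days, included_days)
            site.data = site.data[sel]
            site.trials = site.trials.loc[sel].reset_index(drop=True)
            kept_sites.append(site)
    out.sites = kept_sites
    report = SiteQCReport(day_table=pd.DataFrame(day_rows),
                          site_table=pd.DataFrame(site_rows),
                          config=cfg)
    return report, out
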