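"""Receptive-field estimation from bar-sweep and grid-flash protocols.

Two mapping protocols are supported:

* **bar sweep** -- a light bar drifts across the screen in the four
  cardinal directions (default speed 15.75 deg/s).  The response time
  course per direction is fitted with a 1-D Gaussian; the RF onset and
  offset borders are the 2.5th and 97.5th percentiles of that Gaussian
  (center +- 1.96 sigma after converting time to space with the bar
  speed), and opposite directions are averaged per axis.  A site's
  SNR_RF (Gaussian peak / across-trial SD of the baseline) must reach 2.
* **grid flash** -- small squares are flashed on a grid (default 21 x 21
  of 1 x 1 deg); the mean response per position is fitted with an
  axis-aligned 2-D Gaussian, and sites with r^2 <= 0.4 are excluded.

RF size conventions: ``fwhm = 2.35 * sigma`` (full width at half
maximum of the Gaussian profile) with the geometric mean of sigma_x and
sigma_y as the scalar sigma; the bar method reports
``size_sqrt_area = sqrt(width_x * width_y)`` of the border rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ReceptiveField", "BarRFModel", "GridRFModel", "RFFitResults",
           "fit_bar_rf", "fit_grid_rf", "aggregate_rf",
           "FWHM_PER_SIGMA", "BORDER_QUANTILE_SIGMA"]

FWHM_PER_SIGMA = 2.35
#: the 2.5/97.5 percentile of a Gaussian sits at +-1.959964... sigma
BORDER_QUANTILE_SIGMA = 1.959963984540054


@dataclass
class ReceptiveField:
    """Fitted receptive field of one recording site."""

    center: tuple[float, float]                 # (x, y), d.v.a.
    sigma: tuple[float, float] | None = None    # 2-D fits
    borders: dict | None = None                 # bar fits: axis -> (lo, hi)
    size_sqrt_area: float | None = None         # bar method
    fit_r2: float | None = None
    snr_rf: float | None = None
    included: bool = True
    reason: str = ""
    site_id: str | None = None
    array_id: str | None = None

    @property
    def sigma_scalar(self) -> float | None:
        if self.sigma is None:
            return None
        return float(np.sqrt(self.sigma[0] * self.sigma[1]))

    @property
    def fwhm(self) -> float | None:
        """Full width at half maximum, defined as 2.35 x sigma."""
        s = self.sigma_scalar
        return None if s is None else FWHM_PER_SIGMA * s

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.center))


def _gauss1d(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_gauss1d(x, y):
    amp0 = float(y.max() - y.min())
    mu0 = float(x[np.argmax(y)])
    sigma0 = max((x.max() - x.min()) / 8.0, 1e-3)
    p0 = [amp0, mu0, sigma0, float(y.min())]
    span = x.max() - x.min()
    bounds = ([-np.inf, x.min() - span, 1e-4, -np.inf],
              [np.inf, x.max() + span, 4 * span, np.inf])
    popt, _ = optimize.curve_fit(_gauss1d, x, y, p0=p0, bounds=bounds,
                                 maxfev=5000)
    res = y - _gauss1d(x, *popt)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1 - np.sum(res ** 2) / sst if sst > 0 else 0.0
    return popt, float(r2)


class BarRFModel:
    """RF model fitted to drifting-bar responses in 4 cardinal directions.

    ``sweeps`` maps direction ('right', 'left', 'up', 'down') to a
    (trials, time) response array; ``positions`` maps direction to the
    bar's coordinate along the motion axis at every sample (d.v.a.),
    computed from the bar speed.  ``baseline_mask`` selects the
    -100-0 ms pre-stimulus samples used for the SNR denominator.
    """

    def __init__(self, sweeps: dict, positions: dict,
                 baseline_mask: np.ndarray, *,
                 latency_correction_ms: float = 0.0,
                 speed_deg_per_s: float = 15.75):
        self.sweeps = sweeps
        self.positions = positions
        self.baseline_mask = np.asarray(baseline_mask, bool)
        self.latency_correction_ms = latency_correction_ms
        self.speed = speed_deg_per_s

    _AXIS = {"right": ("x", +1), "left": ("x", -1),
             "up": ("y", +1), "down": ("y", -1)}

    def fit(self, *, snr_min: float = 2.0) -> ReceptiveField:
        lat_shift = self.latency_correction_ms / 1000.0 * self.speed
        axis_borders = {"x": [], "y": []}
        peaks, r2s = [], []
        base_sds = []
        for direction, data in self.sweeps.items():
            axis, sign = self._AXIS[direction]
            pos = np.asarray(self.positions[direction], float)
            m = data.mean(axis=0)
            sel = ~self.baseline_mask
            popt, r2 = _fit_gauss1d(pos[sel], m[sel])
            amp, mu, sigma, _ = popt
            # the response lags the bar: apparent center is shifted along
            # the motion direction by latency * speed
            mu -= sign * lat_shift
            axis_borders[axis].append(
                (mu - BORDER_QUANTILE_SIGMA * sigma,
                 mu + BORDER_QUANTILE_SIGMA * sigma))
            peaks.append(amp)
            r2s.append(r2)
            base_sds.append(data[:, self.baseline_mask].mean(axis=1)
                            .std(ddof=1))
        borders = {ax: (float(np.mean([b[0] for b in bs])),
                        float(np.mean([b[1] for b in bs])))
                   for ax, bs in axis_borders.items() if bs}
        cx = np.mean(borders["x"]) if "x" in borders else np.nan
        cy = np.mean(borders["y"]) if "y" in borders else np.nan
        widths = [hi - lo for lo, hi in borders.values()]
        size = float(np.sqrt(np.prod(widths))) if len(widths) == 2 else None
        base_sd = float(np.mean(base_sds))
        peak = float(np.mean(peaks))
        snr = peak / base_sd if base_sd > 0 else np.inf
        flagged = (snr < snr_min) or (peak <= 0)
        reason = ("low_snr_rf" if snr < snr_min else
                  "negative_peak" if peak <= 0 else "")
        return ReceptiveField(center=(float(cx), float(cy)), borders=borders,
                              size_sqrt_area=size,
                              fit_r2=float(np.mean(r2s)), snr_rf=float(snr),
                              included=not flagged, reason=reason)


def _gauss2d(xy, amp, x0, y0, sx, sy, offset):
    x, y = xy
    return (offset + amp * np.exp(-0.5 * (((x - x0) / sx) ** 2
                                          + ((y - y0) / sy) ** 2)))


class GridRFModel:
    """Axis-aligned 2-D Gaussian RF model of grid-flash responses.

    ``responses`` is an (n_y, n_x) array of mean responses (0-150 ms
    window) to squares centered at ``xs`` (columns) and ``ys`` (rows).
    """

    def __init__(self, responses: np.ndarray, xs: np.ndarray, ys: np.ndarray):
        self.responses = np.asarray(responses, float)
        self.xs = np.asarray(xs, float)
        self.ys = np.asarray(ys, float)
        if self.responses.shape != (self.ys.size, self.xs.size):
            raise ValueError("responses shape must be (len(ys), len(xs))")

    def fit(self, *, r2_threshold: float = 0.4,
            n_starts: int = 4) -> ReceptiveField:
        X, Y = np.meshgrid(self.xs, self.ys)
        z = self.responses.ravel()
        xy = (X.ravel(), Y.ravel())
        zmin, zmax = float(z.min()), float(z.max())
        i_max = int(np.argmax(z))
        span_x = self.xs.max() - self.xs.min()
        span_y = self.ys.max() - self.ys.min()
        starts = []
        for s in np.linspace(0.5, span_x / 3.0, n_starts):
            starts.append([zmax - zmin, xy[0][i_max], xy[1][i_max],
                           s, s, zmin])
        bounds = ([0, self.xs.min() - span_x, self.ys.min() - span_y,
                   0.05, 0.05, -np.inf],
                  [np.inf, self.xs.max() + span_x, self.ys.max() + span_y,
                   4 * span_x, 4 * span_y, np.inf])
        best = None
        for p0 in starts:
            try:
                popt, _ = optimize.curve_fit(_gauss2d, xy, z, p0=p0,
                                             bounds=bounds, maxfev=5000)
            except RuntimeError:
                continue
            rss = float(np.sum((z - _gauss2d(xy, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt)
        if best is None:
            return ReceptiveField(center=(np.nan, np.nan), included=False,
                                  reason="non_convergence")
        rss, popt = best
        sst = float(np.sum((z - z.mean()) ** 2))
        r2 = 1.0 - rss / sst if sst > 0 else 0.0
        amp, x0, y0, sx, sy, off = popt
        included = r2 > r2_threshold
        return ReceptiveField(center=(float(x0), float(y0)),
                              sigma=(float(sx), float(sy)),
                              fit_r2=float(r2), included=included,
                              reason="" if included else "low_r2")


def fit_bar_rf(sweeps, positions, baseline_mask, **kw) -> ReceptiveField:
    """Fit an RF from bar-sweep responses (see :class:`BarRFModel`)."""
    fit_kw = {k: kw.pop(k) for k in ("snr_min",) if k in kw}
    return BarRFModel(sweeps, positions, baseline_mask, **kw).fit(**fit_kw)


def fit_grid_rf(responses, xs, ys, **kw) -> ReceptiveField:
    """Fit an RF from a grid of mean responses (see :class:`GridRFModel`)."""
    return GridRFModel(responses, xs, ys).fit(**kw)


def aggregate_rf(rfs, *, include_flagged: bool = False) -> ReceptiveField:
    """Average RF centers and sizes of the included sites on one array."""
    use = [rf for rf in rfs if rf.included or include_flagged]
    if not use:
        raise ValueError("no included receptive fields to aggregate")
    cx = float(np.mean([rf.center[0] for rf in use]))
    cy = float(np.mean([rf.center[1] for rf in use]))
    sigmas = [rf.sigma_scalar for rf in use if rf.sigma_scalar is not None]
    sizes = [rf.size_sqrt_area for rf in use
             if rf.size_sqrt_area is not None]
    sigma = (float(np.mean(sigmas)), float(np.mean(sigmas))) if sigmas else None
    return ReceptiveField(center=(cx, cy), sigma=sigma,
                          size_sqrt_area=float(np.mean(sizes)) if sizes
                          else None,
                          included=True)
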