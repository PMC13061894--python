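"""Screen geometry and degree <-> pixel conversions.

Coordinates are expressed in degrees of visual angle (d.v.a.) with the
origin at the screen center, x increasing rightward and y increasing
upward.  Pixel arrays follow image convention (row 0 at the top), so the
y axis is flipped when converting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GeometrySpec", "round_half_away"]


def round_half_away(v):
    """Round half away from zero (symmetric rounding), elementwise."""
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.floor(np.abs(v) + 0.5)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


@dataclass(frozen=True)
class GeometrySpec:
    """Display geometry for stimulus rendering.

    Parameters
    ----------
    screen_size_px : (int, int)
        Screen size as (width, height) in pixels.
    pixels_per_degree : float
        Pixels per degree of visual angle.  The default corresponds to a
        1024-px-wide screen spanning 38.7 d.v.a.
    background_luminance : float
        Luminance of the blank screen, cd/m^2.
    max_luminance : float
        Upper bound of the display range, cd/m^2; rendered images are
        clipped to [0, max_luminance].
    """

    screen_size_px: tuple[int, int] = (1024, 768)
    pixels_per_degree: float = 1024 / 38.7
    background_luminance: float = 46.3
    max_luminance: float = 106.0

    def __post_init__(self):
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")

    @classmethod
    def from_viewing(cls, screen_size_px=(1024, 768), screen_width_cm=37.6,
                     viewing_distance_cm=57.0, **kw):
        """Derive pixels/degree from physical screen width and distance."""
        deg_per_cm = math.degrees(2 * math.atan(0.5 / viewing_distance_cm))
        px_per_cm = screen_size_px[0] / screen_width_cm
        return cls(screen_size_px=tuple(screen_size_px),
                   pixels_per_degree=px_per_cm / deg_per_cm, **kw)

    # -- conversions ------------------------------------------------------
    def deg_to_px(self, deg):
        """Degrees -> pixel count, rounded half away from zero."""
        return round_half_away(np.asarray(deg, float) * self.pixels_per_degree)

    def px_to_deg(self, px):
        return np.asarray(px, float) / self.pixels_per_degree

    def deg_to_px_center(self, x_deg, y_deg):
        """Map a (x, y) position in d.v.a. to fractional (col, row) pixels."""
        cx = (self.screen_size_px[0] - 1) / 2.0
        cy = (self.screen_size_px[1] - 1) / 2.0
        col = cx + np.asarray(x_deg, float) * self.pixels_per_degree
        row = cy - np.asarray(y_deg, float) * self.pixels_per_degree
        return col, row

    def pixel_grid_deg(self, shape, center_deg=(0.0, 0.0)):
        """Return (x, y) d.v.a. coordinates of pixel centers of an array.

        ``shape`` is (n_rows, n_cols); the array is taken to be centered on
        ``center_deg`` in screen coordinates.
        """
        n_rows, n_cols = shape
        ppd = self.pixels_per_degree
        x = (np.arange(n_cols) - (n_cols - 1) / 2.0) / ppd + center_deg[0]
        y = -((np.arange(n_rows) - (n_rows - 1) / 2.0) / ppd) + center_deg[1]
        return x, y
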