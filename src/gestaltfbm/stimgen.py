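"""Gestalt texture strips and luminance-embedded Gabor probes.

A *strip* is a horizontal band of textured regions (white oriented line
elements on a dark background) separated by thin black lines.  Regions
alternate between a "figure" and a "ground" role; the outline of the
figure regions carries one Gestalt cue (symmetry, closure or convexity),
all of them combined, or none (ambiguous strip, straight vertical bands).
Gabor probes are added to the luminance of the underlying texture.

Geometric conventions
---------------------
Screen coordinates are degrees of visual angle (d.v.a.), origin at the
screen center, x rightward and y upward.  A strip's pixel array spans
the full screen width and ``strip_height_deg`` vertically, centered on
``(0, vertical_center_deg)``.  The label array distinguishes screen
background, the black separating lines ("edge") and each figure/ground
region individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from gestaltfbm.exceptions import GeometryError, PlacementError, SpecificationError
from gestaltfbm.geometry import GeometrySpec

__all__ = [
    "StripSpec", "GaborSpec", "StripStimulus", "PlacedScene",
    "render_strip", "embed_gabor", "place_two_strips",
    "audit_labels", "check_cue_properties",
    "LABEL_SCREEN", "LABEL_EDGE", "FIGURE_LABELS", "GROUND_LABELS",
    "UPPER_STRIP_OFFSET",
]

LABEL_SCREEN = 0
LABEL_EDGE = 1
FIGURE_LABELS = (10, 11, 12)
GROUND_LABELS = (20, 21, 22)
#: added to the labels of the upper strip in a composite scene
UPPER_STRIP_OFFSET = 100

CUES = ("symmetry", "closure", "convexity", "all_cues", "ambiguous")

#: versioned outline-family parameters; alternatives can be swapped in by
#: registering a new version.
OUTLINE_VERSION = 1

# per-figure (bulge, vertex offset) of the parabolic boundaries, d.v.a.
# The vertical vertex offset is applied with opposite sign to the left and
# right boundary, which keeps convex figures mirror-asymmetric (convexity
# is tested in isolation) without increasing the bulge: boundary
# excursions stay below 0.5 d.v.a. so an RF on a region center keeps the
# required 2-d.v.a. distance from the nearest boundary.
_CONVEX_BULGES = ((0.50, 1.20), (0.45, -1.10), (0.50, 1.35))
# symmetric barrel bulges for the all-cues condition
_ALLCUE_BULGES = (0.48, 0.42, 0.50)
# per-figure sine-wave boundary parameters (amplitude d.v.a., cycles, phase)
_SYM_WAVES = ((0.45, 1.0, 0.9), (0.50, 2.0, 2.1), (0.40, 1.5, 4.0))
# closure uses independent waves on the two sides of each figure
_CLOSURE_WAVES_L = ((0.40, 1.0, 0.3), (0.35, 2.0, 1.2), (0.45, 1.5, 2.6))
_CLOSURE_WAVES_R = ((0.35, 2.0, 4.1), (0.45, 1.0, 5.0), (0.30, 2.5, 0.7))


@dataclass(frozen=True)
class StripSpec:
    """Specification of one textured Gestalt strip.

    ``n_regions`` alternating figure/ground regions of mean width
    ``region_width_deg`` are separated by black lines of width
    ``edge_width_deg``.  The texture consists of white line elements of
    the given thickness/length with orientation 45 or 135 deg,
    alternating by 90 deg between adjacent regions.
    """

    cue: str = "ambiguous"
    n_regions: int = 6
    region_width_deg: float = 5.0
    strip_height_deg: float = 7.0
    edge_width_deg: float = 0.2
    line_thickness_deg: float = 0.04
    line_length_deg: float = 0.8
    orientations_deg: tuple[float, float] = (45.0, 135.0)
    horizontal_shift_deg: float = 0.0
    vertical_center_deg: float = -6.23
    texture_background_luminance: float = 10.0
    line_luminance: float = 74.0
    element_min_spacing_deg: float = 0.42
    outline_version: int = OUTLINE_VERSION

    def __post_init__(self):
        if self.cue not in CUES:
            raise SpecificationError(
                f"unknown cue {self.cue!r}; expected one of {CUES}")
        if self.n_regions % 2 != 0 or self.n_regions < 2:
            raise SpecificationError("n_regions must be a positive even number")
        if self.outline_version != OUTLINE_VERSION:
            raise SpecificationError(
                f"unknown outline version {self.outline_version}")

    @property
    def n_figures(self) -> int:
        return self.n_regions // 2

    def region_role(self, region_index: int) -> str:
        """Figure regions sit at even indices, ground regions at odd ones."""
        return "figure" if region_index % 2 == 0 else "ground"

    def region_label(self, region_index: int) -> int:
        pair = region_index // 2
        return (FIGURE_LABELS[pair] if region_index % 2 == 0
                else GROUND_LABELS[pair])


@dataclass(frozen=True)
class GaborSpec:
    """A vertical Gabor probe added to the luminance of the texture."""

    spatial_frequency: float = 3.0          # cycles/degree
    gaussian_sd_deg: float = 0.33
    aperture_deg: float = 2.0
    michelson_contrast: float = 0.3         # signed; |c| <= 1
    mean_luminance: float = 30.0            # cd/m^2
    center_deg: tuple[float, float] = (0.0, -6.23)

    def __post_init__(self):
        if abs(self.michelson_contrast) > 1:
            raise SpecificationError("|michelson_contrast| must be <= 1")


@dataclass
class StripStimulus:
    """Rendered strip: luminance image + congruent integer label array."""

    image: np.ndarray              # (rows, cols) luminance, cd/m^2
    labels: np.ndarray             # (rows, cols) int codes
    spec: StripSpec
    geometry: GeometrySpec
    center_deg: tuple[float, float]
    seed: int | None = None

    def local_grid_deg(self):
        """(x, y) d.v.a. coordinates of the pixel centers of this strip."""
        return self.geometry.pixel_grid_deg(self.image.shape, self.center_deg)


# --------------------------------------------------------------------------
# Region boundary curves


def _boundary_devs(spec: StripSpec, y: np.ndarray) -> np.ndarray:
    """Deviation of every region boundary from its straight-band position.

    Returns an array of shape ``(len(y), n_regions + 1)`` in d.v.a.;
    ``y`` is measured relative to the strip's vertical center.
    """
    n_b = spec.n_regions + 1
    h = spec.strip_height_deg
    dev = np.zeros((y.size, n_b))
    parab = 1.0 - (2.0 * y / h) ** 2      # 0 at strip edges, 1 at center

    def parab_off(delta):
        return 1.0 - (2.0 * (y - delta) / h) ** 2

    def wave(params):
        a, n, phi = params
        return a * np.sin(2 * np.pi * n * (y / h) + phi)

    for f in range(spec.n_figures):
        left_b, right_b = 2 * f, 2 * f + 1   # boundaries flanking figure f
        if spec.cue == "convexity":
            b, delta = _CONVEX_BULGES[f % 3]
            dev[:, left_b] = -b * parab_off(+delta)
            dev[:, right_b] = +b * parab_off(-delta)
        elif spec.cue == "all_cues":
            b = _ALLCUE_BULGES[f % 3]
            dev[:, left_b] = -b * parab
            dev[:, right_b] = +b * parab
        elif spec.cue == "symmetry":
            w = wave(_SYM_WAVES[f % 3])
            dev[:, left_b] = +w
            dev[:, right_b] = -w
        elif spec.cue == "closure":
            dev[:, left_b] = wave(_CLOSURE_WAVES_L[f % 3])
            dev[:, right_b] = wave(_CLOSURE_WAVES_R[f % 3])
        # ambiguous: straight bands, dev stays 0
    return dev


def _boundary_positions(spec: StripSpec, y: np.ndarray) -> np.ndarray:
    """Boundary x positions (d.v.a., screen frame) per row; (len(y), n_b)."""
    extent = spec.n_regions * spec.region_width_deg
    base = (np.arange(spec.n_regions + 1) * spec.region_width_deg
            - extent / 2.0 + spec.horizontal_shift_deg)
    return base[None, :] + _boundary_devs(spec, np.asarray(y, float))


def _has_caps(spec: StripSpec) -> bool:
    return spec.cue in ("closure", "all_cues")


def _compute_labels(spec: StripSpec, x: np.ndarray, y_local: np.ndarray):
    """Label array for pixel-center coordinates ``x`` (cols) x ``y`` (rows)."""
    e2 = spec.edge_width_deg / 2.0
    xb = _boundary_positions(spec, y_local)           # (rows, n_b)
    labels = np.full((y_local.size, x.size), LABEL_SCREEN, dtype=np.int16)

    # region index per pixel (vectorized searchsorted row by row)
    region = np.empty_like(labels)
    for i in range(y_local.size):
        region[i] = np.searchsorted(xb[i], x) - 1
    inside = (region >= 0) & (region < spec.n_regions)
    for r in range(spec.n_regions):
        labels[inside & (region == r)] = spec.region_label(r)

    # black separating lines
    edge = np.zeros_like(labels, dtype=bool)
    for j in range(xb.shape[1]):
        edge |= np.abs(x[None, :] - xb[:, j][:, None]) < e2

    # closure caps: horizontal lines at strip top/bottom across figures
    if _has_caps(spec):
        h2 = spec.strip_height_deg / 2.0
        cap_rows = (np.abs(y_local) > h2 - spec.edge_width_deg)[:, None]
        fig_cols = np.zeros_like(labels, dtype=bool)
        for f in range(spec.n_figures):
            lo = xb[:, 2 * f][:, None] - e2
            hi = xb[:, 2 * f + 1][:, None] + e2
            fig_cols |= (x[None, :] >= lo) & (x[None, :] <= hi)
        edge |= cap_rows & fig_cols

    labels[edge] = LABEL_EDGE
    return labels


# --------------------------------------------------------------------------
# Texture synthesis


def _poisson_disc(rng, width, height, r, k=20):
    """Bridson Poisson-disc sampling on a width x height rectangle."""
    cell = r / np.sqrt(2.0)
    gw, gh = int(np.ceil(width / cell)), int(np.ceil(height / cell))
    grid = -np.ones((gh, gw), dtype=int)
    pts = []
    active = []

    def fits(p):
        gx, gy = int(p[0] / cell), int(p[1] / cell)
        x0, x1 = max(gx - 2, 0), min(gx + 3, gw)
        y0, y1 = max(gy - 2, 0), min(gy + 3, gh)
        idx = grid[y0:y1, x0:x1]
        idx = idx[idx >= 0]
        if idx.size == 0:
            return True
        q = np.asarray([pts[i] for i in idx])
        return np.all(np.hypot(q[:, 0] - p[0], q[:, 1] - p[1]) >= r)

    def insert(p):
        pts.append(p)
        active.append(len(pts) - 1)
        grid[int(p[1] / cell), int(p[0] / cell)] = len(pts) - 1

    insert((rng.uniform(0, width), rng.uniform(0, height)))
    while active:
        i = active[rng.integers(len(active))]
        base = pts[i]
        for _ in range(k):
            rad = rng.uniform(r, 2 * r)
            ang = rng.uniform(0, 2 * np.pi)
            p = (base[0] + rad * np.cos(ang), base[1] + rad * np.sin(ang))
            if 0 <= p[0] < width and 0 <= p[1] < height and fits(p):
                insert(p)
                break
        else:
            active.remove(i)
    return np.asarray(pts)


def _draw_segment(img, mask, x, y, x0, y0, theta_deg, length, thick, value):
    """Paint a line segment onto ``img`` where ``mask`` is True.

    Coordinates are d.v.a.; ``x``/``y`` are the axis coordinate vectors of
    the (rows, cols) arrays.
    """
    th = np.deg2rad(theta_deg)
    dx, dy = np.cos(th), np.sin(th)
    half = length / 2.0
    pad = half + thick
    c0 = np.searchsorted(x, x0 - pad)
    c1 = np.searchsorted(x, x0 + pad) + 1
    # y is descending (image convention)
    r0 = np.searchsorted(-y, -(y0 + pad))
    r1 = np.searchsorted(-y, -(y0 - pad)) + 1
    if c0 >= c1 or r0 >= r1:
        return
    xs = x[c0:c1][None, :] - x0
    ys = y[r0:r1][:, None] - y0
    t = np.clip(xs * dx + ys * dy, -half, half)
    d2 = (xs - t * dx) ** 2 + (ys - t * dy) ** 2
    hit = (d2 <= (thick / 2.0) ** 2) & mask[r0:r1, c0:c1]
    img[r0:r1, c0:c1][hit] = value


# --------------------------------------------------------------------------
# Public operations


def render_strip(spec: StripSpec, geometry: GeometrySpec,
                 seed: int = 0) -> StripStimulus:
    """Render a textured Gestalt strip.

    The luminance image is rendered on a 2x supersampled grid and box
    downsampled (this anti-aliases the thin 0.04-deg texture lines); the
    label array is computed analytically at the output resolution.
    Texture element placement uses seeded Poisson-disc sampling, so two
    calls with identical ``(spec, seed)`` are bit-identical.
    """
    ppd = geometry.pixels_per_degree
    n_rows = int(round(spec.strip_height_deg * ppd))
    n_cols = geometry.screen_size_px[0]
    extent = spec.n_regions * spec.region_width_deg + spec.edge_width_deg
    if extent + 2 * abs(spec.horizontal_shift_deg) > n_cols / ppd + 1e-9:
        raise GeometryError("strip regions exceed the screen width")
    if spec.strip_height_deg * ppd > geometry.screen_size_px[1]:
        raise GeometryError("strip exceeds the screen height")

    center = (0.0, spec.vertical_center_deg)
    # output-resolution grid (screen frame) and local y relative to center
    x, y = geometry.pixel_grid_deg((n_rows, n_cols), center)
    labels = _compute_labels(spec, x, y - center[1])

    # supersampled grid for the luminance image
    ss = 2
    xs_, ys_ = GeometrySpec(
        screen_size_px=(n_cols * ss, n_rows * ss),
        pixels_per_degree=ppd * ss,
        background_luminance=geometry.background_luminance,
        max_luminance=geometry.max_luminance,
    ).pixel_grid_deg((n_rows * ss, n_cols * ss), center)
    labels_ss = _compute_labels(spec, xs_, ys_ - center[1])

    img = np.full(labels_ss.shape, geometry.background_luminance)
    img[labels_ss == LABEL_EDGE] = 0.0
    in_region = labels_ss >= FIGURE_LABELS[0]
    img[in_region] = spec.texture_background_luminance

    # texture elements: Poisson-disc centers over the region extent
    rng = np.random.default_rng(seed)
    x0 = -extent / 2.0 + spec.horizontal_shift_deg
    pts = _poisson_disc(rng, extent, spec.strip_height_deg,
                        spec.element_min_spacing_deg)
    half_h = spec.strip_height_deg / 2.0
    for px, py in pts:
        gx = x0 + px
        gy = center[1] - half_h + py
        # orientation is set by the region the element's center falls in
        xb = _boundary_positions(spec, np.asarray([gy - center[1]]))[0]
        r = int(np.searchsorted(xb, gx)) - 1
        if r < 0 or r >= spec.n_regions:
            continue
        lab = spec.region_label(r)
        ori = spec.orientations_deg[r % 2]
        # clip the element to its own region (elements never cross edges)
        _draw_segment(img, labels_ss == lab, xs_, ys_, gx, gy, ori,
                      spec.line_length_deg, spec.line_thickness_deg,
                      spec.line_luminance)

    image = img.reshape(n_rows, ss, n_cols, ss).mean(axis=(1, 3))
    return StripStimulus(image=image, labels=labels, spec=spec,
                         geometry=geometry, center_deg=center, seed=seed)


def _gabor_patch(gabor: GaborSpec, x, y):
    """Calibrated additive Gabor luminance modulation on the (x, y) grid.

    The modulation amplitude is rescaled so that, added to a uniform
    field at ``mean_luminance``, the rendered patch's measured Michelson
    contrast (Lmax - Lmin)/(Lmax + Lmin) equals ``|michelson_contrast|``
    exactly; the sign of the contrast gives the sign of the modulation,
    which makes embedding an exact signed inverse.
    """
    cx, cy = gabor.center_deg
    xs = x[None, :] - cx
    ys = y[:, None] - cy
    r2 = xs ** 2 + ys ** 2
    env = np.exp(-r2 / (2.0 * gabor.gaussian_sd_deg ** 2))
    env[r2 > (gabor.aperture_deg / 2.0) ** 2] = 0.0
    carrier = np.cos(2 * np.pi * gabor.spatial_frequency * xs)
    g = env * carrier
    c = abs(gabor.michelson_contrast)
    if c == 0 or not np.any(g):
        return np.zeros_like(g)
    hi, lo = g.max(), g.min()
    L0 = gabor.mean_luminance
    # scale s solves (s(hi-lo)) / (2 L0 + s(hi+lo)) = c
    s = 2.0 * L0 * c / ((hi - lo) - c * (hi + lo))
    return np.sign(gabor.michelson_contrast) * s * g


def embed_gabor(strip: StripStimulus, gabor: GaborSpec, *,
                clip: bool = True) -> StripStimulus:
    """Add a Gabor probe to the luminance of the underlying texture.

    Pixels outside the aperture and the label array are unchanged.  With
    ``clip=True`` the result is clipped to the display range and a
    warning is emitted if more than 0.1% of aperture pixels clip; with
    ``clip=False`` the operation is an exact signed inverse
    (embedding ``-c`` after ``+c`` reconstructs the input bit for bit).
    """
    x, y = strip.local_grid_deg()
    cx, cy = gabor.center_deg
    half = gabor.aperture_deg / 2.0
    if (cx - half < x[0] or cx + half > x[-1]
            or cy + half > y[0] or cy - half < y[-1]):
        raise GeometryError("Gabor aperture exceeds the strip bounds")
    patch = _gabor_patch(gabor, x, y)
    image = strip.image + patch
    if clip:
        clipped = (image < 0) | (image > strip.geometry.max_luminance)
        in_ap = patch != 0
        if in_ap.any() and clipped[in_ap].mean() > 1e-3:
            warnings.warn(
                f"{clipped[in_ap].mean():.1%} of aperture pixels clipped "
                "to the display range", stacklevel=2)
        image = np.clip(image, 0.0, strip.geometry.max_luminance)
    return StripStimulus(image=image, labels=strip.labels, spec=strip.spec,
                         geometry=strip.geometry, center_deg=strip.center_deg,
                         seed=strip.seed)


@dataclass
class PlacedScene:
    """Composite of two strips on the full screen, plus placement metadata."""

    image: np.ndarray
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)


def _paste(canvas, canvas_labels, strip, center_y, shift_x, geometry,
           label_offset=0):
    rows, cols = strip.image.shape
    _, row_c = geometry.deg_to_px_center(0.0, center_y)
    r0 = int(round(row_c - (rows - 1) / 2.0))
    c_shift = int(round(shift_x * geometry.pixels_per_degree))
    if r0 < 0 or r0 + rows > canvas.shape[0]:
        raise GeometryError("strip placement exceeds the screen")
    img = strip.image
    lab = strip.labels
    if c_shift:
        img = np.roll(img, c_shift, axis=1)
        lab = np.roll(lab, c_shift, axis=1)
    canvas[r0:r0 + rows] = img
    lab = lab.copy()
    lab[lab != LABEL_SCREEN] += label_offset
    canvas_labels[r0:r0 + rows] = lab
    return r0


def place_two_strips(fig_strip: StripStimulus, amb_strip: StripStimulus,
                     rf_center: tuple[float, float],
                     geometry: GeometrySpec, *,
                     target_region: int = 2,
                     horizontal_offset_deg: float = 1.5,
                     swap: bool = False,
                     min_boundary_distance_deg: float = 2.0,
                     min_offset_deg: float = 0.25) -> PlacedScene:
    """Compose the figure-background and ambiguous strips around fixation.

    The lower strip is positioned so that the center of region
    ``target_region`` covers ``rf_center``; the other strip mirrors it
    above fixation, displaced horizontally by ``horizontal_offset_deg``
    to break the vertical alignment of region boundaries.  ``swap``
    places the figure-background strip in the upper position instead of
    the lower one.
    """
    if rf_center[1] >= 0:
        raise PlacementError("rf_center must lie in the lower visual field")
    lower, upper = (amb_strip, fig_strip) if swap else (fig_strip, amb_strip)
    spec = lower.spec
    if not 0 <= target_region < spec.n_regions:
        raise PlacementError("target_region out of range")

    # horizontal shift of the lower strip that centers the target region
    xb0 = _boundary_positions(spec, np.asarray([0.0]))[0]
    region_cx = 0.5 * (xb0[target_region] + xb0[target_region + 1])
    shift_lower = rf_center[0] - region_cx

    # anti-alignment rule: the two strips' base boundary grids must be
    # offset (deviated outlines still share the straight-band grid period)
    shift_upper = shift_lower + horizontal_offset_deg
    period = spec.region_width_deg
    base_lower = (-spec.n_regions * spec.region_width_deg / 2.0
                  + spec.horizontal_shift_deg + shift_lower)
    u = upper.spec
    base_upper = (-u.n_regions * u.region_width_deg / 2.0
                  + u.horizontal_shift_deg + shift_upper)
    rel = base_upper - base_lower
    misalign = np.abs((rel + period / 2) % period - period / 2)
    if misalign < min_offset_deg:
        raise PlacementError(
            "region boundaries of the two strips align vertically; use a "
            "nonzero horizontal offset")

    # RF-to-boundary distance at the RF's vertical position
    xb_rf = (_boundary_positions(spec, np.asarray([0.0]))[0] + shift_lower)
    dist = np.min(np.abs(xb_rf - rf_center[0]))
    if dist < min_boundary_distance_deg:
        raise PlacementError(
            f"RF center is {dist:.2f} d.v.a. from the nearest region "
            f"boundary (minimum {min_boundary_distance_deg})")

    w, h = geometry.screen_size_px
    canvas = np.full((h, w), geometry.background_luminance)
    canvas_labels = np.full((h, w), LABEL_SCREEN, dtype=np.int16)
    _paste(canvas, canvas_labels, lower, rf_center[1], shift_lower, geometry)
    _paste(canvas, canvas_labels, upper, -rf_center[1], shift_upper, geometry,
           label_offset=UPPER_STRIP_OFFSET)

    region_centers = 0.5 * (xb0[:-1] + xb0[1:]) + shift_lower
    meta = {
        "lower_strip": "ambiguous" if swap else "figure_background",
        "upper_strip": "figure_background" if swap else "ambiguous",
        "target_region": target_region,
        "target_region_center_deg": (float(region_centers[target_region]),
                                     float(rf_center[1])),
        "region_centers_x_deg": region_centers.tolist(),
        "lower_center_deg": (float(shift_lower), float(rf_center[1])),
        "upper_center_deg": (float(shift_upper), float(-rf_center[1])),
        "horizontal_offset_deg": float(horizontal_offset_deg),
        "rf_center_deg": tuple(map(float, rf_center)),
        "rf_boundary_distance_deg": float(dist),
    }
    return PlacedScene(image=canvas, labels=canvas_labels, metadata=meta)


# --------------------------------------------------------------------------
# Label audits and cue-property oracles


def audit_labels(stim: StripStimulus, *, tol_luminance: float = 3.0) -> dict:
    """Consistency audit of a rendered stimulus.

    Checks that every figure/ground region has pixels, that differently
    labelled texture regions are always separated by an edge line (no
    figure pixel is 4-adjacent to a ground pixel), and that figure and
    ground textures have equal mean luminance up to placement noise.
    """
    lab = stim.labels
    spec = stim.spec
    counts = {spec.region_label(r): int((lab == spec.region_label(r)).sum())
              for r in range(spec.n_regions)}
    fig = np.isin(lab, FIGURE_LABELS)
    gnd = np.isin(lab, GROUND_LABELS)
    adjacent = bool(np.any(fig[1:] & gnd[:-1]) or np.any(fig[:-1] & gnd[1:])
                    or np.any(fig[:, 1:] & gnd[:, :-1])
                    or np.any(fig[:, :-1] & gnd[:, 1:]))
    mean_fig = float(stim.image[fig].mean()) if fig.any() else np.nan
    mean_gnd = float(stim.image[gnd].mean()) if gnd.any() else np.nan
    return {
        "region_pixel_counts": counts,
        "all_regions_nonempty": all(v > 0 for v in counts.values()),
        "edge_separates_regions": not adjacent,
        "mean_luminance_figure": mean_fig,
        "mean_luminance_ground": mean_gnd,
        "luminance_balanced": abs(mean_fig - mean_gnd) < tol_luminance,
    }


def _region_mask(stim: StripStimulus, region_index: int) -> np.ndarray:
    return stim.labels == stim.spec.region_label(region_index)


def _mask_symmetry_score(mask: np.ndarray) -> float:
    """IoU of a mask with its mirror about the vertical centroid axis."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.nan
    c = cols.mean()
    mcols = np.rint(2 * c - cols).astype(int)
    ok = (mcols >= 0) & (mcols < mask.shape[1])
    mirrored = np.zeros_like(mask)
    mirrored[rows[ok], mcols[ok]] = True
    inter = np.logical_and(mask, mirrored).sum()
    union = np.logical_or(mask, mirrored).sum()
    return float(inter) / float(union)


def _mask_convexity_score(mask: np.ndarray) -> float:
    """Area of the mask divided by the area of its convex hull."""
    from matplotlib.path import Path
    from scipy.spatial import ConvexHull

    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows]).astype(float)
    if len(pts) < 3:
        return np.nan
    hull = ConvexHull(pts)
    path = Path(pts[hull.vertices])
    rmin, rmax = rows.min(), rows.max()
    cmin, cmax = cols.min(), cols.max()
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    inside = path.contains_points(
        np.column_stack([cc.ravel(), rr.ravel()]), radius=0.5)
    hull_area = float(inside.sum())
    return float(mask.sum()) / hull_area if hull_area else np.nan


def _mask_is_closed(stim: StripStimulus, mask: np.ndarray) -> bool:
    """True if every pixel bordering the mask from outside is an edge pixel.

    A region whose boundary touches the strip's top or bottom row (or any
    non-edge label) has an open contour.
    """
    lab = stim.labels
    padded = np.pad(mask, 1)
    lab_padded = np.pad(lab, 1, constant_values=LABEL_SCREEN)
    border = np.zeros_like(padded)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        border |= np.roll(padded, sh, axis=ax)
    border &= ~padded
    return bool(np.all(lab_padded[border] == LABEL_EDGE))


def _mask_is_straight_band(mask: np.ndarray, tol_px: float = 1.5) -> bool:
    left = np.array([np.argmax(row) for row in mask if row.any()], float)
    if left.size == 0:
        return False
    return float(left.max() - left.min()) <= tol_px


def check_cue_properties(stim: StripStimulus, *,
                         symmetry_threshold: float = 0.95,
                         convexity_threshold: float = 0.97) -> dict:
    """Independent geometric oracle for the cue-defining outline properties.

    For every figure and ground region the checker reports whether the
    region is mirror-symmetric about its vertical axis, convex (area /
    convex-hull area above threshold), enclosed by a closed black
    contour, and a straight vertical band.
    """
    spec = stim.spec
    out = {"cue": spec.cue, "figure": [], "ground": []}
    for r in range(spec.n_regions):
        mask = _region_mask(stim, r)
        rec = {
            "region": r,
            "symmetric": _mask_symmetry_score(mask) >= symmetry_threshold,
            "symmetry_score": _mask_symmetry_score(mask),
            "convex": _mask_convexity_score(mask) >= convexity_threshold,
            "convexity_score": _mask_convexity_score(mask),
            "closed": _mask_is_closed(stim, mask),
            "straight_band": _mask_is_straight_band(mask),
        }
        out[spec.region_role(r)].append(rec)
    return out
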