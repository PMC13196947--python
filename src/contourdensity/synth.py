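"""Synthetic agricultural scenes for end-to-end testing.

Real inputs to the pipeline are cropland mosaics: contiguous fields of
distinct mean reflectance separated by sharp boundaries, threaded by linear
features (field roads, shelterbelts, canals).  The generator emulates
exactly that — a Voronoi mosaic of fields plus contrasting 1–2 px lines —
and two processes that act on it between acquisition dates:

* *structural degradation* (``degrade_scene``): a convex blend of the scene
  with a heavily smoothed copy, plus erasure of a fraction of the linear
  features.  This removes boundary contrast while barely moving the mean
  reflectance, mimicking abandonment, where spectral signatures stay stable
  while structure simplifies.
* *radiometric perturbation* (``perturb_radiometry``): a global
  multiplicative gain plus additive Gaussian noise, mimicking acquisition-
  condition differences between dates (the thing the correction factor k is
  designed to undo).

All three operations are bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon, box

from .raster import ReflectanceRaster

__all__ = [
    "SceneConfig",
    "generate_mosaic",
    "two_field_scene",
    "degrade_scene",
    "degradation_profile",
    "perturb_radiometry",
    "default_layout",
]

_SCENE_CRS = 32636                 # UTM 36N, a projected CRS in meters
_SCENE_ORIGIN = (400_000.0, 5_300_000.0)


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the synthetic mosaic generator.

    grid_size : pixels per side (default 512 -> 5.12 km at 10 m)
    pixel_size_m : ground sampling distance, meters (10, Sentinel-2-like)
    n_fields : Voronoi cells in the mosaic (150 -> fields ~400 m wide)
    reflectance_range : (low, high) for field mean reflectance; (0.05, 0.45)
        spans bare soil to bright senescent vegetation in a red band while
        leaving headroom so that global gains up to 2 stay below saturation
    boundary_linear_features : roads/shelterbelts per km^2 (1.0)
    settlements_per_km2 : village clusters per km^2 (0.15, one per ~2.5 km grid)
    noise_sd : additive Gaussian noise sd in reflectance units (0.01)
    degradation_d : boundary-blurring fraction in [0, 1] (0 = intact)
    gain : global multiplicative radiometric factor (1.0)
    seed : RNG seed; identical config + seed -> bit-identical scene
    """

    grid_size: int = 512
    pixel_size_m: float = 10.0
    n_fields: int = 150
    reflectance_range: tuple[float, float] = (0.05, 0.45)
    boundary_linear_features: float = 1.0
    settlements_per_km2: float = 0.15
    noise_sd: float = 0.01
    degradation_d: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.degradation_d <= 1:
            raise ValueError("degradation_d must be in [0, 1]")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_fields < 2:
            raise ValueError("need at least 2 fields")
        if self.grid_size < 64:
            raise ValueError("grid_size below 64 px gives no usable mosaic")


def _rasterize_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, label: int, width: int) -> None:
    """Mark pixels along segment p0->p1 (pixel coordinates, row/col) in place."""
    length = float(np.hypot(*(p1 - p0)))
    steps = max(int(length * 3), 2)
    t = np.linspace(0.0, 1.0, steps)
    pts = p0[None, :] * (1 - t[:, None]) + p1[None, :] * t[:, None]
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[1] - 1)
    mask[rows, cols] = label
    if width > 1:
        mask[np.clip(rows + 1, 0, mask.shape[0] - 1), cols] = label


def generate_mosaic(c: SceneConfig) -> ReflectanceRaster:
    """Generate a georeferenced field mosaic per the configuration.

    Voronoi cells around random seed points are filled with field means
    drawn from ``reflectance_range``; contrasting 1–2 px linear features are
    overlaid at the configured density; the global gain and additive noise
    are applied and the result clipped to [0, 1].  The labeled feature
    raster rides along in ``meta["linear_features"]`` so the degradation
    operator can erase features selectively.
    """
    rng = np.random.default_rng(c.seed)
    n = c.grid_size
    seeds = rng.uniform(0, n, size=(c.n_fields, 2))
    # red-band field reflectance is strongly bimodal: dark closed vegetation
    # vs bright bare/senescent soil; draw a two-class mixture with jitter so
    # adjacent fields are distinct and many boundaries are high-contrast
    lo, hi = c.reflectance_range
    cls = rng.integers(0, 2, size=c.n_fields)
    jitter = rng.normal(0.0, 0.12 * (hi - lo), size=c.n_fields)
    means = np.clip(np.where(cls == 0, lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo)) + jitter, lo, hi)
    # clipping can collide two fields on exactly lo/hi, which would merge
    # adjacent cells into one region; a sub-noise offset keeps means distinct
    means += np.arange(c.n_fields) * 1e-9
    rows, cols = np.mgrid[0:n, 0:n]
    pix = np.column_stack([rows.ravel() + 0.5, cols.ravel() + 0.5])
    _, labels = cKDTree(seeds).query(pix)
    values = means[labels].reshape(n, n)

    area_km2 = (n * c.pixel_size_m / 1000.0) ** 2
    n_lines = int(round(c.boundary_linear_features * area_km2))
    feature_labels = np.zeros((n, n), dtype=np.int32)
    # linear features emulate the shelterbelt/road grid of steppe agriculture:
    # full-span lines in near-axis orientations at jittered positions, so the
    # feature network stays connected across the scene
    for i in range(n_lines):
        horizontal = bool(rng.integers(0, 2))
        pos = rng.uniform(0, n)
        tilt = rng.uniform(-0.15 * n, 0.15 * n)
        if horizontal:
            p0, p1 = np.array([pos - tilt, -1.0]), np.array([pos + tilt, float(n)])
        else:
            p0, p1 = np.array([-1.0, pos - tilt]), np.array([float(n), pos + tilt])
        width = int(rng.integers(1, 3))
        _rasterize_segment(feature_labels, p0, p1, i + 1, width)
    # dark shelterbelts/canals dominate; occasional bright bare tracks — both
    # at the same contrast scale as field boundaries so no single feature
    # class owns the gradient maximum
    feature_vals = np.where(rng.random(n_lines + 1) < 0.8, lo, hi)
    on_feature = feature_labels > 0
    values = np.where(on_feature, feature_vals[feature_labels], values)

    # settlements: compact clusters of small high-contrast blocks (roofs,
    # yards) every few km, as in steppe agricultural regions; they are not
    # linear features and are not erased by degradation, only blurred
    n_villages = int(round(c.settlements_per_km2 * area_km2))
    for _ in range(n_villages):
        cr, cc = rng.uniform(0.1 * n, 0.9 * n, size=2)
        for _ in range(int(rng.integers(8, 16))):
            br = int(cr + rng.normal(0, 0.015 * n))
            bc = int(cc + rng.normal(0, 0.015 * n))
            h, w = rng.integers(2, 5, size=2)
            val = lo if rng.random() < 0.5 else hi
            r0, r1 = np.clip([br, br + h], 0, n)
            c0, c1 = np.clip([bc, bc + w], 0, n)
            values[r0:r1, c0:c1] = val

    values = values * c.gain
    if c.noise_sd > 0:
        values = values + rng.normal(0.0, c.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)

    r = ReflectanceRaster(
        values=values,
        valid_mask=np.ones((n, n), dtype=bool),
        pixel_size=(c.pixel_size_m, c.pixel_size_m),
        crs_id=_SCENE_CRS,
        origin=_SCENE_ORIGIN,
        acquisition_label=f"synthetic-seed{c.seed}",
    )
    r.meta["linear_features"] = feature_labels
    r.meta["config"] = c
    return r


def two_field_scene(
    grid_size: int = 128,
    pixel_size_m: float = 10.0,
    low: float = 0.1,
    high: float = 0.4,
) -> ReflectanceRaster:
    """Two fields split by a sharp vertical boundary at mid-grid (noise-free)."""
    values = np.full((grid_size, grid_size), low)
    values[:, grid_size // 2 :] = high
    return ReflectanceRaster(
        values=values,
        valid_mask=np.ones((grid_size, grid_size), dtype=bool),
        pixel_size=(pixel_size_m, pixel_size_m),
        crs_id=_SCENE_CRS,
        origin=_SCENE_ORIGIN,
        acquisition_label="two-field",
    )


def degrade_scene(
    r: ReflectanceRaster,
    d: float | np.ndarray,
    seed: int = 0,
    blur_sigma: float = 8.0,
) -> ReflectanceRaster:
    """Structural degradation: blur-blend boundaries and erase linear features.

    ``out = (1 - d) * r + d * blur(r, blur_sigma)`` with ``d`` a scalar or a
    per-pixel field in [0, 1]; additionally a fraction ``mean(d)`` of the
    scene's linear features (if the raster carries them) is replaced by the
    blurred background.  ``d = 0`` is the identity; ``d = 1`` removes all
    step edges beyond the blur scale.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0) or np.any(d_arr > 1):
        raise ValueError("degradation fraction must lie in [0, 1]")
    if d_arr.ndim == 0 and float(d_arr) == 0.0:
        out = r.with_values(r.values.copy())
        out.meta.update(r.meta)
        return out
    blurred = ndimage.gaussian_filter(r.values, blur_sigma, mode="reflect")
    values = (1.0 - d_arr) * r.values + d_arr * blurred

    features = r.meta.get("linear_features")
    remaining = features
    if features is not None and features.max() > 0:
        rng = np.random.default_rng(seed)
        n_ids = int(features.max())
        # feature i is erased wherever the local degradation fraction
        # exceeds its per-feature resilience draw u_i: erasure is local,
        # nested in d (a trajectory of increasing d only loses features),
        # and for scalar d the expected erased fraction is d
        resilience = rng.uniform(size=n_ids + 1)
        resilience[0] = np.inf  # background is never a feature
        wipe = (features > 0) & (np.broadcast_to(d_arr, features.shape) > resilience[features])
        if wipe.any():
            values = np.where(wipe, blurred, values)
            remaining = np.where(wipe, 0, features)
    out = r.with_values(values)
    if remaining is not None:
        out.meta["linear_features"] = remaining
    return out


def degradation_profile(
    r: ReflectanceRaster,
    line: LineString,
    max_d: float = 0.9,
    scale_m: float = 1500.0,
) -> np.ndarray:
    """Per-pixel degradation fraction decaying with distance from a line.

    ``d(x) = max_d * exp(-dist(x, line) / scale_m)`` — the spatial pattern
    of conflict-driven abandonment: strongest at the frontline, fading with
    distance.  Feed the result to :func:`degrade_scene`.
    """
    x, y = r.pixel_centers()
    xx, yy = np.meshgrid(x, y)
    pts = shapely.points(xx.ravel(), yy.ravel())
    dist = shapely.distance(pts, line).reshape(r.shape)
    return max_d * np.exp(-dist / scale_m)


def perturb_radiometry(
    r: ReflectanceRaster, gain: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> ReflectanceRaster:
    """Apply a global radiometric gain and fresh additive noise, clipped to [0, 1]."""
    if gain <= 0:
        raise ValueError("gain must be > 0")
    values = r.values * gain
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    out = r.with_values(np.clip(values, 0.0, 1.0))
    out.meta.update(r.meta)
    return out


def default_layout(
    r: ReflectanceRaster, buffer_width_m: float | None = None
) -> tuple[Polygon, LineString]:
    """Study-area polygon and a central horizontal frontline for a scene.

    The study area is the raster footprint; the line crosses it west–east
    through the center.  The default buffer half-width is an eighth of the
    north–south extent, scaling the 3-zone layout down to fixture size.
    """
    nrow, ncol = r.shape
    px, py = r.pixel_size
    x0, y0 = r.origin
    x1, y1 = x0 + ncol * px, y0 - nrow * py
    study_area = box(x0, min(y0, y1), x1, max(y0, y1))
    mid_y = (y0 + y1) / 2.0
    line = LineString([(x0 - px, mid_y), (x1 + px, mid_y)])
    return study_area, line
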