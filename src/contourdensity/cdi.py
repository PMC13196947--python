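"""Contour-density maps and their cross-date comparison.

The contour density indicator (CDI) at a pixel is the mean gradient
amplitude ``G`` over a centered M x N sliding window,

    CDI[i, j] = (1 / (M*N)) * sum_{m, n} G[i+m, j+n],

with the window specified in meters and converted to the nearest odd pixel
counts.  It measures both how many contours a neighborhood contains and how
contrasty they are; abandonment of managed fields lowers it, recultivation
raises it.

Cross-date comparability: CDI levels drift with acquisition conditions
(sharpness, haze), so the later map of a pair is rescaled by a correction
factor ``k = mean_1 / mean_2`` computed over *stable areas* — pixels where
the two CDI maps are locally correlated above a threshold (default
r > 0.95) and can be assumed radiometrically invariant.  Change maps
(``delta = CDI_t2 - CDI_t1``) are formed after correction.  Zone-level
summaries use the histogram mode of CDI values and its normalized change
relative to a reference date (``dmcdi``): negative values indicate
structural degradation, positive values recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .contours import ContourGradientMap
from .raster import ReflectanceRaster

__all__ = [
    "CDIMap",
    "ChangeMap",
    "NormalizationResult",
    "ModeSummary",
    "window_pixels",
    "compute_cdi",
    "delta_cdi",
    "find_stable_areas",
    "correction_factor",
    "apply_correction",
    "mode_summary",
    "dmcdi",
    "mean_relative_change",
]


def window_pixels(window_m: float, pixel_size: float) -> int:
    """Nearest odd pixel count for a metric window edge (ties round up).

    A centered window needs an odd extent: 2000 m at 10 m/px -> 201 px,
    200 m -> 21 px.  Windows below 3 px are rejected.
    """
    if window_m < 3 * pixel_size:
        raise ValueError(
            f"window of {window_m} m is below 3 pixels at {pixel_size} m resolution"
        )
    ratio = window_m / pixel_size
    n = int(round(ratio))
    if n % 2 == 0:
        n = n + 1 if ratio >= n else n - 1
    return max(n, 3)


@dataclass
class CDIMap:
    """Sliding-window mean of contour gradient amplitudes."""

    cdi: np.ndarray
    valid_mask: np.ndarray          # window has >= 50% valid source pixels
    frac_valid: np.ndarray          # fraction of valid source pixels per window
    window_m: tuple[float, float]
    window_px: tuple[int, int]
    source_label: str = ""
    corrected: bool = False
    k: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.cdi.shape

    def same_grid(self, other: "CDIMap") -> bool:
        return self.shape == other.shape and self.window_px == other.window_px


@dataclass
class ChangeMap:
    """Elementwise CDI difference, later date minus earlier date."""

    delta: np.ndarray
    valid_mask: np.ndarray
    label_t1: str = ""
    label_t2: str = ""


@dataclass
class NormalizationResult:
    """Stable-area mask and the cross-date correction factor derived from it."""

    stable_mask: np.ndarray
    r_threshold: float
    corr_window_px: int
    cdi_avg_1: float
    cdi_avg_2: float

    @property
    def k(self) -> float:
        return correction_factor(self)


@dataclass
class ModeSummary:
    """Histogram of CDI values with the modal bin center as summary statistic."""

    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    mode: float
    n: int
    reference_mode: float | None = None
    dmcdi: float | None = None


def compute_cdi(
    g: ContourGradientMap,
    window_m: float | tuple[float, float],
    pixel_size: float | tuple[float, float],
) -> CDIMap:
    """Mean of G over a centered metric sliding window at every pixel.

    Window extents in meters are converted to the nearest odd pixel counts
    (M, N).  Borders are handled by reflection.  Windows containing invalid
    pixels average over the valid ones only; pixels whose window is less
    than 50% valid are flagged invalid in the output mask (but the partial
    mean is still recorded, with the coverage fraction alongside).
    """
    wmx, wmy = (window_m, window_m) if np.isscalar(window_m) else window_m
    psx, psy = (pixel_size, pixel_size) if np.isscalar(pixel_size) else pixel_size
    ncol = window_pixels(wmx, psx)   # window extent across columns (x)
    nrow = window_pixels(wmy, psy)   # and rows (y)

    filled = np.where(g.valid_mask, g.g, 0.0)
    size = (nrow, ncol)
    num = ndimage.uniform_filter(filled, size=size, mode="reflect")
    frac = ndimage.uniform_filter(g.valid_mask.astype(float), size=size, mode="reflect")
    cdi = np.zeros_like(num)
    np.divide(num, frac, out=cdi, where=frac > 1e-12)
    np.clip(cdi, 0.0, None, out=cdi)  # uniform_filter round-off can dip below 0
    return CDIMap(
        cdi=cdi,
        valid_mask=frac >= 0.5,
        frac_valid=frac,
        window_m=(float(wmx), float(wmy)),
        window_px=(nrow, ncol),
        source_label=g.source_label,
    )


def delta_cdi(a: CDIMap, b: CDIMap) -> ChangeMap:
    """Change map ``b - a`` (b the chronologically later, corrected map)."""
    if not a.same_grid(b):
        raise ValueError("CDI maps differ in grid or window; cannot difference")
    return ChangeMap(
        delta=b.cdi - a.cdi,
        valid_mask=a.valid_mask & b.valid_mask,
        label_t1=a.source_label,
        label_t2=b.source_label,
    )


def find_stable_areas(
    a: CDIMap,
    b: CDIMap,
    r_threshold: float = 0.95,
    corr_window_px: int = 11,
) -> NormalizationResult:
    """Locate radiometrically stable areas by local correlation of two CDI maps.

    For every pixel, the Pearson correlation of the two maps over the
    centered ``corr_window_px`` square block is computed from valid pixels
    only; blocks need >= 80% valid coverage and nonzero variance in both
    maps.  Pixels with correlation above ``r_threshold`` form the stable
    mask, over which each map's mean CDI is recorded.
    """
    if not a.same_grid(b):
        raise ValueError("CDI maps differ in grid or window")
    if corr_window_px < 5 or corr_window_px % 2 == 0:
        raise ValueError("corr_window_px must be an odd integer >= 5")
    both = a.valid_mask & b.valid_mask
    av = np.where(both, a.cdi, 0.0)
    bv = np.where(both, b.cdi, 0.0)

    def _mean(x: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(x, size=corr_window_px, mode="reflect")

    frac = _mean(both.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = _mean(av) / frac
        mb = _mean(bv) / frac
        cov = _mean(av * bv) / frac - ma * mb
        var_a = _mean(av * av) / frac - ma * ma
        var_b = _mean(bv * bv) / frac - mb * mb
        denom = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
        corr = np.where(denom > 1e-20, cov / np.where(denom > 0, denom, 1.0), np.nan)

    stable = both & (frac >= 0.8) & np.isfinite(corr) & (corr > r_threshold)
    if not stable.any():
        raise ValueError(
            "no stable areas found; lower r_threshold or enlarge corr_window_px"
        )
    return NormalizationResult(
        stable_mask=stable,
        r_threshold=r_threshold,
        corr_window_px=corr_window_px,
        cdi_avg_1=float(a.cdi[stable].mean()),
        cdi_avg_2=float(b.cdi[stable].mean()),
    )


def correction_factor(n: NormalizationResult) -> float:
    """Radiometric correction factor ``k = cdi_avg_1 / cdi_avg_2``."""
    if n.cdi_avg_2 <= 0:
        raise ValueError("stable-area mean of the later date is zero; k undefined")
    return n.cdi_avg_1 / n.cdi_avg_2

def apply_correction(b: CDIMap, k: float) -> CDIMap:
    """Rescale a CDI map by k so its stable-area mean matches the reference date."""
    if k <= 0:
        raise ValueError("k must be > 0")
    return replace(
        b,
        cdi=b.cdi * k,
        valid_mask=b.valid_mask.copy(),
        frac_valid=b.frac_valid.copy(),
        corrected=True,
        k=float(k),
    )


def mode_summary(
    c: CDIMap,
    bin_width: float = 1e-4,
    region_mask: np.ndarray | None = None,
    reference_mode: float | None = None,
) -> ModeSummary:
    """Histogram of valid (optionally region-restricted) CDI values and its mode.

    Bins are ``[j*bin_width, (j+1)*bin_width)``; the mode is the center of
    the maximal-count bin, ties broken toward the lower bin.  Four-decimal
    reporting of modes needs ``bin_width <= 1e-4``, the default.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sel = c.valid_mask if region_mask is None else (c.valid_mask & np.asarray(region_mask, bool))
    vals = c.cdi[sel]
    if vals.size == 0:
        raise ValueError("no valid pixels in the requested region")
    idx = np.floor(vals / bin_width).astype(np.int64)
    counts = np.bincount(idx - idx.min())
    jmin = int(idx.min())
    mode = (jmin + int(np.argmax(counts)) + 0.5) * bin_width
    edges = (jmin + np.arange(counts.size + 1)) * bin_width
    d = dmcdi(mode, reference_mode) if reference_mode is not None else None
    return ModeSummary(
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts,
        mode=float(mode),
        n=int(vals.size),
        reference_mode=reference_mode,
        dmcdi=d,
    )


def dmcdi(mode_t2: float, mode_ref: float) -> float:
    """Normalized mode difference ``(mode_t2 - mode_ref) / mode_ref``.

    Positive values indicate increased contour density (recultivation),
    negative values decreased density (degradation).
    """
    if mode_ref <= 0:
        raise ValueError("reference mode must be > 0")
    return (mode_t2 - mode_ref) / mode_ref


def _values_mask(x) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, CDIMap):
        return x.cdi, x.valid_mask
    if isinstance(x, ContourGradientMap):
        return x.g, x.valid_mask
    if isinstance(x, ReflectanceRaster):
        return x.values, x.valid_mask
    arr = np.asarray(x, dtype=float)
    return arr, np.isfinite(arr)


def mean_relative_change(a, b) -> float:
    """Mean relative change between two co-registered layers, in percent.

    ``100 * mean(|b - a|) / mean(|a|)`` over jointly valid pixels — the
    temporal-stability metric used to compare CDI against NDVI between two
    close acquisition dates (lower = more stable).  Accepts CDI maps,
    contour maps, rasters, or bare arrays.
    """
    va, ma = _values_mask(a)
    vb, mb = _values_mask(b)
    if va.shape != vb.shape:
        raise ValueError("layers differ in shape")
    both = ma & mb
    denom = np.abs(va[both]).mean() if both.any() else 0.0
    if denom == 0:
        raise ValueError("reference layer has zero mean absolute value")
    return float(100.0 * np.abs(vb[both] - va[both]).mean() / denom)
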