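"""Patch-based robust estimation of local background brightness and contrast.

A slice is tiled into patches; in each patch the foreground (bright somata)
forms a heavy right tail on top of an approximately normal background
intensity distribution.  The pipeline per patch is:

1. locate the onset of the power-law right tail (Clauset-style x_min scan
   minimising the Kolmogorov-Smirnov distance) and discard pixels beyond it;
2. iteratively trim symmetric quantile slices from both ends until the
   Shapiro-Wilk statistic of the remaining sample reaches a threshold
   (default 0.98) or a trimming budget is exhausted;
3. take the maximum-likelihood normal fit of the surviving pixels: its mean
   is the local background brightness B, its standard deviation the local
   background contrast C.

Patch centres whose sample passes the normality gate become the valid
support points used to fit the global vignetting surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrimConfig",
    "PatchGrid",
    "SupportPoint",
    "build_patch_grid",
    "powerlaw_tail_cutoff",
    "trim_to_normality",
    "estimate_support_point",
    "estimate_all_support_points",
]

#: Shapiro-Wilk accuracy degrades for very large n; subsample beyond this.
SW_MAX_N = 4000

#: minimum tail size for a power-law fit candidate
MIN_TAIL_POINTS = 10

#: cap on the number of x_min candidates scanned (evenly spaced over the
#: unique values); keeps per-patch cost bounded on large patches
MAX_XMIN_CANDIDATES = 200


@dataclass(frozen=True)
class TrimConfig:
    """Parameters of the normality-gated symmetric trimming.

    sw_threshold
        Shapiro-Wilk statistic required to accept a patch (0 < t <= 1).
    max_trim_fraction
        Maximum fraction of the tail-cut sample removable per side.
    trim_step
        Fraction removed per side per iteration.
    min_pixels
        Fewer remaining pixels than this marks the patch invalid.
    """

    sw_threshold: float = 0.98
    max_trim_fraction: float = 0.25
    trim_step: float = 0.025
    min_pixels: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.sw_threshold <= 1.0):
            raise ValueError("sw_threshold must be in (0, 1]")
        if not (0.0 <= self.max_trim_fraction < 0.5):
            raise ValueError("max_trim_fraction must be in [0, 0.5)")
        if self.trim_step <= 0:
            raise ValueError("trim_step must be positive")
        if self.min_pixels < 20:
            raise ValueError("min_pixels must be >= 20")


@dataclass(frozen=True)
class PatchGrid:
    """Row-major grid of patches fully contained in the image.

    ``corners[i] = (row, col)`` is the top-left pixel of patch i and
    ``centers[i] = (x, y)`` its centre (arithmetic mean of the domain
    corners, 0-based pixel coordinates, x = column).
    """

    patch_width: int
    patch_height: int
    stride: int
    corners: tuple[tuple[int, int], ...]
    centers: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.corners)

    def extract(self, image: np.ndarray, i: int) -> np.ndarray:
        r, c = self.corners[i]
        return image[r:r + self.patch_height, c:c + self.patch_width]


@dataclass(frozen=True)
class SupportPoint:
    """Local background estimate at a patch centre."""

    x: float
    y: float
    brightness: float
    contrast: float
    sw_statistic: float
    n_pixels_used: int
    valid: bool


def build_patch_grid(shape: tuple[int, int], patch_size: int,
                     stride: int | None = None) -> PatchGrid:
    """Tile a (rows, cols) image with square patches, row-major.

    Only patches fully inside the image are produced; the default stride
    equals the patch size (non-overlapping tiling).
    """
    rows, cols = shape
    if stride is None:
        stride = patch_size
    if patch_size < 8:
        raise ValueError("patch_size must be >= 8 pixels")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if patch_size > min(rows, cols):
        raise ValueError(
            f"patch size {patch_size} exceeds image extent {shape}")
    corners = [(r, c)
               for r in range(0, rows - patch_size + 1, stride)
               for c in range(0, cols - patch_size + 1, stride)]
    centers = [(c + (patch_size - 1) / 2.0, r + (patch_size - 1) / 2.0)
               for r, c in corners]
    return PatchGrid(patch_width=patch_size, patch_height=patch_size,
                     stride=stride, corners=tuple(corners),
                     centers=tuple(centers))


def powerlaw_tail_cutoff(values: np.ndarray,
                         min_tail: int = MIN_TAIL_POINTS,
                         max_candidates: int = MAX_XMIN_CANDIDATES) -> float:
    """Onset x_min of the power-law right tail of an intensity sample.

    Scans candidate x_min values (the unique sample values, evenly
    subsampled to at most ``max_candidates``); for each candidate the
    continuous power law is fitted by maximum likelihood to the tail
    ``{v >= x_min}`` and the candidate minimising the Kolmogorov-Smirnov
    distance between the empirical tail and the fitted law is returned.
    Pixels at or above the cutoff are foreground suspects and are discarded
    downstream.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < min_tail + 1:
        raise ValueError(f"need more than {min_tail} values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values equal")
    v = np.sort(v)
    uniq = np.unique(v)
    # candidates must leave at least min_tail points in the tail, be strictly
    # positive (the continuous power law needs x > 0) and lie in the upper
    # half of the sample: the background bulk dominates a patch by
    # construction, so a right-tail onset below the median is never
    # meaningful and admitting such candidates lets the KS minimum collapse
    # onto the bulk when the foreground forms a separated intensity cluster
    positive = uniq[(uniq > 0) & (uniq >= np.median(v))]
    if positive.size == 0:
        raise ValueError("power-law tail fit needs positive values")
    n = v.size
    candidates = positive[np.searchsorted(v, positive) <= n - min_tail]
    if candidates.size == 0:
        candidates = positive[:1]
    if candidates.size > max_candidates:
        idx = np.linspace(0, candidates.size - 1, max_candidates).astype(int)
        candidates = candidates[np.unique(idx)]

    best_xmin, best_ks = None, np.inf
    for xmin in candidates:
        tail = v[v >= xmin]
        if tail.size < min_tail:
            continue
        logsum = float(np.log(tail / xmin).sum())
        if logsum <= 0:  # degenerate tail (all values equal xmin)
            continue
        alpha = 1.0 + tail.size / logsum
        # KS distance: empirical CDF vs fitted CDF 1 - (xmin/x)^(alpha-1)
        cdf = 1.0 - (xmin / tail) ** (alpha - 1.0)
        ecdf_hi = np.arange(1, tail.size + 1) / tail.size
        ecdf_lo = np.arange(0, tail.size) / tail.size
        ks = float(np.maximum(np.abs(cdf - ecdf_hi),
                              np.abs(cdf - ecdf_lo)).max())
        if ks < best_ks:
            best_ks, best_xmin = ks, float(xmin)
    if best_xmin is None:
        # no candidate supported a proper fit (e.g. constant bulk plus one
        # outlier); cut just above the largest repeated value
        best_xmin = float(uniq[-2]) if uniq.size > 1 else float(uniq[-1])
        return np.nextafter(best_xmin, np.inf)
    return best_xmin


def _sw_statistic(values: np.ndarray) -> float:
    """Shapiro-Wilk W, on a deterministic even subsample above SW_MAX_N."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size > SW_MAX_N:
        v = v[np.linspace(0, v.size - 1, SW_MAX_N).astype(int)]
    if v.size < 3 or np.ptp(v) == 0:
        return 0.0
    return float(stats.shapiro(v).statistic)


def trim_to_normality(values: np.ndarray, cfg: TrimConfig
                      ) -> tuple[np.ndarray, float, bool]:
    """Greedy quantile trimming until the sample looks normal.

    Iteratively removes ``cfg.trim_step`` of the (tail-cut) sample per
    step, taken from the left end, the right end, or split over both —
    whichever raises the Shapiro-Wilk statistic most — until the statistic
    reaches ``cfg.sw_threshold`` or the total trimming budget
    (``2 * cfg.max_trim_fraction`` of the input) is exhausted.  The greedy
    side choice matters because foreground contamination is one-sided:
    purely symmetric trimming cannot recover a normal core from a sample
    whose upper flank was already censored by the tail cut.

    Returns (trimmed sample, its SW statistic, converged flag); the best
    window seen is returned even on failure, and fewer than
    ``cfg.min_pixels`` survivors yield ``converged = False`` rather than
    an exception.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    n0 = v.size
    if n0 == 0:
        raise ValueError("empty sample")
    lo, hi = 0, n0
    sw = _sw_statistic(v)
    best = (sw, lo, hi)
    budget = int(np.floor(2 * cfg.max_trim_fraction * n0))
    k = max(1, int(np.floor(cfg.trim_step * n0)))
    while sw < cfg.sw_threshold and (n0 - (hi - lo)) + k <= budget:
        half = max(1, k // 2)
        options = []
        for dl, dr in ((k, 0), (0, k), (half, k - half)):
            l2, h2 = lo + dl, hi - dr
            if h2 - l2 >= cfg.min_pixels:
                options.append((_sw_statistic(v[l2:h2]), l2, h2))
        if not options:
            break
        sw, lo, hi = max(options)
        if sw > best[0]:
            best = (sw, lo, hi)
    sw, lo, hi = best
    current = v[lo:hi]
    converged = bool(sw >= cfg.sw_threshold and current.size >= cfg.min_pixels)
    return current, sw, converged


def estimate_support_point(patch: np.ndarray, center: tuple[float, float],
                           cfg: TrimConfig | None = None) -> SupportPoint:
    """Estimate background brightness/contrast of one patch.

    Applies the power-law tail cut, then normality-gated trimming, then the
    maximum-likelihood normal fit (sample mean and standard deviation,
    ddof = 0).  The point is valid only if the Shapiro-Wilk gate was passed
    and the contrast is strictly positive (the full correction divides by
    the contrast field).
    """
    cfg = cfg or TrimConfig()
    v = np.asarray(patch, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty patch")
    x, y = center
    if np.ptp(v) == 0:
        return SupportPoint(x=x, y=y, brightness=float(v[0]), contrast=0.0,
                            sw_statistic=0.0, n_pixels_used=v.size, valid=False)

    sw_raw = _sw_statistic(np.sort(v))
    if sw_raw >= cfg.sw_threshold:
        # already a clean normal background: nothing to remove
        return _make_point(v, sw_raw, True, center)

    # the tail cut helps when a genuine foreground tail exists but can
    # censor the bulk when it does not; run the trim with and without it
    # and keep the candidate that converges while discarding least data
    candidates = []
    try:
        cutoff = powerlaw_tail_cutoff(v)
        kept = v[v < cutoff]
        if kept.size < cfg.min_pixels:
            kept = v[v <= cutoff]
        if kept.size >= cfg.min_pixels:
            candidates.append(trim_to_normality(kept, cfg))
    except ValueError:
        pass
    candidates.append(trim_to_normality(v, cfg))
    trimmed, sw, converged = max(
        candidates, key=lambda c: (c[2], c[0].size, c[1]))
    return _make_point(trimmed, sw, converged, center)


def _make_point(sample: np.ndarray, sw: float, converged: bool,
                center: tuple[float, float]) -> SupportPoint:
    B = float(sample.mean())
    C = float(sample.std(ddof=0))
    return SupportPoint(x=center[0], y=center[1], brightness=B, contrast=C,
                        sw_statistic=sw, n_pixels_used=int(sample.size),
                        valid=bool(converged and C > 0))


def estimate_all_support_points(image: np.ndarray, grid: PatchGrid,
                                cfg: TrimConfig | None = None
                                ) -> list[SupportPoint]:
    """One SupportPoint per grid patch, in grid (row-major) order."""
    image = np.asarray(image)
    cfg = cfg or TrimConfig()
    points = []
    for i in range(len(grid)):
        patch = grid.extract(image, i)
        points.append(estimate_support_point(patch, grid.centers[i], cfg))
    return points


def support_points_array(points: Sequence[SupportPoint],
                         field: str = "brightness",
                         valid_only: bool = True) -> np.ndarray:
    """(n, 3) array of (x, y, value) for surface fitting."""
    rows = [(p.x, p.y, getattr(p, field)) for p in points
            if p.valid or not valid_only]
    return np.asarray(rows, dtype=float).reshape(-1, 3)
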