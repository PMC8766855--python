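"""Vignetting-field modelling and image correction.

The spatial falloff of background brightness ``M_B(x, y)`` and of background
contrast (gain) ``M_C(x, y)`` across a microscopy slice is modelled by an
axis-aligned two-dimensional Gaussian surface with a constant offset,

    M(x, y) = A * exp(-[(x - x0)^2 / (2 sx^2) + (y - y0)^2 / (2 sy^2)]) + b.

Both surfaces are estimated per slice from the valid support points produced
by :mod:`vigncorr.patches` and then used in one of three pixelwise
corrections:

* full       -- ``I = C_T * (I0 - M_B) / M_C + B_T`` (brightness and gain)
* brightness -- ``I = I0 - M_B + B_T``
* contrast   -- ``I = C_T * (I0 - M_B) / M_C + M_B`` (gain equalised, local
  brightness restored)

``B_T`` and ``C_T`` are user-chosen constants that place the corrected image
in a convenient value range; they are not part of the estimation problem.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GaussianSurfaceParams",
    "SurfaceFitResult",
    "CorrectionConstants",
    "eval_surface",
    "fit_surface",
    "correct_full",
    "correct_brightness",
    "correct_contrast",
    "choose_constants",
    "SurfaceFitError",
]

#: evaluations of M_C below this multiple of C_T are treated as degenerate
MC_FLOOR_FACTOR = 1e-3

#: minimum number of support points for a 6-parameter surface fit
MIN_FIT_POINTS = 15


class SurfaceFitError(RuntimeError):
    """Raised when the Gaussian surface fit cannot be performed."""


@dataclass(frozen=True)
class GaussianSurfaceParams:
    """Axis-aligned 2D Gaussian plus offset: A, (x0, y0), (sx, sy), b."""

    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError("sigma_x and sigma_y must be positive")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianSurfaceParams":
        return cls(**{k: float(d[k]) for k in
                      ("amplitude", "x0", "y0", "sigma_x", "sigma_y", "offset")})


@dataclass(frozen=True)
class SurfaceFitResult:
    params: GaussianSurfaceParams
    r_squared: float
    n_points: int
    residual_rms: float


@dataclass(frozen=True)
class CorrectionConstants:
    """Target brightness ``B_T`` and contrast ``C_T`` of the corrected image."""

    B_T: float
    C_T: float

    def __post_init__(self) -> None:
        if not self.C_T > 0:
            raise ValueError("C_T must be positive")


def eval_surface(params: GaussianSurfaceParams, x, y):
    """Evaluate the Gaussian surface at (x, y); broadcasts like numpy."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = params.amplitude * np.exp(
        -((x - params.x0) ** 2 / (2.0 * params.sigma_x ** 2)
          + (y - params.y0) ** 2 / (2.0 * params.sigma_y ** 2))
    ) + params.offset
    return z


def eval_surface_on_grid(params: GaussianSurfaceParams,
                         shape: tuple[int, int]) -> np.ndarray:
    """Evaluate the surface at every pixel centre of a (rows, cols) image."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    return eval_surface(params, x, y)


def _model(xy, A, x0, y0, sx, sy, b):
    x, y = xy
    return A * np.exp(-((x - x0) ** 2 / (2 * sx ** 2)
                        + (y - y0) ** 2 / (2 * sy ** 2))) + b


def fit_surface(points: Sequence[tuple[float, float, float]] | np.ndarray,
                min_sigma: float | None = None) -> SurfaceFitResult:
    """Fit an axis-aligned 2D Gaussian + offset to (x, y, value) points.

    Nonlinear least squares over (A, x0, y0, sx, sy, b).  Initialisation:
    offset = min value, amplitude = value range, centre = value-weighted
    centroid, sigma = half the point-cloud extent.  Bounds keep the widths
    in [min_sigma, 10 * extent] and the centre within one extent of the
    point cloud; vignetting surfaces are wide and near-centred, and the
    bounds exclude needle solutions.

    Parameters
    ----------
    points
        Iterable of (x, y, value) triples, or an (n, 3) array.
    min_sigma
        Lower bound for the Gaussian widths.  Defaults to the smallest
        spacing between distinct support-point coordinates (the patch
        stride for a regular grid).

    Raises
    ------
    SurfaceFitError
        For fewer than 15 points, a flat value set (no Gaussian is
        identifiable), or optimizer failure.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of (x, y, value)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite entries")
    n = pts.shape[0]
    if n < MIN_FIT_POINTS:
        raise SurfaceFitError(
            f"need at least {MIN_FIT_POINTS} support points, got {n}")

    x, y, v = pts[:, 0], pts[:, 1], pts[:, 2]
    vmin, vmax = float(v.min()), float(v.max())
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot == 0.0:
        raise SurfaceFitError("all values identical: flat surface has no "
                              "Gaussian fit (SS_tot = 0)")

    span = float(max(x.max() - x.min(), y.max() - y.min()))
    if span <= 0:
        raise SurfaceFitError("degenerate point spread: zero spatial extent")
    if min_sigma is None:
        min_sigma = _min_spacing(x, y)

    w = v - vmin
    wsum = w.sum()
    if wsum > 0:
        cx, cy = float((w * x).sum() / wsum), float((w * y).sum() / wsum)
    else:  # pragma: no cover - excluded by ss_tot check
        cx, cy = float(x.mean()), float(y.mean())
    sigma0 = max(span / 2.0, min_sigma * 1.01)
    p0 = [vmax - vmin, cx, cy, sigma0, sigma0, vmin]
    lo = [0.0, x.min() - span, y.min() - span, min_sigma, min_sigma, -np.inf]
    hi = [np.inf, x.max() + span, y.max() + span, 10 * span, 10 * span, np.inf]
    p0 = np.clip(p0, lo, hi)

    try:
        popt, _ = curve_fit(_model, (x, y), v, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise SurfaceFitError(
            f"surface fit did not converge (init={p0!r}): {exc}") from exc

    fitted = _model((x, y), *popt)
    ss_res = float(np.sum((v - fitted) ** 2))
    params = GaussianSurfaceParams(amplitude=float(popt[0]), x0=float(popt[1]),
                                   y0=float(popt[2]), sigma_x=float(popt[3]),
                                   sigma_y=float(popt[4]), offset=float(popt[5]))
    return SurfaceFitResult(
        params=params,
        r_squared=1.0 - ss_res / ss_tot,
        n_points=n,
        residual_rms=float(np.sqrt(ss_res / n)),
    )


def _min_spacing(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest positive spacing between distinct coordinates on either axis."""
    spacings = []
    for c in (x, y):
        u = np.unique(c)
        if u.size > 1:
            spacings.append(np.diff(u).min())
    return float(min(spacings)) if spacings else 1.0


def _contrast_grid(M_C: GaussianSurfaceParams, shape, C_T: float) -> np.ndarray:
    mc = eval_surface_on_grid(M_C, shape)
    floor = MC_FLOOR_FACTOR * C_T
    bad = mc < floor
    if np.any(bad):
        r, c = np.unravel_index(int(np.argmin(mc)), mc.shape)
        raise ValueError(
            f"contrast field below floor {floor:g} at (x={c}, y={r}) "
            f"(value {mc[r, c]:g}); correction would amplify noise")
    return mc


def correct_full(image: np.ndarray, M_B: GaussianSurfaceParams,
                 M_C: GaussianSurfaceParams,
                 constants: CorrectionConstants) -> np.ndarray:
    """Brightness-and-contrast correction: C_T (I0 - M_B)/M_C + B_T."""
    img = np.asarray(image, dtype=float)
    mb = eval_surface_on_grid(M_B, img.shape[-2:])
    mc = _contrast_grid(M_C, img.shape[-2:], constants.C_T)
    return constants.C_T * (img - mb) / mc + constants.B_T


def correct_brightness(image: np.ndarray, M_B: GaussianSurfaceParams,
                       B_T: float) -> np.ndarray:
    """Brightness-only correction: I0 - M_B + B_T."""
    img = np.asarray(image, dtype=float)
    mb = eval_surface_on_grid(M_B, img.shape[-2:])
    return img - mb + B_T


def correct_contrast(image: np.ndarray, M_B: GaussianSurfaceParams,
                     M_C: GaussianSurfaceParams, C_T: float) -> np.ndarray:
    """Contrast-only correction: C_T (I0 - M_B)/M_C + M_B.

    Equalises the local gain while restoring the local background level,
    so only the contrast component of the vignetting is removed.
    """
    img = np.asarray(image, dtype=float)
    mb = eval_surface_on_grid(M_B, img.shape[-2:])
    mc = _contrast_grid(M_C, img.shape[-2:], C_T)
    return C_T * (img - mb) / mc + mb


def choose_constants(support_points: Iterable, policy: str = "mean"
                     ) -> CorrectionConstants:
    """Pick B_T and C_T from valid support points (held fixed stack-wide).

    The default policy sets B_T to the mean brightness and C_T to the mean
    contrast over all valid support points of the reference slice set, so
    the corrected stack sits in the same value range as the raw data.
    """
    if policy != "mean":
        raise ValueError(f"unknown constants policy: {policy!r}")
    valid = [(sp.brightness, sp.contrast) for sp in support_points if sp.valid]
    if not valid:
        raise ValueError("no valid support points to derive constants from")
    arr = np.asarray(valid, dtype=float)
    return CorrectionConstants(B_T=float(arr[:, 0].mean()),
                               C_T=float(arr[:, 1].mean()))
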