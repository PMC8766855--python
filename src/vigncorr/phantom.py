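"""Synthetic two-day microscopy phantoms with known ground-truth vignetting.

Real functional stacks come without ground truth, so validation runs on
phantoms: each slice is a noisy normal background (the undistorted scene has
brightness ``B_T = scene_background_mean`` and contrast
``C_T = scene_background_std``) carrying bright disk-shaped somata, observed
through a vignetting distortion that is the exact generative inverse of the
full correction:

    observed = (true - B_T) / C_T * M_C(x, y) + M_B(x, y)

so correcting the observed stack with the true fields and scene constants
reproduces the true scene to floating-point accuracy.  Two imaging days share
neuron positions; day-1 amplitudes are correlated with day-0 amplitudes at a
configurable level, which gives the day-to-day activity-change measures
something real to track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .field import GaussianSurfaceParams, eval_surface_on_grid

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom",
           "default_brightness_field", "default_contrast_field",
           "LAYER_LABELS"]

LAYER_LABELS = ("II/III", "IV", "V", "VI")

_PLACEMENT_RETRIES = 1000


def default_brightness_field(side: int = 512) -> GaussianSurfaceParams:
    """Default ground-truth brightness falloff for a square slice.

    Centred, wide (sigma ~ 0.35 side) and strong enough that the corner
    background sits at roughly half the central level — the visually obvious
    vignetting regime the correction is meant for.
    """
    c = (side - 1) / 2.0
    return GaussianSurfaceParams(amplitude=60.0, x0=c, y0=c,
                                 sigma_x=0.35 * side, sigma_y=0.35 * side,
                                 offset=20.0)


def default_contrast_field(side: int = 512) -> GaussianSurfaceParams:
    """Default ground-truth contrast (gain) falloff; positive everywhere."""
    c = (side - 1) / 2.0
    return GaussianSurfaceParams(amplitude=6.0, x0=c, y0=c,
                                 sigma_x=0.4 * side, sigma_y=0.4 * side,
                                 offset=3.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; defaults emulate a 512x512 two-photon slice.

    ``scene_background_mean`` / ``scene_background_std`` are the true scene
    constants B_T, C_T; ``day_correlation`` is the across-day correlation
    level of neuron amplitudes in [0, 1].
    """

    width: int = 512
    height: int = 512
    n_slices: int = 4
    true_brightness_field: GaussianSurfaceParams | None = None
    true_contrast_field: GaussianSurfaceParams | None = None
    scene_background_mean: float = 100.0
    scene_background_std: float = 8.0
    neurons_per_slice: int = 150
    neuron_radius: int = 4
    neuron_amplitude_range: tuple[float, float] = (40.0, 120.0)
    day_correlation: float = 0.6
    noise_model: str = "gaussian"
    blob_shape: str = "disk"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height, self.n_slices) < 1:
            raise ValueError("width, height, n_slices must all be >= 1")
        # field defaults scale with the slice geometry
        side = max(self.width, self.height)
        if self.true_brightness_field is None:
            f = default_brightness_field(side)
            object.__setattr__(self, "true_brightness_field", replace(
                f, x0=(self.width - 1) / 2.0, y0=(self.height - 1) / 2.0))
        if self.true_contrast_field is None:
            f = default_contrast_field(side)
            object.__setattr__(self, "true_contrast_field", replace(
                f, x0=(self.width - 1) / 2.0, y0=(self.height - 1) / 2.0))
        if self.neuron_radius < 1:
            raise ValueError("neuron_radius must be >= 1 pixel")
        if not self.scene_background_std > 0:
            raise ValueError("scene_background_std must be positive")
        if not (0.0 <= self.day_correlation <= 1.0):
            raise ValueError("day_correlation must be in [0, 1]")
        if self.noise_model != "gaussian":
            raise ValueError(f"unknown noise model: {self.noise_model!r}")
        if self.blob_shape not in ("disk", "gaussian"):
            raise ValueError(f"unknown blob shape: {self.blob_shape!r}")
        lo, hi = self.neuron_amplitude_range
        if not (0 <= lo <= hi):
            raise ValueError("neuron_amplitude_range must be 0 <= lo <= hi")

    def with_(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhantomOutput:
    """Observed and true stacks plus the neuron table and true fields."""

    stack_day0: np.ndarray
    stack_day1: np.ndarray
    true_scene_day0: np.ndarray
    true_scene_day1: np.ndarray
    neuron_table: pd.DataFrame
    ground_truth_fields: tuple[GaussianSurfaceParams, GaussianSurfaceParams]


def _slice_rng(seed: int, day: int, slice_idx: int) -> np.random.Generator:
    # fixed-offset sub-streams: regeneration of one slice never perturbs others
    return np.random.default_rng([seed, day, slice_idx])


def layer_of_slice(slice_idx: int, n_slices: int) -> str:
    """Laminar compartment by slice-index quartile (II/III, IV, V, VI)."""
    return LAYER_LABELS[min(3, (4 * slice_idx) // n_slices)]


def _place_neurons(rng: np.random.Generator, spec: PhantomSpec
                   ) -> np.ndarray:
    """Uniform non-overlapping integer centres, rejection-sampled."""
    r = spec.neuron_radius
    lo_x, hi_x = r, spec.width - 1 - r
    lo_y, hi_y = r, spec.height - 1 - r
    if lo_x > hi_x or lo_y > hi_y:
        raise ValueError("neuron radius too large for the image extent")
    min_d2 = (2 * r + 1) ** 2
    centers: list[tuple[int, int]] = []
    for k in range(spec.neurons_per_slice):
        for _ in range(_PLACEMENT_RETRIES):
            x = int(rng.integers(lo_x, hi_x + 1))
            y = int(rng.integers(lo_y, hi_y + 1))
            if all((x - cx) ** 2 + (y - cy) ** 2 >= min_d2
                   for cx, cy in centers):
                centers.append((x, y))
                break
        else:
            raise ValueError(
                f"could not place neuron {k + 1}/{spec.neurons_per_slice} "
                f"without overlap after {_PLACEMENT_RETRIES} retries; reduce "
                "neurons_per_slice or neuron_radius")
    return np.asarray(centers, dtype=int)


def _draw_amplitudes(rng: np.random.Generator, n: int,
                     lo: float, hi: float) -> np.ndarray:
    """Truncated-exponential soma amplitudes on [lo, hi].

    Dim cells are common and very bright cells rare, so the patch intensity
    histogram acquires the long right tail the background estimator expects;
    the exponential scale is (hi - lo) / 3, truncated by resampling (no atom
    at hi).
    """
    if hi == lo:
        return np.full(n, float(lo))
    scale = (hi - lo) / 3.0
    out = np.empty(0)
    while out.size < n:
        draw = lo + rng.exponential(scale, size=max(2 * n, 16))
        out = np.concatenate([out, draw[draw <= hi]])
    return out[:n]


def _paint_blobs(scene: np.ndarray, centers: np.ndarray,
                 amplitudes: np.ndarray, spec: PhantomSpec) -> None:
    """Add somata onto the noisy background scene.

    Disk blobs add a flat amplitude over a hard disk; the optional
    Gaussian bump adds a smooth profile instead.
    """
    r = spec.neuron_radius
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = xx ** 2 + yy ** 2
    disk = (d2 <= r ** 2).astype(float)
    bump = np.exp(-d2 / (2 * (r / 2.0) ** 2))
    profile = disk if spec.blob_shape == "disk" else bump
    for (x, y), a in zip(centers, amplitudes):
        scene[y - r:y + r + 1, x - r:x + r + 1] += a * profile


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate the two-day phantom described by ``spec``.

    Deterministic given ``spec.seed``.  Neuron positions are drawn once and
    shared across days; amplitudes on day 1 follow
    ``a1 = rho * a0 + sqrt(1 - rho^2) * eps`` with ``eps`` drawn fresh from
    the amplitude distribution.  The table records the noise-free activity
    signal (background mean + amplitude) per day; the centre pixel of the
    true scene carries that value plus its background noise draw.
    """
    shape = (spec.height, spec.width)
    mb = eval_surface_on_grid(spec.true_brightness_field, shape)
    mc = eval_surface_on_grid(spec.true_contrast_field, shape)
    if not np.all(mc > 0):
        raise ValueError("true_contrast_field must be positive everywhere")
    mu, sd = spec.scene_background_mean, spec.scene_background_std
    rho = spec.day_correlation
    amp_lo, amp_hi = spec.neuron_amplitude_range

    true = [np.empty((spec.n_slices,) + shape) for _ in range(2)]
    observed = [np.empty_like(true[0]) for _ in range(2)]
    rows = []
    nid = 0
    for s in range(spec.n_slices):
        layer = layer_of_slice(s, spec.n_slices)
        place_rng = _slice_rng(spec.seed, 2, s)  # day-independent positions
        centers = (_place_neurons(place_rng, spec)
                   if spec.neurons_per_slice else
                   np.empty((0, 2), dtype=int))
        a0 = _draw_amplitudes(place_rng, len(centers), amp_lo, amp_hi)
        eps = _draw_amplitudes(place_rng, len(centers), amp_lo, amp_hi)
        a1 = rho * a0 + np.sqrt(1.0 - rho ** 2) * eps
        for day, amps in enumerate((a0, a1)):
            rng = _slice_rng(spec.seed, day, s)
            scene = rng.normal(mu, sd, size=shape)
            _paint_blobs(scene, centers, amps, spec)
            true[day][s] = scene
            observed[day][s] = (scene - mu) / sd * mc + mb
        for (x, y), v0, v1 in zip(centers, a0, a1):
            rows.append((nid, int(x), int(y), s, layer,
                         mu + float(v0), mu + float(v1)))
            nid += 1

    table = pd.DataFrame(rows, columns=["neuron_id", "x", "y", "slice",
                                        "layer", "activity_day0",
                                        "activity_day1"])
    return PhantomOutput(
        stack_day0=observed[0], stack_day1=observed[1],
        true_scene_day0=true[0], true_scene_day1=true[1],
        neuron_table=table,
        ground_truth_fields=(spec.true_brightness_field,
                             spec.true_contrast_field),
    )
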