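"""End-to-end orchestration: estimate fields per slice, correct, evaluate.

Fields are fitted per slice independently — the method operates on single
images, which is what makes it robust to day-by-day and depth variation of
the vignetting — while the target constants ``B_T``/``C_T`` are pooled over
the stack so all corrected slices share one value range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import bias
from .field import (CorrectionConstants, SurfaceFitError, SurfaceFitResult,
                    choose_constants, correct_brightness, correct_contrast,
                    correct_full, fit_surface)
from .io import RunConfig
from .patches import (TrimConfig, build_patch_grid,
                      estimate_all_support_points, support_points_array)

log = logging.getLogger("vigncorr")

__all__ = ["SliceFields", "estimate_stack_fields", "correct_stack",
           "evaluate_stack_pair"]


@dataclass
class SliceFields:
    """Fitted brightness/contrast surfaces for one slice (None if failed)."""

    slice_index: int
    brightness: SurfaceFitResult | None
    contrast: SurfaceFitResult | None
    n_valid_points: int
    support_points: list | None = None

    @property
    def correctable(self) -> bool:
        return self.brightness is not None and self.contrast is not None


def _trim_config(config: RunConfig) -> TrimConfig:
    return TrimConfig(sw_threshold=config.sw_threshold,
                      max_trim_fraction=config.max_trim_fraction,
                      trim_step=config.trim_step,
                      min_pixels=config.min_pixels)


def estimate_slice_fields(image: np.ndarray, config: RunConfig | None = None,
                          slice_index: int = 0) -> SliceFields:
    """STEP 1 + STEP 2 for a single slice."""
    config = config or RunConfig()
    grid = build_patch_grid(image.shape, config.patch_size, config.stride)
    points = estimate_all_support_points(image, grid, _trim_config(config))
    n_valid = sum(p.valid for p in points)
    log.info("slice %d: %d/%d valid support points", slice_index, n_valid,
             len(points))
    fits: dict[str, SurfaceFitResult | None] = {}
    for name, field_attr in (("brightness", "brightness"),
                             ("contrast", "contrast")):
        try:
            fits[name] = fit_surface(
                support_points_array(points, field_attr),
                min_sigma=float(config.patch_size))
        except (SurfaceFitError, ValueError) as exc:
            log.warning("slice %d: %s fit failed: %s", slice_index, name, exc)
            fits[name] = None
    for name in fits:
        if fits[name] is not None:
            log.info("slice %d: %s fit R^2 = %.3f", slice_index, name,
                     fits[name].r_squared)
    return SliceFields(slice_index=slice_index, brightness=fits["brightness"],
                       contrast=fits["contrast"], n_valid_points=n_valid,
                       support_points=points)


def estimate_stack_fields(stack: np.ndarray,
                          config: RunConfig | None = None
                          ) -> list[SliceFields]:
    """Per-slice field estimation over a (slices, rows, cols) stack."""
    stack = np.asarray(stack)
    return [estimate_slice_fields(stack[s], config, slice_index=s)
            for s in range(stack.shape[0])]


def stack_constants(fields: list[SliceFields],
                    policy: str = "mean") -> CorrectionConstants:
    """Pool B_T/C_T over the valid support points of every slice."""
    pts = [p for f in fields if f.support_points
           for p in f.support_points]
    return choose_constants(pts, policy)


def correct_stack(stack: np.ndarray, fields: list[SliceFields],
                  constants: CorrectionConstants,
                  mode: str = "full") -> np.ndarray:
    """Apply the chosen correction slice by slice.

    Raises if any slice is uncorrectable (no fitted fields); callers that
    want to skip such slices filter beforehand.
    """
    stack = np.asarray(stack, dtype=float)
    out = np.empty_like(stack)
    for f in fields:
        img = stack[f.slice_index]
        if not f.correctable:
            raise ValueError(f"slice {f.slice_index} has no fitted fields")
        mb = f.brightness.params
        mc = f.contrast.params
        if mode == "full":
            out[f.slice_index] = correct_full(img, mb, mc, constants)
        elif mode == "brightness":
            out[f.slice_index] = correct_brightness(img, mb, constants.B_T)
        elif mode == "contrast":
            out[f.slice_index] = correct_contrast(img, mb, mc, constants.C_T)
        else:
            raise ValueError(f"unknown correction mode: {mode!r}")
    return out


def evaluate_stack_pair(stack_day0: np.ndarray, stack_day1: np.ndarray,
                        neuron_table, p_threshold: float = 0.01,
                        layers: list[str] | None = None,
                        measures: tuple[str, ...] = bias.MEASURES,
                        ):
    """Pairwise region tests and bias summaries for a two-day stack pair.

    Returns ``(report, summaries)``: the long-format pairwise report over
    all requested layers and measures, and a dict
    ``{(layer, measure): BiasSummary DataFrame}``.
    """
    import pandas as pd

    grid = bias.build_region_grid(stack_day0.shape[-2:])
    table = bias.activity_table(stack_day0, stack_day1, neuron_table, grid)
    if layers is None:
        layers = sorted(table["layer"].unique())
    reports = []
    summaries = {}
    for layer in layers:
        for measure in measures:
            rep = bias.pairwise_region_tests(table, layer, measure)
            reports.append(rep)
            summaries[(layer, measure)] = bias.summarize_bias(rep, p_threshold)
    return pd.concat(reports, ignore_index=True), summaries
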