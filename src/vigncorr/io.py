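"""File formats: multi-page TIFF stacks, CSV tables, JSON field records.

Stacks are plain multi-page grayscale TIFF, 16-bit unsigned by default or
32-bit float; neuron tables are CSV with the header
``neuron_id,x,y,slice,layer,activity_day0,activity_day1``; fitted field
parameters travel as JSON, one record per slice and field:
``{"A", "x0", "y0", "sx", "sy", "b", "r2", "n_points"}``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .field import GaussianSurfaceParams, SurfaceFitResult
from .patches import SupportPoint

__all__ = ["read_stack", "write_stack", "read_neuron_table",
           "write_neuron_table", "fields_to_json", "fields_from_json",
           "support_points_to_csv", "support_points_from_csv", "RunConfig"]

NEURON_COLUMNS = ["neuron_id", "x", "y", "slice", "layer",
                  "activity_day0", "activity_day1"]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a (slices, rows, cols) array."""
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"expected a single-channel stack, got shape "
                         f"{arr.shape} from {path}")
    return arr


def write_stack(path: str | Path, stack: np.ndarray,
                dtype: str = "uint16") -> None:
    """Write a stack as multi-page TIFF.

    ``dtype='uint16'`` clips and rounds with saturation; ``'float32'``
    preserves the values exactly (up to float32 precision).
    """
    stack = np.asarray(stack)
    if dtype == "uint16":
        data = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max
                       ).astype(np.uint16)
    elif dtype == "float32":
        data = stack.astype(np.float32)
    else:
        raise ValueError(f"unsupported TIFF dtype: {dtype!r}")
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_neuron_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path)
    missing = [c for c in NEURON_COLUMNS[:5] if c not in t.columns]
    if missing:
        raise ValueError(f"neuron table {path} lacks columns {missing}")
    return t


def write_neuron_table(path: str | Path, table: pd.DataFrame) -> None:
    cols = [c for c in NEURON_COLUMNS if c in table.columns]
    table.to_csv(path, columns=cols, index=False)


def _fit_record(fit: SurfaceFitResult) -> dict:
    p = fit.params
    return {"A": p.amplitude, "x0": p.x0, "y0": p.y0, "sx": p.sigma_x,
            "sy": p.sigma_y, "b": p.offset, "r2": fit.r_squared,
            "n_points": fit.n_points}


def fields_to_json(path: str | Path,
                   records: Sequence[dict]) -> None:
    """Write per-slice field records.

    Each record: ``{"slice": int, "brightness": fit, "contrast": fit,
    "n_valid_points": int}`` where fits are SurfaceFitResult or None for an
    uncorrectable slice.
    """
    out = []
    for rec in records:
        r = {"slice": rec["slice"], "n_valid_points": rec["n_valid_points"]}
        for key in ("brightness", "contrast"):
            fit = rec.get(key)
            r[key] = _fit_record(fit) if fit is not None else None
        out.append(r)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")


def fields_from_json(path: str | Path) -> list[dict]:
    """Load field records; fit dicts become GaussianSurfaceParams + r2."""
    raw = json.loads(Path(path).read_text())
    records = []
    for rec in raw:
        r = {"slice": rec["slice"],
             "n_valid_points": rec.get("n_valid_points")}
        for key in ("brightness", "contrast"):
            d = rec.get(key)
            if d is None:
                r[key] = None
            else:
                r[key] = {
                    "params": GaussianSurfaceParams(
                        amplitude=d["A"], x0=d["x0"], y0=d["y0"],
                        sigma_x=d["sx"], sigma_y=d["sy"], offset=d["b"]),
                    "r2": d.get("r2"),
                    "n_points": d.get("n_points"),
                }
        records.append(r)
    return records


def support_points_to_csv(path: str | Path,
                          points: Sequence[SupportPoint]) -> None:
    pd.DataFrame([{"x": p.x, "y": p.y, "B": p.brightness, "C": p.contrast,
                   "sw": p.sw_statistic, "valid": p.valid}
                  for p in points]).to_csv(path, index=False)


def support_points_from_csv(path: str | Path) -> list[SupportPoint]:
    t = pd.read_csv(path)
    return [SupportPoint(x=r.x, y=r.y, brightness=r.B, contrast=r.C,
                         sw_statistic=r.sw, n_pixels_used=0,
                         valid=bool(r.valid))
            for r in t.itertuples()]


@dataclasses.dataclass
class RunConfig:
    """Flat pipeline configuration (YAML/JSON file keys mirror the fields)."""

    patch_size: int = 32
    stride: int | None = None
    sw_threshold: float = 0.98
    max_trim_fraction: float = 0.25
    trim_step: float = 0.025
    min_pixels: int = 20
    mode: str = "full"          # full | brightness | contrast
    constants_policy: str = "mean"
    p_threshold: float = 0.01
    seed: int = 0
    tiff_dtype: str = "uint16"

    def __post_init__(self) -> None:
        if self.mode not in ("full", "brightness", "contrast"):
            raise ValueError(f"unknown correction mode: {self.mode!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
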