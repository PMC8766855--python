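"""Center-periphery bias diagnostics for neural-activity measures.

A slice is divided into a 4x4 grid of regions typed as center (the inner
2x2: C1-C4), edge (non-corner border cells: E1-E8) and angle (corner cells:
A1-A4).  Per laminar compartment and per activity measure, every unordered
pair of the 16 regions is compared with a Welch t-test (Bonferroni-corrected
over the 120 pairs) and by the relative difference of the within-region
standard deviations,

    delta_STD = |s_a - s_b| / ((s_a + s_b) / 2).

Region-type pair summaries follow: c_p is the fraction of non-significant
pairs (corrected p >= threshold), and the normalised statistics

    DeltaC   = c_p / <c_p>_same,
    DeltaSTD = mean(delta_STD) / <mean(delta_STD)>_same,

with <.>_same the unweighted average over the within-type pairs (C-C, E-E,
A-A), are near 1 when no center-periphery bias exists.  Vignetting drives
DeltaC(C-A) well below 1 and DeltaSTD(C-A) above 1; a successful correction
pulls both back toward 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionGrid",
    "build_region_grid",
    "count_region_pairs",
    "read_activity",
    "derive_changes",
    "pairwise_region_tests",
    "summarize_bias",
    "highly_active_cells",
    "overlap_rate",
    "TYPE_PAIRS",
    "WITHIN_TYPE_PAIRS",
    "N_REGION_PAIRS",
]

REGION_TYPES = ("C", "E", "A")
TYPE_PAIRS = ("C-C", "E-E", "A-A", "C-E", "E-A", "C-A")
WITHIN_TYPE_PAIRS = ("C-C", "E-E", "A-A")
N_REGION_PAIRS = 120  # C(16, 2); the Bonferroni family per layer x measure

MEASURES = ("X", "dX", "rdX")


@dataclass(frozen=True)
class RegionGrid:
    """4x4 region partition of a (rows, cols) slice.

    ``labels`` is the 4x4 array of region ids; ``row_edges`` / ``col_edges``
    are the 5 half-open cell boundaries along each axis (remainder pixels
    go to the last row/column of cells).
    """

    labels: np.ndarray
    row_edges: np.ndarray
    col_edges: np.ndarray

    @property
    def region_ids(self) -> list[str]:
        return [self.labels[r, c] for r in range(4) for c in range(4)]

    def region_of(self, x, y) -> np.ndarray:
        """Region id(s) for pixel coordinates (x = column, y = row)."""
        x = np.asarray(x)
        y = np.asarray(y)
        ci = np.clip(np.searchsorted(self.col_edges, x, side="right") - 1, 0, 3)
        ri = np.clip(np.searchsorted(self.row_edges, y, side="right") - 1, 0, 3)
        return self.labels[ri, ci]


def _cell_type(r: int, c: int) -> str:
    corner = r in (0, 3) and c in (0, 3)
    center = r in (1, 2) and c in (1, 2)
    return "A" if corner else ("C" if center else "E")


def region_type(region_id: str) -> str:
    return region_id[0]


def build_region_grid(shape: tuple[int, int]) -> RegionGrid:
    """Evenly divide a (rows, cols) slice into the 16 typed regions."""
    rows, cols = shape
    if rows < 4 or cols < 4:
        raise ValueError("image must be at least 4x4 pixels")
    re = np.array([0, rows // 4, 2 * (rows // 4), 3 * (rows // 4), rows])
    ce = np.array([0, cols // 4, 2 * (cols // 4), 3 * (cols // 4), cols])
    labels = np.empty((4, 4), dtype=object)
    counters = {"C": 0, "E": 0, "A": 0}
    for r in range(4):
        for c in range(4):
            t = _cell_type(r, c)
            counters[t] += 1
            labels[r, c] = f"{t}{counters[t]}"
    return RegionGrid(labels=labels, row_edges=re, col_edges=ce)


def count_region_pairs(grid: RegionGrid) -> dict[str, int]:
    """Number of unordered region pairs per type-pair (sums to 120)."""
    ids = grid.region_ids
    counts = dict.fromkeys(TYPE_PAIRS, 0)
    for a, b in itertools.combinations(ids, 2):
        counts[_type_pair(region_type(a), region_type(b))] += 1
    return counts


def _type_pair(ta: str, tb: str) -> str:
    for tp in TYPE_PAIRS:
        u, v = tp.split("-")
        if {ta, tb} == {u, v} or (u == v == ta == tb):
            return tp
    raise KeyError((ta, tb))  # pragma: no cover


def read_activity(stack: np.ndarray, neuron_table: pd.DataFrame,
                  grid: RegionGrid | None = None) -> pd.DataFrame:
    """Read per-neuron activity as the centre-pixel intensity.

    The same centres (segmented once, on the uncorrected data) are used for
    raw and corrected stacks, so activities before/after correction refer to
    identical pixels.  Returns a copy of the table with an ``X`` column and,
    if a grid is given, a ``region`` column.
    """
    stack = np.asarray(stack)
    t = neuron_table.copy()
    n_slices, rows, cols = stack.shape
    bad = t[(t.x < 0) | (t.x >= cols) | (t.y < 0) | (t.y >= rows)
            | (t.slice < 0) | (t.slice >= n_slices)]
    if len(bad):
        raise ValueError("neuron centres outside the image domain: ids "
                         f"{sorted(bad.neuron_id.tolist())}")
    t["X"] = stack[t["slice"].to_numpy(), t["y"].to_numpy(),
                   t["x"].to_numpy()]
    if grid is not None:
        t["region"] = grid.region_of(t["x"].to_numpy(), t["y"].to_numpy())
    return t


def activity_table(stack_day0: np.ndarray, stack_day1: np.ndarray,
                   neuron_table: pd.DataFrame,
                   grid: RegionGrid | None = None) -> pd.DataFrame:
    """Two-day activity table with derived change measures attached."""
    t = read_activity(stack_day0, neuron_table, grid)
    t = t.rename(columns={"X": "X_day0"})
    t["X_day1"] = read_activity(stack_day1, neuron_table)["X"]
    return derive_changes(t)


def derive_changes(table: pd.DataFrame) -> pd.DataFrame:
    """Attach absolute (dX) and relative (rdX) day-to-day activity changes.

    ``dX = X(day1) - X(day0)``; ``rdX = dX / (X(day1) + X(day0))``, left NaN
    (flagged in ``rdX_defined``) where the denominator is zero.
    """
    t = table.copy()
    x0 = t["X_day0"].to_numpy(dtype=float)
    x1 = t["X_day1"].to_numpy(dtype=float)
    t["dX"] = x1 - x0
    denom = x1 + x0
    with np.errstate(divide="ignore", invalid="ignore"):
        rdx = np.where(denom != 0, (x1 - x0) / denom, np.nan)
    t["rdX"] = rdx
    t["rdX_defined"] = denom != 0
    # convenience alias so measure="X" refers to day-0 activity
    t["X"] = t["X_day0"]
    return t


def pairwise_region_tests(table: pd.DataFrame, layer: str | None,
                          measure: str = "X",
                          family_size: int = N_REGION_PAIRS,
                          grid: RegionGrid | None = None) -> pd.DataFrame:
    """Welch t-test and delta_STD for every unordered region pair.

    Long-format result with one row per pair: region ids and types,
    Bonferroni-corrected p-value (p * family_size, capped at 1), delta_STD
    computed from the within-region sample standard deviations, and a
    ``testable`` flag (False when either region holds < 2 neurons with a
    defined measure value).
    """
    if "region" not in table.columns:
        if grid is None:
            raise ValueError("table lacks a 'region' column and no grid given")
        table = table.copy()
        table["region"] = grid.region_of(table["x"].to_numpy(),
                                         table["y"].to_numpy())
    sub = table if layer is None else table[table["layer"] == layer]
    canonical = ([f"C{i}" for i in range(1, 5)]
                 + [f"E{i}" for i in range(1, 9)]
                 + [f"A{i}" for i in range(1, 5)])
    if grid is not None:
        ids = grid.region_ids
    elif set(table["region"].unique()) <= set(canonical):
        ids = canonical  # empty regions still appear, flagged untestable
    else:
        ids = sorted(sub["region"].unique(), key=_region_sort_key)
    groups = {rid: sub.loc[sub["region"] == rid, measure].dropna().to_numpy()
              for rid in ids}
    rows = []
    for a, b in itertools.combinations(ids, 2):
        va, vb = groups[a], groups[b]
        testable = len(va) >= 2 and len(vb) >= 2
        if testable:
            p = stats.ttest_ind(va, vb, equal_var=False).pvalue
            p_corr = min(1.0, float(p) * family_size)
            sa, sb = va.std(ddof=1), vb.std(ddof=1)
            d_std = (abs(sa - sb) / ((sa + sb) / 2.0)
                     if (sa + sb) > 0 else 0.0)
        else:
            p_corr, d_std = np.nan, np.nan
        rows.append((layer, measure, a, b,
                     _type_pair(region_type(a), region_type(b)),
                     p_corr, float(d_std) if testable else np.nan, testable))
    return pd.DataFrame(rows, columns=["layer", "measure", "region_a",
                                       "region_b", "type_pair", "p_corrected",
                                       "delta_std", "testable"])


def _region_sort_key(rid: str) -> tuple[int, int]:
    return ({"C": 0, "E": 1, "A": 2}[rid[0]], int(rid[1:]))


def summarize_bias(report: pd.DataFrame, p_threshold: float = 0.01
                   ) -> pd.DataFrame:
    """Region-type pair summary: c_p, DeltaC, mean delta_STD, DeltaSTD.

    ``c_p`` is the fraction of testable pairs with corrected p >= threshold;
    the normalisers are unweighted means over the within-type pairs.  When a
    normaliser is zero the corresponding ratio is NaN (flagged undefined).
    """
    rows = {}
    for tp in TYPE_PAIRS:
        sub = report[(report["type_pair"] == tp) & report["testable"]]
        n = len(sub)
        if n == 0:
            rows[tp] = dict(n_pairs=0, c_p=np.nan, mean_delta_std=np.nan)
            continue
        rows[tp] = dict(
            n_pairs=n,
            c_p=float((sub["p_corrected"] >= p_threshold).mean()),
            mean_delta_std=float(sub["delta_std"].mean()),
        )
    cp_same = np.nanmean([rows[tp]["c_p"] for tp in WITHIN_TYPE_PAIRS])
    ds_same = np.nanmean([rows[tp]["mean_delta_std"]
                          for tp in WITHIN_TYPE_PAIRS])
    out = []
    for tp in TYPE_PAIRS:
        r = rows[tp]
        dc = (r["c_p"] / cp_same
              if cp_same and np.isfinite(cp_same) else np.nan)
        dstd = (r["mean_delta_std"] / ds_same
                if ds_same and np.isfinite(ds_same) else np.nan)
        out.append((tp, r["n_pairs"], r["c_p"], dc,
                    r["mean_delta_std"], dstd))
    return pd.DataFrame(out, columns=["type_pair", "n_pairs", "c_p",
                                      "delta_c", "mean_delta_std",
                                      "delta_stdev"]).set_index("type_pair")


def highly_active_cells(table: pd.DataFrame, layer: str | None = None,
                        measure: str = "rdX") -> set:
    """Neurons whose relative activity change exceeds mean + 3 std.

    The three-sigma rule on rdX flags memory-trace candidates; with normally
    distributed changes the expected flagged fraction is ~0.13%.
    """
    sub = table if layer is None else table[table["layer"] == layer]
    vals = sub[measure].dropna()
    if len(vals) < 2:
        return set()
    cut = vals.mean() + 3.0 * vals.std(ddof=1)
    return set(sub.loc[sub[measure] > cut, "neuron_id"])


def overlap_rate(H_i: set, H_j: set) -> float:
    """|H_i & H_j| / |H_i| — overlap relative to the reference set H_i."""
    if not H_i:
        raise ValueError("reference set H_i is empty; overlap rate undefined")
    return len(set(H_i) & set(H_j)) / len(set(H_i))
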