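"""Region partition, pairwise tests and center-periphery bias statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vigncorr.bias import (N_REGION_PAIRS, TYPE_PAIRS, build_region_grid,
                           count_region_pairs, derive_changes,
                           highly_active_cells, overlap_rate,
                           pairwise_region_tests, read_activity,
                           region_type, summarize_bias)


@pytest.fixture(scope="module")
def grid512():
    return build_region_grid((512, 512))


class TestRegionGrid:
    def test_16_even_cells(self, grid512):
        assert np.diff(grid512.row_edges).tolist() == [128] * 4
        assert np.diff(grid512.col_edges).tolist() == [128] * 4
        assert len(grid512.region_ids) == 16

    def test_type_layout(self, grid512):
        lab = grid512.labels
        assert region_type(lab[0, 0]) == "A"
        assert region_type(lab[1, 1]) == "C"
        assert region_type(lab[0, 1]) == "E"
        types = [region_type(t) for t in grid512.region_ids]
        assert (types.count("C"), types.count("E"), types.count("A")) \
            == (4, 8, 4)

    def test_ids_unique_and_deterministic(self, grid512):
        assert sorted(grid512.region_ids) == sorted(
            [f"C{i}" for i in range(1, 5)] + [f"E{i}" for i in range(1, 9)]
            + [f"A{i}" for i in range(1, 5)])
        assert grid512.labels[0, 0] == "A1"
        assert grid512.labels[3, 3] == "A4"
        assert grid512.labels[1, 1] == "C1"

    def test_region_lookup(self, grid512):
        assert grid512.region_of(0, 0) == "A1"
        assert grid512.region_of(511, 511) == "A4"
        assert grid512.region_of(256, 256) == "C4"

    def test_remainder_pixels_to_last_cells(self):
        g = build_region_grid((10, 10))
        assert g.row_edges.tolist() == [0, 2, 4, 6, 10]

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            build_region_grid((3, 40))


class TestPairCounts:
    def test_per_type_counts(self, grid512):
        counts = count_region_pairs(grid512)
        assert counts == {"C-C": 6, "E-E": 28, "A-A": 6,
                          "C-E": 32, "E-A": 32, "C-A": 16}

    def test_total_is_all_pairs(self, grid512):
        assert sum(count_region_pairs(grid512).values()) == N_REGION_PAIRS
        assert N_REGION_PAIRS == len(
            list(itertools.combinations(range(16), 2)))


def _table(grid, rng, n_per_region=40, shift=None, scale=None, layer="II/III"):
    """Synthetic neuron table with per-region Normal(100+shift, 10*scale)."""
    rows = []
    nid = 0
    for r in range(4):
        for c in range(4):
            rid = grid.labels[r, c]
            x0, x1 = grid.col_edges[c], grid.col_edges[c + 1]
            y0, y1 = grid.row_edges[r], grid.row_edges[r + 1]
            mu = 100 + (shift(rid) if shift else 0)
            sd = 10 * (scale(rid) if scale else 1)
            for _ in range(n_per_region):
                rows.append(dict(
                    neuron_id=nid, x=rng.integers(x0, x1),
                    y=rng.integers(y0, y1), slice=0, layer=layer,
                    X=rng.normal(mu, sd), region=rid))
                nid += 1
    return pd.DataFrame(rows)


class TestReadActivity:
    def test_constant_image(self):
        t = pd.DataFrame(dict(neuron_id=[0, 1], x=[5, 60], y=[7, 50],
                              slice=[0, 0], layer=["IV", "IV"]))
        stack = np.full((1, 64, 64), 3.5)
        out = read_activity(stack, t)
        assert (out.X == 3.5).all()

    def test_center_pixel_lookup(self):
        stack = np.zeros((2, 8, 8))
        stack[1, 3, 6] = 42
        t = pd.DataFrame(dict(neuron_id=[0], x=[6], y=[3], slice=[1],
                              layer=["V"]))
        assert read_activity(stack, t).X.iloc[0] == 42

    def test_out_of_domain_listed(self):
        t = pd.DataFrame(dict(neuron_id=[7, 8], x=[5, 99], y=[5, 5],
                              slice=[0, 0], layer=["V", "V"]))
        with pytest.raises(ValueError, match=r"\[8\]"):
            read_activity(np.zeros((1, 64, 64)), t)


class TestDeriveChanges:
    @pytest.mark.parametrize("x0,x1,dx,rdx", [
        (10, 10, 0, 0.0),
        (0, 20, 20, 1.0),
        (30, 10, -20, -0.5),
    ])
    def test_printed_formula_arithmetic(self, x0, x1, dx, rdx):
        t = derive_changes(pd.DataFrame(dict(X_day0=[x0], X_day1=[x1])))
        assert t.dX.iloc[0] == dx
        assert t.rdX.iloc[0] == pytest.approx(rdx)

    def test_zero_denominator_flagged(self):
        t = derive_changes(pd.DataFrame(dict(X_day0=[5.0, 0.0],
                                             X_day1=[-5.0, 0.0])))
        assert not t.rdX_defined.iloc[0]  # 5 + (-5) = 0
        assert np.isnan(t.rdX.iloc[0])
        assert t.rdX_defined.sum() == 0

    def test_relative_change_bounded_for_positive_activity(self, rng):
        x0 = rng.uniform(1, 100, 500)
        x1 = rng.uniform(1, 100, 500)
        t = derive_changes(pd.DataFrame(dict(X_day0=x0, X_day1=x1)))
        assert t.rdX.between(-1, 1).all()


class TestPairwiseTests:
    def test_identical_regions_nonsignificant(self, grid512, rng):
        t = _table(grid512, rng)
        a = t[t.region == "C1"].copy()
        b = a.copy()
        b["region"] = "C2"
        rep = pairwise_region_tests(pd.concat([a, b]), "II/III", "X")
        row = rep[(rep.region_a == "C1") & (rep.region_b == "C2")].iloc[0]
        assert row.p_corrected == 1.0
        assert row.delta_std == 0.0

    def test_strong_shift_detected(self, grid512, rng):
        t = _table(grid512, rng, n_per_region=200,
                   shift=lambda rid: 30 if rid == "A1" else 0)
        rep = pairwise_region_tests(t, "II/III", "X")
        sub = rep[(rep.region_a == "A1") | (rep.region_b == "A1")]
        assert (sub.p_corrected < 0.01).all()

    def test_delta_std_formula(self):
        t = pd.DataFrame(dict(
            neuron_id=range(8),
            region=["C1"] * 4 + ["C2"] * 4, layer=["IV"] * 8,
            X=[0, 10, 20, 30, 0, 30, 60, 90]))  # sd ratio 1:3
        rep = pairwise_region_tests(t, "IV", "X")
        row = rep[(rep.region_a == "C1") & (rep.region_b == "C2")].iloc[0]
        assert row.delta_std == pytest.approx(1.0)

    def test_small_region_flagged_untestable(self, grid512, rng):
        t = _table(grid512, rng, n_per_region=5)
        t = t[~((t.region == "E3") & (t.neuron_id % 5 != 0))]
        rep = pairwise_region_tests(t, "II/III", "X")
        sub = rep[(rep.region_a == "E3") | (rep.region_b == "E3")]
        assert (~sub.testable).all()
        assert rep.testable.sum() == N_REGION_PAIRS - len(sub)

    def test_report_covers_all_120_pairs(self, grid512, rng):
        rep = pairwise_region_tests(_table(grid512, rng), "II/III", "X")
        assert len(rep) == N_REGION_PAIRS
        assert set(rep.type_pair) == set(TYPE_PAIRS)


class TestSummarizeBias:
    def test_homogeneous_null_gives_unit_ratios(self, grid512, rng):
        rep = pairwise_region_tests(_table(grid512, rng), "II/III", "X")
        summ = summarize_bias(rep)
        assert (summ.c_p == 1.0).all()
        assert summ.delta_c.to_numpy() == pytest.approx(np.ones(6))

    def test_printed_formula_ratio(self):
        rows = []
        for tp, n, nsig in [("C-C", 6, 6), ("E-E", 28, 28), ("A-A", 6, 6),
                            ("C-E", 32, 32), ("E-A", 32, 32), ("C-A", 16, 4)]:
            for i in range(n):
                rows.append(dict(layer="IV", measure="X", region_a="x",
                                 region_b="y", type_pair=tp,
                                 p_corrected=1.0 if i < nsig else 0.001,
                                 delta_std=0.1, testable=True))
        summ = summarize_bias(pd.DataFrame(rows))
        # c_p(C-A) = 0.25, <c_p>_same = 1 -> DeltaC(C-A) = 0.25
        assert summ.loc["C-A", "c_p"] == pytest.approx(0.25)
        assert summ.loc["C-A", "delta_c"] == pytest.approx(0.25)
        assert summ.loc["E-E", "delta_c"] == pytest.approx(1.0)

    def test_center_angle_bias_detected_when_scaled(self, grid512, rng):
        # periphery regions get lower mean and std, as under vignetting
        fade = {"C": 1.0, "E": 0.75, "A": 0.45}
        t = _table(grid512, rng, n_per_region=120,
                   shift=lambda rid: 50 * (fade[rid[0]] - 1),
                   scale=lambda rid: fade[rid[0]])
        summ = summarize_bias(pairwise_region_tests(t, "II/III", "X"))
        assert summ.loc["C-A", "delta_c"] < summ.loc["E-E", "delta_c"]
        assert summ.loc["C-A", "delta_stdev"] > summ.loc["E-E", "delta_stdev"]


class TestHighlyActive:
    def test_all_equal_gives_empty_set(self):
        t = pd.DataFrame(dict(neuron_id=range(5), layer=["IV"] * 5,
                              rdX=[0.2] * 5))
        assert highly_active_cells(t, "IV") == set()

    def test_single_extreme_cell_flagged(self, rng):
        t = pd.DataFrame(dict(neuron_id=range(1001), layer=["IV"] * 1001,
                              rdX=np.append(rng.normal(0, 0.1, 1000), 0.9)))
        assert 1000 in highly_active_cells(t, "IV")

    def test_normal_tail_fraction(self, rng):
        n = 200_000
        t = pd.DataFrame(dict(neuron_id=range(n), layer=["IV"] * n,
                              rdX=rng.normal(0, 0.1, n)))
        frac = len(highly_active_cells(t, "IV")) / n
        assert frac == pytest.approx(0.00135, abs=0.0005)

    def test_overlap_rates(self):
        assert overlap_rate({1, 2, 3}, {1, 2, 3}) == 1.0
        assert overlap_rate({1, 2}, {3, 4}) == 0.0
        assert overlap_rate({1, 2, 3, 4}, {3, 4, 5}) == 0.5
        with pytest.raises(ValueError):
            overlap_rate(set(), {1})
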