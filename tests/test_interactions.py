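"""DI/HOI term computation: kernel, hand-worked values, batch vs oracle."""

import numpy as np
import pandas as pd
import pytest

import treehoi as th
from conftest import make_plot, random_plot, terms_frame_equal


class TestKernelWeight:
    def test_identity_case(self):
        for u, v in [(0, 0), (1, 1), (2, 0.5), (0.3, 1.7)]:
            assert th.kernel_weight(1.0, 1.0, th.KernelParams(u, v, 10)) == 1.0

    def test_simple_ratio(self):
        assert th.kernel_weight(10, 2, th.KernelParams(1, 1, 20)) == 5.0

    def test_truncation_is_exact_zero(self):
        p = th.KernelParams(1, 1, 20)
        assert th.kernel_weight(10, 25, p) == 0.0
        assert th.kernel_weight(10, 20, p) == 0.0   # boundary d == R excluded

    def test_coincident_stems_error(self):
        with pytest.raises(th.CoincidentStemsError):
            th.kernel_weight(10, 0.0, th.KernelParams(1, 1, 20))


class TestHandWorkedValues:
    """Three-tree configurations evaluated by hand against the definitions."""

    def test_di_two_groups(self):
        # A at 3 m with DBH 8 -> 8/3; B at 4 m with DBH 2 -> 0.5;
        # B at 30 m is beyond R = 20 and contributes nothing.
        plot = make_plot([("f", "A", 0, 0, 5), ("n1", "A", 3, 0, 8),
                          ("n2", "B", 4, 0, 2), ("n3", "B", 30, 0, 50)],
                         bounds=(-50, 50, -50, 50))
        di = th.di_terms("f", plot, th.KernelParams(1, 1, 20))
        assert di["A"] == pytest.approx(8 / 3, abs=1e-12)
        assert di["B"] == pytest.approx(0.5, abs=1e-12)

    def test_hoi_asymmetric_pair(self):
        # transmitter A (dbh 2, 3 m from focal), initiator B (dbh 5, 4 m from
        # the transmitter, 5 m from the focal): hoi[A,B] = (2/3)(5/4);
        # swapping roles gives hoi[B,A] = (5/5)(2/4) — not equal.
        plot = make_plot([("f", "X", 0, 0, 5), ("t", "A", 3, 0, 2),
                          ("i", "B", 3, 4, 5)], bounds=(-20, 20, -20, 20))
        hoi = th.hoi_terms("f", plot, th.KernelParams(1, 1, 10))
        assert hoi[("A", "B")] == pytest.approx(5 / 6, abs=1e-12)
        assert hoi[("B", "A")] == pytest.approx(0.5, abs=1e-12)

    def test_single_neighbour_has_no_chains(self):
        plot = make_plot([("f", "A", 0, 0, 5), ("n", "A", 2, 0, 9)],
                         bounds=(-20, 20, -20, 20))
        hoi = th.hoi_terms("f", plot, th.KernelParams(1, 1, 10))
        assert all(v == 0.0 for v in hoi.values())


class TestDegenerateKernel:
    """At u = v = 0 the terms are pure neighbour and chain counts."""

    @pytest.fixture
    def plot(self):
        # focal at origin; A at 1 and 5 m; B at 3 m and at 12 m (beyond R).
        return make_plot([("f", "A", 0, 0, 5), ("a1", "A", 1, 0, 8),
                          ("a2", "A", 5, 0, 100), ("b1", "B", 0, 3, 2),
                          ("b2", "B", 12, 0, 60)],
                         bounds=(-20, 20, -20, 20))

    def test_di_counts(self, plot):
        di = th.di_terms("f", plot, th.KernelParams(0, 0, 10))
        assert di == {"A": 2.0, "B": 1.0}

    def test_beyond_radius_contributes_zero_even_at_v0(self, plot):
        # regression against the d = infinity substitution: inf**0 == 1
        # would count b2 (12 m > R) into di_B
        di = th.di_terms("f", plot, th.KernelParams(0, 0, 10))
        assert di["B"] == 1.0
        di = th.di_terms("f", plot, th.KernelParams(0.7, 0, 10))
        assert di["B"] == pytest.approx(2.0 ** 0.7)

    def test_hoi_chain_counts(self, plot):
        # enumerate ordered chains by brute force from the distance matrix
        t = plot.trees
        xy = t[["x", "y"]].to_numpy(float)
        R = 10.0
        expected = {(j, k): 0 for j in ["A", "B"] for k in ["A", "B"]}
        for p in range(len(t)):
            if t.at[p, "id"] == "f":
                continue
            d1 = np.hypot(*(xy[p] - xy[0]))
            if d1 >= R:
                continue
            for q in range(len(t)):
                if q == p or t.at[q, "id"] == "f":
                    continue
                if np.hypot(*(xy[q] - xy[p])) < R:
                    expected[(t.at[p, "group"], t.at[q, "group"])] += 1
        hoi = th.hoi_terms("f", plot, th.KernelParams(0, 0, R))
        assert hoi == {k: float(v) for k, v in expected.items()}


class TestBatchConsistency:
    def test_batch_equals_per_tree_calls(self):
        rng = np.random.default_rng(5)
        plot = random_plot(rng, n=50, side=40)
        params = th.KernelParams(1.2, 0.6, 12)
        batch = th.terms_batch(plot, params,
                               focal_ids=plot.trees["id"].tolist())
        for _, row in batch.iloc[::7].iterrows():
            di = th.di_terms(row["focal_id"], plot, params)
            hoi = th.hoi_terms(row["focal_id"], plot, params)
            for g, val in di.items():
                assert row[f"di_{g}"] == pytest.approx(val, rel=1e-10)
            for (j, k), val in hoi.items():
                assert row[f"hoi_{j}_{k}"] == pytest.approx(val, rel=1e-10)

    def test_batch_equals_oracle(self):
        rng = np.random.default_rng(11)
        plot = random_plot(rng, n=60, side=40)
        params = th.KernelParams(0.8, 1.4, 15)
        batch = th.terms_batch(plot, params,
                               focal_ids=plot.trees["id"].tolist())
        for _, row in batch.iloc[::11].iterrows():
            oracle = th.oracle_terms(row["focal_id"], plot, params)
            assert terms_frame_equal(row, oracle) < 1e-10

    def test_ordered_pair_completeness(self):
        rng = np.random.default_rng(2)
        plot = random_plot(rng, n=30, side=30, groups=("A", "B", "C"))
        batch = th.terms_batch(plot, th.KernelParams(1, 1, 10),
                               focal_ids=plot.trees["id"].tolist())
        assert sum(c.startswith("hoi_") for c in batch.columns) == 9
        single = random_plot(rng, n=20, side=30, groups=("A",))
        batch1 = th.terms_batch(single, th.KernelParams(1, 1, 10),
                                focal_ids=single.trees["id"].tolist())
        assert [c for c in batch1.columns if c.startswith("hoi_")] == ["hoi_A_A"]

    def test_focal_initiator_flag(self):
        # with the flag, chains neighbour -> focal -> focal's neighbour count
        plot = make_plot([("f", "A", 0, 0, 5), ("t", "A", 3, 0, 2),
                          ("i", "A", 6, 0, 4)], bounds=(-20, 20, -20, 20))
        params = th.KernelParams(1, 1, 5)
        strict = th.hoi_terms("f", plot, params)
        loose = th.hoi_terms("f", plot, params, allow_focal_initiator=True)
        # only "t" is within R of the focal; "i" is within R of "t";
        # allowing the focal as initiator adds the chain f -> t.
        assert loose[("A", "A")] > strict[("A", "A")]
        b_strict = th.terms_batch(plot, params, focal_ids=["f"])
        b_loose = th.terms_batch(plot, params, focal_ids=["f"],
                                 allow_focal_initiator=True)
        assert b_strict["hoi_A_A"].iloc[0] == pytest.approx(strict[("A", "A")])
        assert b_loose["hoi_A_A"].iloc[0] == pytest.approx(loose[("A", "A")])

    def test_coincident_stems_named_in_batch(self):
        plot = make_plot([("x1", "A", 1, 1, 5), ("x2", "A", 1, 1, 7)],
                         bounds=(0, 10, 0, 10))
        with pytest.raises(th.CoincidentStemsError, match="x1.*x2|x2.*x1"):
            th.terms_batch(plot, th.KernelParams(1, 1, 5), focal_ids=["x1"])


class TestInvariants:
    @pytest.mark.parametrize("u,v", [(0.0, 0.0), (1.0, 0.8), (2.0, 1.5)])
    def test_monotone_in_radius(self, u, v):
        rng = np.random.default_rng(13)
        plot = random_plot(rng, n=80, side=40)
        ids = plot.trees["id"].tolist()
        small = th.terms_batch(plot, th.KernelParams(u, v, 8), focal_ids=ids)
        big = th.terms_batch(plot, th.KernelParams(u, v, 16), focal_ids=ids)
        cols = [c for c in small.columns if c != "focal_id"]
        assert (big[cols].to_numpy() >= small[cols].to_numpy() - 1e-12).all()

    @pytest.mark.parametrize("u,v,c", [(1.0, 0.8, 2.0), (0.5, 1.2, 3.0)])
    def test_dbh_scaling(self, u, v, c):
        # DBH -> c*DBH multiplies di by c^u and hoi by c^(2u)
        rng = np.random.default_rng(17)
        plot = random_plot(rng, n=60, side=40)
        scaled = th.CensusPlot(
            trees=plot.trees.assign(dbh0=plot.trees["dbh0"] * c),
            bounds=plot.bounds)
        params = th.KernelParams(u, v, 12)
        ids = plot.trees["id"].tolist()
        base = th.terms_batch(plot, params, focal_ids=ids)
        big = th.terms_batch(scaled, params, focal_ids=ids)
        for col in base.columns:
            if col.startswith("di_"):
                np.testing.assert_allclose(big[col], base[col] * c ** u,
                                           rtol=1e-10)
            elif col.startswith("hoi_"):
                np.testing.assert_allclose(big[col], base[col] * c ** (2 * u),
                                           rtol=1e-10)
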