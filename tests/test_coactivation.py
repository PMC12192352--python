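"""Binning, forward smoothing, Jaccard / Z-Jaccard, distance relation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import casim
from casim.coactivation import (
    BinnedEventMatrix,
    SmoothedEventMatrix,
    _pair_null_intersections,
    bin_events,
    distance_vs_synchrony,
    forward_smooth,
    jaccard_matrix,
    synchronized_proportion,
    z_jaccard,
)


def _events(d, segment):
    return casim.EventTrains(
        {c: np.asarray(t, float) for c, t in d.items()},
        {c: np.ones(len(t)) for c, t in d.items()},
        segment,
    )


def _smoothed(rows):
    y = np.asarray(rows, dtype=np.uint8)
    return SmoothedEventMatrix(list(range(len(rows))), y, 0.2, 4)


def jaccard_set_oracle(y_star):
    """|A n B| / |A u B| over active-bin index sets, straight from the sets."""
    C = y_star.shape[0]
    sets = [set(np.flatnonzero(r)) for r in y_star]
    out = np.full((C, C), np.nan)
    for i in range(C):
        for j in range(C):
            union = sets[i] | sets[j]
            if union:
                out[i, j] = len(sets[i] & sets[j]) / len(union)
    return out


class TestBinEvents:
    def test_definitional_placement(self):
        ev = _events({"a": [0.05, 0.19, 0.21]}, (0.0, 0.6))
        bm = bin_events(ev, 0.2)
        np.testing.assert_array_equal(bm.y[0], [1, 1, 0])

    def test_bin_edge_half_open(self):
        ev = _events({"a": [0.2]}, (0.0, 0.6))
        bm = bin_events(ev, 0.2)
        np.testing.assert_array_equal(bm.y[0], [0, 1, 0])

    def test_bin_count_600s(self):
        ev = _events({"a": [1.0]}, (0.0, 600.0))
        assert bin_events(ev, 0.2).n_bins == 3000

    def test_trailing_partial_bin_discarded(self):
        ev = _events({"a": [0.65]}, (0.0, 0.7))
        bm = bin_events(ev, 0.2)
        assert bm.n_bins == 3  # the event in the 0.1 s remainder is dropped

    def test_binary_not_counts(self):
        ev = _events({"a": [0.01, 0.02, 0.03]}, (0.0, 0.4))
        assert bin_events(ev, 0.2).y[0, 0] == 1

    def test_segment_shorter_than_bin_rejected(self):
        ev = _events({"a": [0.05]}, (0.0, 0.1))
        with pytest.raises(ValueError):
            bin_events(ev, 0.2)


class TestForwardSmooth:
    def test_definitional_example(self):
        bm = BinnedEventMatrix([0], np.array([[0, 0, 0, 0, 1, 0, 0]], np.uint8), 0.2)
        sm = forward_smooth(bm, 4)
        np.testing.assert_array_equal(sm.y_star[0], [1, 1, 1, 1, 1, 0, 0])

    def test_all_zero_row_unchanged(self):
        bm = BinnedEventMatrix([0], np.zeros((1, 10), np.uint8), 0.2)
        assert forward_smooth(bm).y_star.sum() == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=40),
        st.integers(0, 6),
    )
    def test_matches_definition_and_monotone(self, bits, look):
        y = np.array([bits], dtype=np.uint8)
        sm = forward_smooth(BinnedEventMatrix([0], y, 0.2), look)
        T = y.shape[1]
        expect = [
            int(any(y[0, t + j] for j in range(look + 1) if t + j < T))
            for t in range(T)
        ]
        np.testing.assert_array_equal(sm.y_star[0], expect)
        assert np.all(sm.y_star >= y)  # adding events never clears smoothed bins


class TestJaccard:
    def test_hand_evaluated_formula(self):
        sm = _smoothed([[1, 0, 1, 0, 1, 0], [1, 0, 0, 0, 1, 1]])
        assert jaccard_matrix(sm)[0, 1] == pytest.approx(0.5)

    def test_identical_rows_give_one(self):
        sm = _smoothed([[1, 0, 1], [1, 0, 1]])
        assert jaccard_matrix(sm)[0, 1] == pytest.approx(1.0)

    def test_disjoint_rows_give_zero(self):
        sm = _smoothed([[1, 0, 0], [0, 1, 1]])
        assert jaccard_matrix(sm)[0, 1] == pytest.approx(0.0)

    def test_both_empty_flagged_nan(self):
        sm = _smoothed([[0, 0, 0], [0, 0, 0]])
        assert np.isnan(jaccard_matrix(sm)[0, 1])

    def test_matches_set_oracle_random(self, rng):
        for _ in range(50):
            y = (rng.random((rng.integers(2, 8), rng.integers(5, 60))) < 0.3)
            sm = SmoothedEventMatrix(list(range(y.shape[0])), y.astype(np.uint8), 0.2, 4)
            got = jaccard_matrix(sm)
            np.testing.assert_allclose(got, jaccard_set_oracle(sm.y_star))

    def test_cell_permutation_equivariance(self, rng):
        y = (rng.random((6, 50)) < 0.3).astype(np.uint8)
        sm = SmoothedEventMatrix(list(range(6)), y, 0.2, 4)
        perm = rng.permutation(6)
        smp = SmoothedEventMatrix(list(perm), y[perm], 0.2, 4)
        np.testing.assert_allclose(
            jaccard_matrix(smp), jaccard_matrix(sm)[np.ix_(perm, perm)]
        )


class TestZJaccard:
    def test_rng_required(self):
        sm = _smoothed([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="rng"):
            z_jaccard(sm, 100)

    def test_fft_rotation_equals_explicit_roll(self, rng):
        a = (rng.random(101) < 0.3).astype(np.int64)
        b = (rng.random(101) < 0.3).astype(np.int64)
        inter = _pair_null_intersections(a, b)
        for o in (0, 1, 7, 100):
            rolled = np.roll(b, -o)  # rolled[t] = b[(t+o) % T]
            assert inter[o] == int(np.sum(a * rolled))
            assert rolled.sum() == b.sum()  # rotation conserves the row sum

    def test_silent_cell_pair_invalid(self, rng):
        y = np.zeros((2, 200), np.uint8)
        y[0, ::10] = 1
        sm = SmoothedEventMatrix([0, 1], y, 0.2, 4)
        ps = z_jaccard(sm, 100, rng=rng)
        row = ps.table.iloc[0]
        assert not row["valid"]
        assert row["null_sd"] == 0.0

    def test_planted_common_input_detected(self, rng):
        cfg = casim.SimConfig(
            n_cells=4, duration_s=600.0, base_rate_hz=0.1, seed=13,
            synchrony_spec=[casim.SynchronySpec((0, 1), 0.1)], make_traces=False,
        )
        b = casim.generate_session(cfg)
        sm = forward_smooth(bin_events(b.events))
        ps = z_jaccard(sm, 200, rng=rng)
        pair = b.ground_truth.synchrony_pairs[0]
        z = ps.table.set_index(["cell_a", "cell_b"]).loc[pair, "z"]
        assert z > 1.96


class TestSynchronizedProportion:
    def test_counting(self):
        import pandas as pd

        table = pd.DataFrame(
            dict(
                cell_a=list("aaabbbcccd"),
                cell_b=list("bcdcdedefe"),
                z=[2.5, -3.0, 0.5, 1.0, -0.2, 2.0, 1.2, 0.3, 0.1, 1.9],
                valid=True,
                jaccard=0.1,
                null_mean=0.1,
                null_sd=0.01,
            )
        )
        ps = casim.coactivation.PairSynchrony(table, 100, 0.2, 4)
        assert synchronized_proportion(ps) == pytest.approx(0.3)

    def test_all_below_threshold_zero(self):
        import pandas as pd

        table = pd.DataFrame(
            dict(cell_a=["a"], cell_b=["b"], z=[1.0], valid=[True],
                 jaccard=[0.1], null_mean=[0.1], null_sd=[0.01])
        )
        ps = casim.coactivation.PairSynchrony(table, 100, 0.2, 4)
        assert synchronized_proportion(ps) == 0.0

    def test_all_invalid_rejected(self):
        import pandas as pd

        table = pd.DataFrame(
            dict(cell_a=["a"], cell_b=["b"], z=[np.nan], valid=[False],
                 jaccard=[np.nan], null_mean=[0.0], null_sd=[0.0])
        )
        ps = casim.coactivation.PairSynchrony(table, 100, 0.2, 4)
        with pytest.raises(ValueError):
            synchronized_proportion(ps)


class TestDistanceVsSynchrony:
    def test_three_four_five_distance(self, tiny_bundle, rng):
        sm = forward_smooth(bin_events(tiny_bundle.events, segment=(0.0, 6.0)))
        ps = z_jaccard(sm, 100, rng=rng)
        table, _ = distance_vs_synchrony(ps, tiny_bundle.cell_map)
        got = table.set_index(["cell_a", "cell_b"])
        if ("a", "b") in got.index:
            assert got.loc[("a", "b"), "distance"] == pytest.approx(50.0)

    def test_flat_relation_recovered(self):
        """When Z is independent of distance the loess curve stays flat."""
        import pandas as pd

        rng = np.random.default_rng(3)
        n = 500
        table = pd.DataFrame(
            dict(
                cell_a=[f"x{i}" for i in range(n)],
                cell_b=[f"y{i}" for i in range(n)],
                jaccard=0.1, null_mean=0.1, null_sd=0.05,
                z=rng.normal(0, 1, n),
                valid=True,
            )
        )
        cents = {f"x{i}": (0.0, 0.0) for i in range(n)}
        cents.update({f"y{i}": (rng.uniform(10, 300), 0.0) for i in range(n)})
        ps = casim.coactivation.PairSynchrony(table, 100, 0.2, 4)
        tab, curve = distance_vs_synchrony(ps, casim.CellMap(cents))
        assert curve is not None
        assert np.all(np.abs(curve["z_fit"] - tab["z"].mean()) < 0.3)

    def test_degenerate_distances_return_table_only(self, rng):
        import pandas as pd

        table = pd.DataFrame(
            dict(
                cell_a=[f"x{i}" for i in range(6)],
                cell_b=[f"y{i}" for i in range(6)],
                jaccard=0.1, null_mean=0.1, null_sd=0.05,
                z=rng.normal(0, 1, 6), valid=True,
            )
        )
        cents = {c: (5.0, 5.0) for c in table["cell_a"]} | {
            c: (8.0, 9.0) for c in table["cell_b"]
        }
        ps = casim.coactivation.PairSynchrony(table, 100, 0.2, 4)
        tab, curve = distance_vs_synchrony(ps, casim.CellMap(cents))
        assert curve is None
        assert len(tab) == 6
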