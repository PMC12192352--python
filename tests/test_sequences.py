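"""Sequence enumeration, greedy counting, circular-shift null, summaries."""

import numpy as np
import pytest

import casim
from casim.sequences import (
    SequenceConfig,
    _pair_counts_shifted,
    circular_shift_times,
    count_occurrences,
    detect_sequences,
    enumerate_and_count,
    null_quantile,
    sequence_null,
    sequence_spatial_distribution,
    summarize_sequences,
    validate_occurrences,
)


def _events(d, segment=(0.0, 600.0)):
    return casim.EventTrains(
        {c: np.asarray(t, float) for c, t in d.items()},
        {c: np.ones(len(t)) for c, t in d.items()},
        segment,
    )


class TestCountOccurrences:
    def test_forced_triplet_counted_five_times(self):
        a = np.array([10.0, 70.0, 130.0, 190.0, 250.0])
        cnt, occs = count_occurrences([a, a + 0.5, a + 1.0], 0.05, 2.0, record=True)
        assert cnt == 5
        assert len(occs) == 5
        for occ in occs:
            np.testing.assert_allclose(np.diff(occ), 0.5)

    def test_gap_rule_below_minimum(self):
        a = np.array([10.0, 70.0, 130.0])
        cnt, _ = count_occurrences([a, a + 0.01], 0.05, 2.0)
        assert cnt == 0

    def test_lag_rule_beyond_maximum(self):
        a = np.array([10.0, 70.0, 130.0])
        cnt, _ = count_occurrences([a, a + 2.5], 0.05, 2.0)
        assert cnt == 0

    def test_boundary_gap_exactly_max_lag_included(self):
        cnt, _ = count_occurrences(
            [np.array([0.0]), np.array([2.0])], 0.05, 2.0
        )
        assert cnt == 1

    def test_boundary_gap_exactly_min_excluded(self):
        cnt, _ = count_occurrences(
            [np.array([0.0]), np.array([0.05])], 0.05, 2.0
        )
        assert cnt == 0

    def test_backtracking_finds_feasible_completion(self):
        """The earliest B would dead-end; the counter must try the later one."""
        a = np.array([0.0])
        b = np.array([0.1, 1.0])
        c = np.array([2.5])  # only reachable from b=1.0
        cnt, occs = count_occurrences([a, b, c], 0.05, 2.0, record=True)
        assert cnt == 1
        assert occs[0] == (0.0, 1.0, 2.5)

    def test_events_consumed_across_occurrences(self):
        a = np.array([0.0, 0.5])
        b = np.array([1.0])  # reachable from both anchors but usable once
        cnt, _ = count_occurrences([a, b], 0.05, 2.0)
        assert cnt == 1


class TestDownwardClosure:
    def test_motif_count_never_exceeds_contiguous_submotifs(self, rng):
        for _ in range(100):
            times = [np.sort(rng.uniform(0, 30, rng.integers(0, 10))) for _ in range(3)]
            c_abc, _ = count_occurrences(times, 0.05, 2.0)
            c_ab, _ = count_occurrences(times[:2], 0.05, 2.0)
            c_bc, _ = count_occurrences(times[1:], 0.05, 2.0)
            assert c_abc <= c_ab
            assert c_abc <= c_bc


class TestEnumerateAndCount:
    def test_planted_pair_enumerated(self):
        a = np.array([10.0, 70.0, 130.0, 190.0, 250.0])
        ev = _events({"A": a, "B": a + 0.5, "C": []})
        counts = enumerate_and_count(ev, SequenceConfig())
        assert counts[("A", "B")] == 5
        assert ("B", "A") in counts

    def test_extension_only_from_frequent_motifs(self):
        a = np.array([10.0, 70.0, 130.0, 190.0, 250.0])
        ev = _events({"A": a, "B": a + 0.5, "C": a + 1.0})
        counts = enumerate_and_count(ev, SequenceConfig())
        assert counts[("A", "B", "C")] == 5
        # (A, C) occurs 5x too (1 s steps), so its extensions are also present
        assert counts[("A", "C")] == 5

    def test_window_longer_than_segment_rejected(self):
        ev = _events({"A": [1.0]}, segment=(0.0, 100.0))
        with pytest.raises(ValueError, match="window"):
            enumerate_and_count(ev, SequenceConfig())


class TestSequenceNull:
    def test_rng_required(self, spontaneous_session):
        with pytest.raises(ValueError, match="rng"):
            sequence_null(
                spontaneous_session.events, [("c000", "c001")], SequenceConfig()
            )

    def test_planted_motif_null_counts_near_zero(self):
        """Shuffling silent-except-plants trains leaves only wrap coincidences."""
        # aperiodic plant times: an evenly spaced grid could re-align wholesale
        # under a circular shift, which is not the planted-motif situation
        a = np.sort(np.random.default_rng(8).uniform(20, 580, 10))
        ev = _events({"A": a, "B": a + 0.5, "C": a + 1.0})
        cfg = SequenceConfig()
        nulls = sequence_null(
            ev, [("A", "B", "C")], cfg, rng=np.random.default_rng(0)
        )
        assert np.all(nulls[("A", "B", "C")] <= 2)
        assert np.mean(nulls[("A", "B", "C")]) < 0.5

    def test_circular_shift_conserves_events_and_range(self, rng):
        t = np.sort(rng.uniform(0, 600, 50))
        for _ in range(20):
            s = circular_shift_times(t, rng.uniform(0, 600), (0.0, 600.0))
            assert s.size == t.size
            assert np.all((s >= 0) & (s < 600))
            assert np.all(np.diff(s) >= 0)

    def test_vectorized_pair_counts_match_scalar(self, rng):
        for trial in range(100):
            L = 30.0
            a = np.sort(rng.uniform(0, L, rng.integers(0, 10)))
            b = np.sort(rng.uniform(0, L, rng.integers(0, 10)))
            offs = rng.uniform(0, L, 8)
            vec = _pair_counts_shifted(a, b, offs, (0.0, L), 0.05, 2.0)
            for k, o in enumerate(offs):
                c, _ = count_occurrences(
                    [a, circular_shift_times(b, o, (0.0, L))], 0.05, 2.0
                )
                assert c == vec[k]

    def test_null_brackets_observed_for_independent_cells(self):
        b = casim.generate_session(
            casim.SimConfig(n_cells=2, duration_s=600.0, base_rate_hz=0.2,
                            seed=17, make_traces=False)
        )
        ev = b.events
        motif = tuple(ev.cells)
        cnt, _ = count_occurrences(
            [ev.times[motif[0]], ev.times[motif[1]]], 0.05, 2.0
        )
        nulls = sequence_null(
            ev, [motif], SequenceConfig(n_shuffles=200),
            rng=np.random.default_rng(1),
        )[motif]
        assert nulls.min() <= cnt <= null_quantile(nulls, 0.99) + 2


class TestDetectSequences:
    def test_planted_motif_recovered(self):
        cfg = casim.SimConfig(
            n_cells=20, duration_s=600.0, base_rate_hz=0.05, seed=2,
            motif_spec=[casim.MotifSpec((0, 1, 2), (0.5, 0.5), 6)],
            make_traces=False,
        )
        b = casim.generate_session(cfg)
        motifs = detect_sequences(
            b.events, SequenceConfig(n_shuffles=300), rng=np.random.default_rng(3)
        )
        planted = tuple(b.ground_truth.motifs[0]["cells"])
        hit = [m for m in motifs if m.cells == planted]
        assert hit and hit[0].significant
        assert validate_occurrences(motifs, SequenceConfig())

    def test_three_repetitions_never_significant(self):
        """The minimum-repetition gate holds regardless of the null."""
        a = np.array([50.0, 250.0, 450.0])
        ev = _events({"A": a, "B": a + 0.5})
        motifs = detect_sequences(
            ev, SequenceConfig(n_shuffles=200), rng=np.random.default_rng(4)
        )
        assert all(not m.significant for m in motifs)

    def test_subsumed_pairs_flagged_but_retained(self):
        a = np.linspace(20, 580, 8)
        ev = _events({"A": a, "B": a + 0.5, "C": a + 1.0})
        motifs = detect_sequences(
            ev, SequenceConfig(n_shuffles=200), rng=np.random.default_rng(5)
        )
        by_cells = {m.cells: m for m in motifs}
        abc = by_cells[("A", "B", "C")]
        ab = by_cells[("A", "B")]
        assert abc.significant and not abc.subsumed
        assert ab.significant and ab.subsumed

    def test_determinism_under_fixed_seed(self, spontaneous_session):
        cfg = SequenceConfig(n_shuffles=100)
        m1 = detect_sequences(
            spontaneous_session.events, cfg, rng=np.random.default_rng(6)
        )
        m2 = detect_sequences(
            spontaneous_session.events, cfg, rng=np.random.default_rng(6)
        )
        assert [(m.cells, m.count, m.significant) for m in m1] == [
            (m.cells, m.count, m.significant) for m in m2
        ]


class TestNullQuantile:
    def test_order_statistic_definition(self):
        null = np.arange(1, 101)  # 1..100
        assert null_quantile(null, 0.95) == 95.0
        assert null_quantile(null, 0.5) == 50.0


class TestSummaries:
    def _motif(self, cells, count, sig=True):
        return casim.SequenceMotif(cells, [], count, significant=sig)

    def test_normalized_count(self):
        motifs = [self._motif(("a", "b"), 5) for _ in range(13)]
        s = summarize_sequences(motifs, 40)
        assert s.normalized_n == pytest.approx(0.325)

    def test_no_sequences_all_zero(self):
        s = summarize_sequences([], 18)
        assert s.n_significant == 0
        assert s.normalized_n == 0.0
        assert s.proportion_cells_in_sequences == 0.0

    def test_member_proportion(self):
        motifs = [
            self._motif(("c1", "c2"), 4),
            self._motif(("c2", "c3"), 4),
            self._motif(("c3", "c4"), 4),
        ]
        s = summarize_sequences(motifs, 18)
        assert s.proportion_cells_in_sequences == pytest.approx(4 / 18)

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            summarize_sequences([], 0)


class TestSpatialDistribution:
    def test_uniform_members_not_rejected(self, rng):
        cents = {f"c{i}": tuple(rng.uniform(0, 400, 2)) for i in range(40)}
        cmap = casim.CellMap(cents)
        members = rng.choice(40, 12, replace=False)
        motifs = [
            casim.SequenceMotif(
                (f"c{members[2*i]}", f"c{members[2*i+1]}"), [], 4, significant=True
            )
            for i in range(6)
        ]
        out = sequence_spatial_distribution(motifs, cmap)
        assert out["ks"]["p_value"] > 0.01

    def test_clustered_members_rejected(self, rng):
        cents = {f"c{i}": tuple(rng.uniform(0, 400, 2)) for i in range(40)}
        for i in range(12):  # plant a tight spatial cluster
            cents[f"c{i}"] = (200.0 + rng.uniform(0, 4), 200.0 + rng.uniform(0, 4))
        cmap = casim.CellMap(cents)
        motifs = [
            casim.SequenceMotif((f"c{2*i}", f"c{2*i+1}"), [], 4, significant=True)
            for i in range(6)
        ]
        out = sequence_spatial_distribution(motifs, cmap)
        assert out["ks"]["p_value"] < 0.01

    def test_single_member_skips_comparison(self):
        cmap = casim.CellMap({"a": (0, 0), "b": (1, 1)})
        out = sequence_spatial_distribution([], cmap)
        assert out["ks"] is None
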