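"""Detection of precisely timed multi-cell sequences of calcium events.

A *sequence* (motif) is an ordered tuple of two or more distinct cells
whose events recur in that temporal order, each consecutive step falling in
a gap window of (0.05, 2] s — the lower bound rejects simultaneous bursts,
the upper bound limits each step to 2 s.  A motif is accepted as
significant within a 10-min window when it occurs at least 4 times and
more often than the 95th percentile of a circular-shift null in which every
member cell except the first is independently rotated by a random offset
(which preserves each train's internal structure but destroys cross-cell
timing).

Occurrence counting is greedy-earliest and event-disjoint: anchor events
are scanned in time order and each is extended by the earliest unused event
of the next cell in the gap window, with backtracking, so an anchor matches
whenever any completion exists; matched events are consumed.  This makes
the observed count well defined and reproducible; it is tested against an
exhaustive maximum-disjoint-matching oracle on small instances.

Candidate motifs are grown by downward-closure pruning: all ordered pairs
are counted, and only motifs reaching the minimum repetition count are
extended by one cell at a time (a longer motif can never occur more often
than its contiguous sub-motifs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CellId, CellMap, EventTrains, split_windows


@dataclass
class SequenceConfig:
    """Parameters of the sequence search.

    ``max_step_lag_s`` and ``min_intra_gap_s`` bound each consecutive step
    of an occurrence; ``min_repetitions`` and ``null_percentile`` define
    significance; ``window_s`` is the observation window; ``max_order``
    caps the enumeration (the unbounded combinatorial space is intractable
    for 100+ cells).
    """

    max_step_lag_s: float = 2.0
    min_intra_gap_s: float = 0.05
    min_repetitions: int = 4
    window_s: float = 600.0
    n_shuffles: int = 1000
    null_percentile: float = 0.95
    min_order: int = 2
    max_order: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.min_intra_gap_s < self.max_step_lag_s):
            raise ValueError("need 0 < min_intra_gap_s < max_step_lag_s")
        if self.min_repetitions < 2:
            raise ValueError("min_repetitions must be >= 2")
        if not (2 <= self.min_order <= self.max_order):
            raise ValueError("need 2 <= min_order <= max_order")
        if not (0 < self.null_percentile < 1):
            raise ValueError("null_percentile must be in (0, 1)")


@dataclass
class SequenceMotif:
    """An ordered cell tuple with its occurrences and null distribution."""

    cells: tuple[CellId, ...]
    occurrence_times: list[tuple[float, ...]]
    count: int
    null_counts: np.ndarray | None = None
    null_q: float | None = None
    significant: bool = False
    subsumed: bool = False

    @property
    def order(self) -> int:
        return len(self.cells)


@dataclass
class SequenceSummary:
    """Per-window sequence statistics (counts normalised by cell number)."""

    label: str
    n_cells: int
    n_significant: int
    normalized_n: float
    repetitions: list[int] = field(default_factory=list)
    proportion_cells_in_sequences: float = 0.0


# ---------------------------------------------------------------------------
# greedy occurrence counting


def _extend(times, used, gap, lag, t_prev, level, picks) -> bool:
    if level == len(times):
        return True
    t = times[level]
    lo = int(np.searchsorted(t, t_prev + gap, side="right"))
    hi = int(np.searchsorted(t, t_prev + lag, side="right"))
    u = used[level]
    for k in range(lo, hi):
        if u[k]:
            continue
        picks.append(k)
        if _extend(times, used, gap, lag, t[k], level + 1, picks):
            return True
        picks.pop()
    return False


def count_occurrences(
    times: list[np.ndarray],
    min_gap_s: float,
    max_lag_s: float,
    record: bool = False,
) -> tuple[int, list[tuple[float, ...]]]:
    """Greedy-earliest disjoint occurrence count of an ordered motif.

    ``times`` holds one sorted event-time array per motif cell, in motif
    order.  Consecutive matched events must satisfy
    ``min_gap_s < dt <= max_lag_s``.  Events are consumed by the occurrence
    that matches them; anchors are scanned in time order and each anchor
    takes the lexicographically earliest feasible completion.
    """
    used = [np.zeros(t.size, dtype=bool) for t in times]
    count = 0
    occs: list[tuple[float, ...]] = []
    anchors = times[0]
    for i0 in range(anchors.size):
        picks = [i0]
        if _extend(times, used, min_gap_s, max_lag_s, anchors[i0], 1, picks):
            for lvl, idx in enumerate(picks):
                used[lvl][idx] = True
            count += 1
            if record:
                occs.append(tuple(float(times[lvl][idx]) for lvl, idx in enumerate(picks)))
    return count, occs


def _pair_counts_shifted(
    a: np.ndarray,
    b: np.ndarray,
    offsets: np.ndarray,
    segment: tuple[float, float],
    min_gap_s: float,
    max_lag_s: float,
) -> np.ndarray:
    """Greedy pair counts of (a, b + offset mod L) for many offsets at once.

    Vectorised replica of :func:`count_occurrences` for two-cell motifs: the
    pointer sweep over the anchor events is shared, with one lane per
    offset.  Returns an int array of counts, one per offset.
    """
    t0, t1 = segment
    L = t1 - t0
    K = offsets.size
    if b.size == 0 or a.size == 0:
        return np.zeros(K, dtype=np.int64)
    B = np.sort((b[None, :] - t0 + offsets[:, None]) % L, axis=1) + t0
    n = B.shape[1]
    ptr = np.zeros(K, dtype=np.int64)
    counts = np.zeros(K, dtype=np.int64)
    lanes = np.arange(K)
    for t_a in a:
        lo = (B <= t_a + min_gap_s).sum(axis=1)
        np.maximum(ptr, lo, out=ptr)
        open_ = ptr < n
        cand = np.where(open_, B[lanes, np.minimum(ptr, n - 1)], np.inf)
        hit = open_ & (cand <= t_a + max_lag_s)
        counts += hit
        ptr += hit
    return counts


def circular_shift_times(
    t: np.ndarray, offset: float, segment: tuple[float, float]
) -> np.ndarray:
    """Rotate event times by ``offset`` with wrap-around on ``segment``.

    Preserves the event count and the within-train interval structure
    (except across the single wrap point); returns a sorted array.
    """
    t0, t1 = segment
    return np.sort((t - t0 + offset) % (t1 - t0)) + t0


# ---------------------------------------------------------------------------
# enumeration, null, detection


def enumerate_and_count(
    events: EventTrains, cfg: SequenceConfig
) -> dict[tuple[CellId, ...], int]:
    """Count greedy occurrences of all candidate ordered motifs.

    All ordered cell pairs are counted; motifs reaching
    ``cfg.min_repetitions`` are extended one cell at a time (cells are
    distinct within a motif) up to ``cfg.max_order``.
    """
    if events.duration_s + 1e-9 < cfg.window_s:
        raise ValueError("segment shorter than the observation window")
    gap, lag = cfg.min_intra_gap_s, cfg.max_step_lag_s
    cells = events.cells
    t = events.times
    counts: dict[tuple[CellId, ...], int] = {}
    frontier: list[tuple[CellId, ...]] = []
    for a in cells:
        if t[a].size == 0:
            continue
        for b in cells:
            if b == a or t[b].size == 0:
                continue
            motif = (a, b)
            c, _ = count_occurrences([t[a], t[b]], gap, lag)
            counts[motif] = c
            if c >= cfg.min_repetitions:
                frontier.append(motif)
    order = 2
    while frontier and order < cfg.max_order:
        nxt: list[tuple[CellId, ...]] = []
        for motif in frontier:
            for c in cells:
                if c in motif or t[c].size == 0:
                    continue
                ext = motif + (c,)
                cnt, _ = count_occurrences([t[m] for m in ext], gap, lag)
                counts[ext] = cnt
                if cnt >= cfg.min_repetitions:
                    nxt.append(ext)
        frontier = nxt
        order += 1
    return counts


def sequence_null(
    events: EventTrains,
    motifs: list[tuple[CellId, ...]],
    cfg: SequenceConfig,
    rng: np.random.Generator | None = None,
) -> dict[tuple[CellId, ...], np.ndarray]:
    """Null occurrence-count distributions under independent circular shifts.

    Per replicate, every motif cell except the first is independently
    circularly shifted by a uniform offset in ``(0, L)`` (L = segment
    length) and the greedy count recomputed.  Each replicate conserves every
    cell's event count.  Two-cell motifs use the vectorised counter.
    """
    if rng is None:
        raise ValueError("sequence_null requires an rng (reproducibility)")
    gap, lag = cfg.min_intra_gap_s, cfg.max_step_lag_s
    t0, t1 = events.segment
    L = t1 - t0
    out: dict[tuple[CellId, ...], np.ndarray] = {}
    for motif in motifs:
        times = [events.times[c] for c in motif]
        if len(motif) == 2:
            offsets = rng.uniform(0.0, L, size=cfg.n_shuffles)
            out[motif] = _pair_counts_shifted(
                times[0], times[1], offsets, events.segment, gap, lag
            )
        else:
            counts = np.zeros(cfg.n_shuffles, dtype=np.int64)
            for k in range(cfg.n_shuffles):
                shifted = [times[0]]
                for tt in times[1:]:
                    shifted.append(
                        circular_shift_times(tt, rng.uniform(0.0, L), events.segment)
                    )
                counts[k], _ = count_occurrences(shifted, gap, lag)
            out[motif] = counts
    return out


def null_quantile(null_counts: np.ndarray, percentile: float) -> float:
    """Empirical order-statistic quantile: the ceil(p*K)-th sorted value."""
    k = int(np.ceil(percentile * null_counts.size))
    return float(np.sort(null_counts)[k - 1])


def _is_contiguous_subsequence(short: tuple, long: tuple) -> bool:
    n, m = len(short), len(long)
    return any(long[i : i + n] == short for i in range(m - n + 1))


def detect_sequences(
    events: EventTrains,
    cfg: SequenceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SequenceMotif]:
    """Enumerate, count, and test motifs in one observation window.

    A motif is significant when its observed count reaches
    ``cfg.min_repetitions`` *and* strictly exceeds the
    ``cfg.null_percentile`` order statistic of its shuffle null.  The
    minimum-repetition filter applies only to the observed data; null
    counts are raw greedy counts.  Significant motifs contained (as a
    contiguous ordered subsequence) in a longer significant motif are
    flagged ``subsumed`` but retained.
    """
    cfg = cfg or SequenceConfig()
    counts = enumerate_and_count(events, cfg)
    candidates = [
        m
        for m, c in counts.items()
        if c >= cfg.min_repetitions and len(m) >= cfg.min_order
    ]
    nulls = sequence_null(events, candidates, cfg, rng=rng) if candidates else {}
    motifs: list[SequenceMotif] = []
    for m in candidates:
        _, occs = count_occurrences(
            [events.times[c] for c in m], cfg.min_intra_gap_s, cfg.max_step_lag_s,
            record=True,
        )
        q = null_quantile(nulls[m], cfg.null_percentile)
        sig = counts[m] >= cfg.min_repetitions and counts[m] > q
        motifs.append(
            SequenceMotif(m, occs, counts[m], nulls[m], q, significant=sig)
        )
    sig_cells = [mo.cells for mo in motifs if mo.significant]
    for mo in motifs:
        if mo.significant and any(
            len(other) > mo.order and _is_contiguous_subsequence(mo.cells, other)
            for other in sig_cells
        ):
            mo.subsumed = True
    return motifs


def summarize_sequences(
    motifs: list[SequenceMotif], n_cells: int, label: str = ""
) -> SequenceSummary:
    """Per-window summary: counts normalised by cell number, membership."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    sig = [m for m in motifs if m.significant]
    members: set[CellId] = set()
    for m in sig:
        members.update(m.cells)
    return SequenceSummary(
        label=label,
        n_cells=n_cells,
        n_significant=len(sig),
        normalized_n=len(sig) / n_cells,
        repetitions=[m.count for m in sig],
        proportion_cells_in_sequences=len(members) / n_cells,
    )


def detect_sequences_windowed(
    events: EventTrains,
    cfg: SequenceConfig | None = None,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> list[tuple[SequenceSummary, list[SequenceMotif]]]:
    """Run detection per consecutive non-overlapping observation window.

    Segments longer than ``cfg.window_s`` are split; a trailing remainder
    shorter than the window is dropped.
    """
    cfg = cfg or SequenceConfig()
    windows = split_windows(events.segment, cfg.window_s)
    out = []
    for i, w in enumerate(windows):
        sub = events.restrict(w)
        motifs = detect_sequences(sub, cfg, rng=rng)
        name = f"{label or 'segment'} {i + 1}" if len(windows) > 1 else (label or "segment")
        out.append((summarize_sequences(motifs, sub.n_cells, name), motifs))
    return out


def sequence_spatial_distribution(
    motifs: list[SequenceMotif], cell_map: CellMap
) -> dict:
    """Pairwise centroid distances: sequence members vs all cells.

    Returns both distance distributions and a two-sample Kolmogorov-Smirnov
    comparison (None when fewer than 2 member cells exist).
    """
    members = sorted(
        {c for m in motifs if m.significant for c in m.cells}, key=str
    )
    all_cells = cell_map.cells

    def pdist(cells):
        return np.array(
            [
                cell_map.distance(a, b)
                for i, a in enumerate(cells)
                for b in cells[i + 1 :]
            ]
        )

    d_all = pdist(all_cells)
    if len(members) < 2:
        return dict(member_distances=np.empty(0), all_distances=d_all, ks=None)
    d_mem = pdist(members)
    ks = stats.ks_2samp(d_mem, d_all)
    return dict(
        member_distances=d_mem,
        all_distances=d_all,
        ks=dict(statistic=float(ks.statistic), p_value=float(ks.pvalue)),
    )


def validate_occurrences(
    motifs: list[SequenceMotif], cfg: SequenceConfig
) -> bool:
    """Post-hoc check that every reported occurrence obeys the gap window."""
    for m in motifs:
        for occ in m.occurrence_times:
            gaps = np.diff(occ)
            if np.any(gaps <= cfg.min_intra_gap_s) or np.any(
                gaps > cfg.max_step_lag_s
            ):
                return False
    return True
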