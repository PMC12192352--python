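"""Synthetic calcium-event sessions with known planted structure.

The generator emulates the statistical shape of deconvolved one-photon
microendoscopy exports: sparse Poisson-like event trains (~0.01-1 events/s
per cell) on a continuous clock, fluorescence traces on a 10 Hz frame grid,
cell centroids in a field of view, and behavioral trial tables for simple
one- or two-target reaching tasks.  Structure can be planted on top of the
Poisson background — pairwise synchrony from a shared (common-input)
process, precisely timed multi-cell motifs, and direction-tuned task
responses — and is recorded in a :class:`~casim.core.GroundTruth` so every
downstream analysis has a parameter-recovery test.

Event times are continuous seconds; only trace synthesis and downstream
binning quantise to the frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    CellId,
    CellMap,
    EventTrains,
    GroundTruth,
    ONE_TARGET_DIRECTIONS,
    SessionBundle,
    TraceMatrix,
    TrialTable,
    TWO_TARGET_DIRECTIONS,
)
import pandas as pd

DEFAULT_AMPLITUDE_DIST = (0.0, 0.5)  # log-normal (mu, sigma)
DEFAULT_JITTER_S = 0.2  # one coactivation analysis bin
DEFAULT_KERNEL_TAU_S = 0.5
DEFAULT_NOISE_SD = 0.05
FOV_SIZE_UM = 400.0


@dataclass
class SynchronySpec:
    """A cell pair receiving events from a shared Poisson process.

    Each shared event is copied to both cells with independent uniform
    jitter on ``[0, jitter_s]``.
    """

    pair: tuple[int, int]
    shared_rate_hz: float
    jitter_s: float = DEFAULT_JITTER_S


@dataclass
class MotifSpec:
    """An ordered multi-cell motif planted ``n_plants`` times.

    One event per member cell is placed at cumulative ``step_lags_s`` from
    the occurrence start; each lag is perturbed by independent uniform
    jitter on ``[-lag_jitter_s, +lag_jitter_s]``.
    """

    cells: tuple[int, ...]
    step_lags_s: tuple[float, ...]
    n_plants: int
    lag_jitter_s: float = 0.0


@dataclass
class TuningSpec:
    """A direction-tuned task response.

    During the ``response_window_s`` after target onset of trials in the
    preferred direction, the cell's event rate is multiplied by
    ``rate_gain``.  ``preferred_direction=None`` makes the cell responsive
    to every direction (untuned-but-responsive).
    """

    cell: int
    preferred_direction: str | None
    rate_gain: float = 5.0
    response_window_s: float = 1.0


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic session."""

    n_cells: int
    duration_s: float
    base_rate_hz: float | tuple[float, float] = 0.2
    frame_rate_hz: float = 10.0
    synchrony_spec: list[SynchronySpec] = field(default_factory=list)
    motif_spec: list[MotifSpec] = field(default_factory=list)
    tuning_spec: list[TuningSpec] = field(default_factory=list)
    amplitude_dist: tuple[float, float] = DEFAULT_AMPLITUDE_DIST
    seed: int = 0
    task: str | None = None  # None | "one_target" | "two_target"
    n_trials: int = 0
    task_start_s: float = 0.0
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S
    noise_sd: float = DEFAULT_NOISE_SD
    make_traces: bool = True

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = (
            self.base_rate_hz
            if isinstance(self.base_rate_hz, (tuple, list))
            else (self.base_rate_hz, self.base_rate_hz)
        )
        if lo < 0 or hi < lo:
            raise ValueError("base_rate_hz must be a nonnegative scalar or (lo, hi)")
        for s in self.synchrony_spec:
            if s.shared_rate_hz < 0 or s.jitter_s < 0:
                raise ValueError("synchrony rates and jitter must be >= 0")
            self._check_cells(s.pair)
        for m in self.motif_spec:
            self._check_cells(m.cells)
            if len(m.step_lags_s) != len(m.cells) - 1:
                raise ValueError("motif needs one step lag per transition")
            for lag in m.step_lags_s:
                if not (0.05 < lag - m.lag_jitter_s and lag + m.lag_jitter_s <= 2.0):
                    raise ValueError(
                        "motif step lags must stay in (0.05, 2.0] s after jitter"
                    )
        for t in self.tuning_spec:
            self._check_cells((t.cell,))
            if t.rate_gain < 0 or t.response_window_s <= 0:
                raise ValueError("invalid tuning spec")
        if self.tuning_spec and self.task is None:
            raise ValueError("tuning_spec requires a task")
        if self.task is not None and self.task not in ("one_target", "two_target"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task is not None and self.n_trials < 1:
            raise ValueError("task sessions need n_trials >= 1")

    def _check_cells(self, cells: Sequence[int]) -> None:
        for c in cells:
            if not (0 <= int(c) < self.n_cells):
                raise ValueError(f"cell index {c} outside 0..{self.n_cells - 1}")

    def cell_ids(self) -> list[str]:
        width = max(3, len(str(self.n_cells - 1)))
        return [f"c{i:0{width}d}" for i in range(self.n_cells)]


def generate_trial_table(
    task: str,
    n_trials: int,
    seed: int | None = None,
    *,
    start_s: float = 0.0,
    success_rate: float = 1.0,
    rng: np.random.Generator | None = None,
) -> TrialTable:
    """Generate a behavioral trial table for a reaching task.

    One-target trials draw a direction uniformly from {left, center, right};
    two-target trials from {left, right} and include a movement-onset time
    (hand leaving the held center target) after a 1 s hold.  Inter-trial
    intervals are uniform on [2, 3] s.
    """
    if task not in ("one_target", "two_target"):
        raise ValueError(f"unknown task {task!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    directions = (
        ONE_TARGET_DIRECTIONS if task == "one_target" else TWO_TARGET_DIRECTIONS
    )
    rows = []
    t = float(start_s)
    for i in range(n_trials):
        iti_start = t
        iti = rng.uniform(2.0, 3.0)
        direction = directions[rng.integers(len(directions))]
        success = bool(rng.random() < success_rate)
        if task == "one_target":
            target_onset = iti_start + iti
            movement_onset = np.nan
            touch = target_onset + rng.uniform(0.5, 1.5)
        else:
            center_touch = iti_start + iti
            target_onset = center_touch + 1.0  # 1 s hold of the center target
            movement_onset = target_onset + rng.uniform(0.2, 0.8)
            touch = movement_onset + rng.uniform(0.2, 0.5)
        rows.append(
            dict(
                trial_id=i,
                iti_start_s=iti_start,
                target_onset_s=target_onset,
                direction=direction,
                movement_onset_s=movement_onset,
                success=success,
            )
        )
        t = touch + 0.5  # reward delivery / hand release before next ITI
    return TrialTable(pd.DataFrame(rows))


def trial_span_s(table: TrialTable) -> float:
    """Conservative end-of-task time (s) for a generated trial table."""
    df = table.df
    last = df.iloc[-1]
    end = max(
        float(last["target_onset_s"]) + 3.0,
        float(np.nan_to_num(last["movement_onset_s"], nan=0.0)) + 2.0,
    )
    return end


def events_to_traces(
    events: EventTrains,
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
    noise_sd: float = DEFAULT_NOISE_SD,
    frame_rate_hz: float = 10.0,
    rng: np.random.Generator | None = None,
) -> TraceMatrix:
    """Render event trains into fluorescence traces on the frame grid.

    Each event contributes ``amplitude * exp(-(t - t_event)/tau)`` for
    ``t >= t_event``; contributions superpose linearly and i.i.d. Gaussian
    noise of standard deviation ``noise_sd`` is added per frame.
    """
    if kernel_tau_s <= 0:
        raise ValueError("kernel_tau_s must be > 0")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    t0, t1 = events.segment
    n_frames = int(np.ceil((t1 - t0) * frame_rate_hz - 1e-9))
    tf = t0 + np.arange(n_frames) / frame_rate_hz
    data = np.zeros((events.n_cells, n_frames))
    for i, c in enumerate(events.cells):
        for te, amp in zip(events.times[c], events.amplitudes[c]):
            if not (t0 <= te < t1):
                raise ValueError(f"event at {te} s outside [{t0}, {t1})")
            i0 = int(np.ceil((te - t0) * frame_rate_hz - 1e-9))
            if i0 >= n_frames:
                continue
            data[i, i0:] += amp * np.exp(-(tf[i0:] - te) / kernel_tau_s)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng for reproducibility")
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return TraceMatrix(events.cells, data, frame_rate_hz=frame_rate_hz, t0_s=t0)


def _poisson_times(
    rng: np.random.Generator, rate_hz: float, t0: float, t1: float
) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def generate_session(config: SimConfig) -> SessionBundle:
    """Generate one synthetic session from ``config`` (deterministic per seed).

    Background events are independent homogeneous Poisson at the base rate;
    synchrony pairs additionally receive jittered copies of a shared Poisson
    process; motif plants place one event per member cell at cumulative step
    lags from a start time drawn with rejection so occurrences never overlap
    within a cell; tuned cells receive extra Poisson events in the response
    window of matching successful trials.  Amplitudes are i.i.d. log-normal.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng_sync, rng_motif, rng_task, rng_amp, rng_trace, rng_map = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    ids = config.cell_ids()
    D = config.duration_s
    lo, hi = (
        config.base_rate_hz
        if isinstance(config.base_rate_hz, (tuple, list))
        else (config.base_rate_hz, config.base_rate_hz)
    )
    base_rates = rng_bg.uniform(lo, hi, size=config.n_cells) if hi > lo else np.full(
        config.n_cells, lo
    )

    times: dict[CellId, list[np.ndarray]] = {c: [] for c in ids}
    for i, c in enumerate(ids):
        times[c].append(_poisson_times(rng_bg, base_rates[i], 0.0, D))

    truth = GroundTruth()

    for spec in config.synchrony_spec:
        a, b = (ids[int(i)] for i in spec.pair)
        shared = _poisson_times(rng_sync, spec.shared_rate_hz, 0.0, D)
        for c in (a, b):
            jit = shared + rng_sync.uniform(0.0, spec.jitter_s, size=shared.size)
            times[c].append(jit[jit < D])
        truth.synchrony_pairs.append((a, b))

    for spec in config.motif_spec:
        cells = tuple(ids[int(i)] for i in spec.cells)
        span = float(np.sum(spec.step_lags_s)) + len(spec.step_lags_s) * spec.lag_jitter_s
        if span >= D:
            raise ValueError("motif span exceeds session duration")
        starts: list[float] = []
        tries = 0
        while len(starts) < spec.n_plants:
            tries += 1
            if tries > 1000 * max(1, spec.n_plants):
                raise RuntimeError(
                    "could not place motif instances without overlap; "
                    "reduce n_plants or lengthen the session"
                )
            s = rng_motif.uniform(0.0, D - span - 1e-9)
            if all(abs(s - s2) > span for s2 in starts):
                starts.append(s)
        starts.sort()
        occurrences = []
        for s in starts:
            t = s
            occ = [t]
            for lag in spec.step_lags_s:
                t = t + lag + (
                    rng_motif.uniform(-spec.lag_jitter_s, spec.lag_jitter_s)
                    if spec.lag_jitter_s > 0
                    else 0.0
                )
                occ.append(t)
            occurrences.append(tuple(occ))
            for c, te in zip(cells, occ):
                times[c].append(np.array([te]))
        truth.motifs.append(
            dict(cells=cells, start_times=starts, event_times=occurrences)
        )

    trials: TrialTable | None = None
    if config.task is not None:
        trials = generate_trial_table(
            config.task,
            config.n_trials,
            start_s=config.task_start_s,
            rng=rng_task,
        )
        if trial_span_s(trials) > D:
            raise ValueError(
                "trial table extends past duration_s; lengthen the session"
            )
        for spec in config.tuning_spec:
            c = ids[int(spec.cell)]
            extra_rate = base_rates[int(spec.cell)] * max(spec.rate_gain - 1.0, 0.0)
            for row in trials.successful.itertuples(index=False):
                if (
                    spec.preferred_direction is not None
                    and row.direction != spec.preferred_direction
                ):
                    continue
                w0 = row.target_onset_s
                w1 = min(w0 + spec.response_window_s, D)
                times[c].append(_poisson_times(rng_task, extra_rate, w0, w1))
            truth.tuned_cells[c] = spec

    merged_t: dict[CellId, np.ndarray] = {}
    merged_a: dict[CellId, np.ndarray] = {}
    mu, sigma = config.amplitude_dist
    for c in ids:
        t = np.sort(np.concatenate(times[c])) if times[c] else np.empty(0)
        merged_t[c] = t
        merged_a[c] = rng_amp.lognormal(mu, sigma, size=t.size)
    events = EventTrains(merged_t, merged_a, (0.0, D))

    traces = (
        events_to_traces(
            events,
            kernel_tau_s=config.kernel_tau_s,
            noise_sd=config.noise_sd,
            frame_rate_hz=config.frame_rate_hz,
            rng=rng_trace,
        )
        if config.make_traces
        else None
    )
    cell_map = CellMap(
        {
            c: tuple(rng_map.uniform(0.0, FOV_SIZE_UM, size=2))
            for c in ids
        },
        unit="um",
    )
    return SessionBundle(
        events,
        traces,
        cell_map,
        trials,
        truth,
        meta=dict(seed=config.seed, base_rate_hz=list(map(float, base_rates))),
    )
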