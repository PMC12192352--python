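"""Core in-memory containers for a calcium-imaging session.

A *session* is the unit of analysis: the deconvolved event trains of all
accepted cells, the denoised fluorescence traces they were extracted from,
the spatial centroids of the cells, and (for task recordings) the behavioral
trial table.  Event times are kept in continuous seconds from recording
start; binning onto the 10 Hz frame grid or the 0.2 s analysis grid happens
only at the point of use.  Segments are half-open ``[t_start, t_end)`` so
that splitting a recording never double-counts boundary events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

CellId = Hashable

TRIAL_COLUMNS = [
    "trial_id",
    "iti_start_s",
    "target_onset_s",
    "direction",
    "movement_onset_s",
    "success",
]

ONE_TARGET_DIRECTIONS = ("left", "center", "right")
TWO_TARGET_DIRECTIONS = ("left", "right")


class SessionValidationError(ValueError):
    """A session component violates one of its structural invariants."""


@dataclass
class EventTrains:
    """Per-cell deconvolved calcium event times and amplitudes.

    Parameters
    ----------
    times
        Mapping from cell id to a sorted float array of event times (s).
    amplitudes
        Mapping from cell id to the matching array of event amplitudes
        (arbitrary units, strictly positive).
    segment
        Half-open recording span ``(t_start_s, t_end_s)`` that all event
        times must fall inside.
    """

    times: dict[CellId, np.ndarray]
    amplitudes: dict[CellId, np.ndarray]
    segment: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = {c: np.asarray(t, dtype=float) for c, t in self.times.items()}
        self.amplitudes = {
            c: np.asarray(a, dtype=float) for c, a in self.amplitudes.items()
        }
        self.segment = (float(self.segment[0]), float(self.segment[1]))
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        t0, t1 = self.segment
        if not t1 > t0:
            raise SessionValidationError(f"empty segment [{t0}, {t1})")
        if set(self.times) != set(self.amplitudes):
            raise SessionValidationError("times/amplitudes cell sets differ")
        for c, t in self.times.items():
            a = self.amplitudes[c]
            if t.shape != a.shape:
                raise SessionValidationError(f"cell {c!r}: times/amplitudes length mismatch")
            if t.size and (np.any(np.diff(t) < 0)):
                raise SessionValidationError(f"cell {c!r}: event times not sorted")
            if t.size and (t[0] < t0 or t[-1] >= t1):
                raise SessionValidationError(
                    f"cell {c!r}: event outside segment [{t0}, {t1})"
                )
            if np.any(a <= 0):
                raise SessionValidationError(f"cell {c!r}: amplitude <= 0")

    # -- convenience ----------------------------------------------------
    @property
    def cells(self) -> list[CellId]:
        return list(self.times)

    @property
    def n_cells(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return self.segment[1] - self.segment[0]

    @property
    def n_events(self) -> int:
        return int(sum(t.size for t in self.times.values()))

    def restrict(self, segment: tuple[float, float]) -> "EventTrains":
        """Return the events falling in half-open ``segment`` (same clock)."""
        t0, t1 = float(segment[0]), float(segment[1])
        if not t1 > t0:
            raise SessionValidationError(f"empty segment [{t0}, {t1})")
        times, amps = {}, {}
        for c, t in self.times.items():
            keep = (t >= t0) & (t < t1)
            times[c] = t[keep]
            amps[c] = self.amplitudes[c][keep]
        return EventTrains(times, amps, (t0, t1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTrains):
            return NotImplemented
        return (
            self.segment == other.segment
            and list(self.times) == list(other.times)
            and all(np.array_equal(self.times[c], other.times[c]) for c in self.times)
            and all(
                np.array_equal(self.amplitudes[c], other.amplitudes[c])
                for c in self.amplitudes
            )
        )


@dataclass
class TraceMatrix:
    """Dense cells x frames fluorescence matrix on a fixed frame grid."""

    cells: list[CellId]
    data: np.ndarray  # shape (n_cells, n_frames)
    frame_rate_hz: float = 10.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.cells = list(self.cells)
        if self.frame_rate_hz <= 0:
            raise SessionValidationError("frame_rate_hz must be > 0")
        if self.data.shape[0] != len(self.cells):
            raise SessionValidationError(
                f"{len(self.cells)} cells but {self.data.shape[0]} trace rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise SessionValidationError("non-finite trace values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frame_times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def row(self, cell: CellId) -> np.ndarray:
        return self.data[self.cells.index(cell)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceMatrix):
            return NotImplemented
        return (
            self.cells == other.cells
            and self.frame_rate_hz == other.frame_rate_hz
            and self.t0_s == other.t0_s
            and np.array_equal(self.data, other.data)
        )


@dataclass
class CellMap:
    """Spatial centroid (x, y) per cell, with the coordinate unit recorded."""

    centroids: dict[CellId, tuple[float, float]]
    unit: str = "um"

    def __post_init__(self) -> None:
        self.centroids = {
            c: (float(x), float(y)) for c, (x, y) in self.centroids.items()
        }
        for c, (x, y) in self.centroids.items():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise SessionValidationError(f"cell {c!r}: non-finite centroid")

    @property
    def cells(self) -> list[CellId]:
        return list(self.centroids)

    def distance(self, a: CellId, b: CellId) -> float:
        xa, ya = self.centroids[a]
        xb, yb = self.centroids[b]
        return float(np.hypot(xa - xb, ya - yb))


@dataclass
class TrialTable:
    """Behavioral trial table (one row per trial).

    Columns: ``trial_id, iti_start_s, target_onset_s, direction,
    movement_onset_s, success``.  ``movement_onset_s`` is NaN for the
    one-target task, which has no hold-release event.  ``iti_start_s`` marks
    the start of the inter-trial interval preceding the trial; its first
    second provides the Z-scoring baseline downstream.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise SessionValidationError(f"trial table missing columns: {missing}")
        df = df[TRIAL_COLUMNS].reset_index(drop=True)
        df["success"] = df["success"].astype(bool)
        self.df = df
        self.validate()

    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        onsets = df["target_onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise SessionValidationError("target onsets not strictly increasing")
        if np.any(df["iti_start_s"].to_numpy(float) >= onsets):
            raise SessionValidationError("iti_start_s must precede target_onset_s")
        allowed = set(ONE_TARGET_DIRECTIONS)
        bad = set(df["direction"]) - allowed
        if bad:
            raise SessionValidationError(f"unknown directions: {sorted(bad)}")
        move = df["movement_onset_s"].to_numpy(float)
        has_move = ~np.isnan(move)
        if np.any(move[has_move] < onsets[has_move]):
            raise SessionValidationError("movement_onset_s before target_onset_s")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def successful(self) -> pd.DataFrame:
        return self.df[self.df["success"]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic session, for recovery tests."""

    synchrony_pairs: list[tuple[CellId, CellId]] = field(default_factory=list)
    motifs: list[dict[str, Any]] = field(default_factory=list)
    tuned_cells: dict[CellId, Any] = field(default_factory=dict)


@dataclass
class SessionBundle:
    """One recording session: events, traces, centroids, trials.

    ``trials`` is None for spontaneous-only sessions and ``ground_truth`` is
    None for sessions read from disk rather than simulated.
    """

    events: EventTrains
    traces: TraceMatrix | None = None
    cell_map: CellMap | None = None
    trials: TrialTable | None = None
    ground_truth: GroundTruth | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = set(self.events.cells)
        if self.cell_map is not None:
            missing = cells - set(self.cell_map.cells)
            if missing:
                raise SessionValidationError(
                    f"cells missing from centroid map: {sorted(map(str, missing))}"
                )
        if self.traces is not None:
            if set(self.traces.cells) != cells:
                raise SessionValidationError("trace cells differ from event cells")

    @property
    def cells(self) -> list[CellId]:
        return self.events.cells


def split_windows(
    segment: tuple[float, float], window_s: float
) -> list[tuple[float, float]]:
    """Split a half-open segment into consecutive non-overlapping windows.

    A trailing remainder shorter than ``window_s`` is dropped; callers log
    the drop.  Returns at least one window only if the segment fits one.
    """
    t0, t1 = segment
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    n = int(np.floor((t1 - t0) / window_s + 1e-9))
    return [(t0 + i * window_s, t0 + (i + 1) * window_s) for i in range(n)]
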