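"""Read and write session artifacts as fixed CSV schemas.

Four files make up a session on disk, mirroring IDPS-style tabular exports:

* ``events.csv`` — tidy long format, one row per deconvolved event:
  ``cell_id,time_s,amplitude``
* ``traces.csv`` — wide format, ``time_s`` then one column per cell id
* ``centroids.csv`` — ``cell_id,x,y,unit``
* ``trials.csv`` — ``trial_id,iti_start_s,target_onset_s,direction,
  movement_onset_s,success``

All times share one session clock (seconds from recording start).  Event
times round-trip losslessly at 9 decimal places (~ns).  Validation errors
name the file, row, and rule violated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CellMap,
    EventTrains,
    SessionBundle,
    SessionValidationError,
    TraceMatrix,
    TrialTable,
    TRIAL_COLUMNS,
)

_FLOAT_FMT = "%.9g"


class SchemaError(SessionValidationError):
    """A CSV artifact violates its schema; message names file, row, rule."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_events(path, segment: tuple[float, float] | None = None) -> EventTrains:
    """Read ``events.csv``; infer the segment from the data if not given."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "time_s", "amplitude"], path)
    bad = df.index[df["amplitude"].to_numpy(float) <= 0]
    if len(bad):
        raise SchemaError(
            f"{path}: row {bad[0] + 2}: rule 'amplitude > 0' violated"
        )
    if segment is None:
        tmax = float(df["time_s"].max()) if len(df) else 0.0
        segment = (0.0, tmax + 1e-6 if len(df) else 1.0)
    times, amps = {}, {}
    for cell, grp in df.groupby("cell_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            row = grp.index[np.flatnonzero(np.diff(t) < 0)[0] + 1] + 2
            raise SchemaError(f"{path}: row {row}: rule 'times sorted' violated")
        times[cell] = t
        amps[cell] = grp["amplitude"].to_numpy(float)
    return EventTrains(times, amps, segment)


def read_traces(path) -> TraceMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s"], path)
    cells = [c for c in df.columns if c != "time_s"]
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 frames to infer frame rate")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise SchemaError(f"{path}: rule 'uniform frame grid' violated")
    data = df[cells].to_numpy(float).T
    if not np.all(np.isfinite(data)):
        r = int(np.argwhere(~np.isfinite(data))[0][1]) + 2
        raise SchemaError(f"{path}: row {r}: rule 'finite values' violated")
    return TraceMatrix(cells, data, frame_rate_hz=1.0 / dt[0], t0_s=float(t[0]))


def read_centroids(path) -> CellMap:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["cell_id", "x", "y"], path)
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else "um"
    if df["cell_id"].duplicated().any():
        row = int(df.index[df["cell_id"].duplicated()][0]) + 2
        raise SchemaError(f"{path}: row {row}: rule 'one centroid per cell' violated")
    return CellMap(
        {r.cell_id: (r.x, r.y) for r in df.itertuples(index=False)}, unit=unit
    )


def read_trials(path) -> TrialTable:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    if "movement_onset_s" in df.columns:
        df["movement_onset_s"] = pd.to_numeric(df["movement_onset_s"], errors="coerce")
    try:
        return TrialTable(df)
    except SessionValidationError as e:
        raise SchemaError(f"{path}: {e}") from e


def read_session(
    events_path,
    traces_path=None,
    centroids_path=None,
    trials_path=None,
    segment: tuple[float, float] | None = None,
) -> SessionBundle:
    """Assemble a validated :class:`SessionBundle` from CSV artifacts.

    Trials and traces are optional (spontaneous-only sessions); cells present
    in the events but absent from the centroid file raise an error naming the
    offenders.
    """
    traces = read_traces(traces_path) if traces_path else None
    if segment is None:
        meta_path = Path(events_path).parent / "session.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if "segment" in meta:
                segment = tuple(meta["segment"])
    if segment is None and traces is not None:
        segment = (
            traces.t0_s,
            traces.t0_s + traces.n_frames / traces.frame_rate_hz,
        )
    events = read_events(events_path, segment=segment)
    if traces is not None:
        # traces may include silent cells; events must be a subset
        extra = set(events.cells) - set(traces.cells)
        if extra:
            raise SchemaError(f"cells in events but not traces: {sorted(map(str, extra))}")
        silent = [c for c in traces.cells if c not in events.times]
        for c in silent:
            events.times[c] = np.empty(0)
            events.amplitudes[c] = np.empty(0)
    cell_map = read_centroids(centroids_path) if centroids_path else None
    trials = read_trials(trials_path) if trials_path else None
    return SessionBundle(events, traces, cell_map, trials)


def write_session(bundle: SessionBundle, out_dir) -> dict[str, Path]:
    """Write the four CSV artifacts (plus a small JSON metadata sidecar).

    Returns the paths written.  An empty trial table yields a header-only
    ``trials.csv``; cells without events appear in ``centroids.csv`` but have
    no rows in ``events.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for c in bundle.events.cells:
        t = bundle.events.times[c]
        a = bundle.events.amplitudes[c]
        rows.append(pd.DataFrame({"cell_id": c, "time_s": t, "amplitude": a}))
    ev = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["cell_id", "time_s", "amplitude"])
    )
    paths["events"] = out / "events.csv"
    ev.to_csv(paths["events"], index=False, float_format=_FLOAT_FMT)

    if bundle.traces is not None:
        tr = bundle.traces
        df = pd.DataFrame(tr.data.T, columns=[str(c) for c in tr.cells])
        df.insert(0, "time_s", tr.frame_times())
        paths["traces"] = out / "traces.csv"
        df.to_csv(paths["traces"], index=False, float_format=_FLOAT_FMT)

    if bundle.cell_map is not None:
        cm = bundle.cell_map
        df = pd.DataFrame(
            [(c, x, y, cm.unit) for c, (x, y) in cm.centroids.items()],
            columns=["cell_id", "x", "y", "unit"],
        )
        paths["centroids"] = out / "centroids.csv"
        df.to_csv(paths["centroids"], index=False, float_format=_FLOAT_FMT)

    if bundle.trials is not None:
        paths["trials"] = out / "trials.csv"
        bundle.trials.df.to_csv(paths["trials"], index=False, float_format=_FLOAT_FMT)

    meta = dict(bundle.meta)
    meta["segment"] = list(bundle.events.segment)
    paths["meta"] = out / "session.json"
    paths["meta"].write_text(json.dumps(meta, indent=2, default=str) + "\n")
    return paths
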