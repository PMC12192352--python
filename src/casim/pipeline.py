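"""End-to-end orchestration: simulate/load -> describe -> align ->
coactivation -> sequences, from one nested config, with deterministic
seeding and a machine-readable run manifest.

The config is a plain nested mapping (typically loaded from YAML).  Top
level keys:

``seed``
    Global seed.  Per-stage generators are derived with
    ``numpy.random.SeedSequence(seed).spawn`` so stages are individually
    reproducible; the spawn order is recorded in the manifest.
``simulate`` | ``session``
    Either a :class:`~casim.simulate.SimConfig` block or paths to session
    CSVs.
``segments``
    Mapping of label -> ``[t0, t1]`` half-open analysis segments
    (e.g. ``spontaneous``, ``task``); must be non-overlapping.
``describe`` / ``align`` / ``coactivation`` / ``sequences``
    Per-stage parameter blocks; a stage runs iff its block is present (an
    empty block requests defaults).

Every exclusion downstream (dropped trials, invalid pairs, skipped
comparisons) is counted and echoed in the manifest rather than silently
discarded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    AlignmentConfig,
    extract_aligned_epochs,
    magnitude_comparisons,
    modulation_test,
)
from .coactivation import coactivation_analysis
from .core import SessionBundle
from .descriptors import METRICS, adjust_family, compare_paired, compute_descriptors
from .io import read_session, write_session
from .sequences import (
    SequenceConfig,
    detect_sequences_windowed,
    sequence_spatial_distribution,
    validate_occurrences,
)
from .simulate import MotifSpec, SimConfig, SynchronySpec, TuningSpec, generate_session

log = logging.getLogger("casim")

_FLOAT_FMT = "%.9g"
STAGES = ("simulate", "describe", "align", "coactivation", "sequences")


class PipelineError(RuntimeError):
    pass


def _build_sim_config(block: Mapping[str, Any]) -> SimConfig:
    block = dict(block)
    block["synchrony_spec"] = [
        SynchronySpec(tuple(s["pair"]), s["shared_rate_hz"], s.get("jitter_s", 0.2))
        for s in block.get("synchrony_spec", [])
    ]
    block["motif_spec"] = [
        MotifSpec(
            tuple(m["cells"]),
            tuple(m["step_lags_s"]),
            m["n_plants"],
            m.get("lag_jitter_s", 0.0),
        )
        for m in block.get("motif_spec", [])
    ]
    block["tuning_spec"] = [
        TuningSpec(
            t["cell"],
            t.get("preferred_direction"),
            t.get("rate_gain", 5.0),
            t.get("response_window_s", 1.0),
        )
        for t in block.get("tuning_spec", [])
    ]
    if isinstance(block.get("base_rate_hz"), list):
        block["base_rate_hz"] = tuple(block["base_rate_hz"])
    return SimConfig(**block)


def _validate_segments(
    segments: Mapping[str, Any], span: tuple[float, float]
) -> dict[str, tuple[float, float]]:
    segs = {k: (float(v[0]), float(v[1])) for k, v in segments.items()}
    for k, (a, b) in segs.items():
        if not (span[0] <= a < b <= span[1] + 1e-9):
            raise PipelineError(f"segment {k!r} [{a}, {b}) outside recording {span}")
    ordered = sorted(segs.values())
    for (a0, b0), (a1, b1) in zip(ordered, ordered[1:]):
        if a1 < b0:
            raise PipelineError("segments overlap")
    return segs


def run_pipeline(config: Mapping[str, Any], out_dir=None) -> dict[str, Any]:
    """Execute the configured stages in dependency order.

    Writes per-stage CSVs plus ``manifest.json`` under ``out_dir`` (or
    ``config['out_dir']``) and returns the manifest.  Any stage error
    aborts the run; a ``manifest.partial.json`` records completed stages.
    """
    out = Path(out_dir or config.get("out_dir", "casim_run"))
    # config-level validation happens before any stage executes
    if "segments" in config:
        spans = sorted(
            (float(v[0]), float(v[1])) for v in config["segments"].values()
        )
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            if a1 < b0:
                raise PipelineError("segments overlap")
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest: dict[str, Any] = dict(
        casim_version=__version__,
        seed=seed,
        seed_scheme="SeedSequence(seed).spawn per stage, order: " + ",".join(STAGES),
        stages_completed=[],
        exclusions={},
        parameters={k: config[k] for k in config if k != "out_dir"},
        outputs=[],
    )

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"].append(name)

    def _fail(stage: str, err: Exception) -> None:
        (out / "manifest.partial.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # -- stage 1: obtain the session ------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = _build_sim_config(
                {**config["simulate"], "seed": config["simulate"].get("seed", seed)}
            )
            bundle = generate_session(sim_cfg)
            write_session(bundle, out / "session")
            manifest["stages_completed"].append("simulate")
        elif "session" in config:
            paths = config["session"]
            bundle = read_session(
                paths["events"],
                paths.get("traces"),
                paths.get("centroids"),
                paths.get("trials"),
            )
            manifest["stages_completed"].append("simulate")  # load stands in
        else:
            raise PipelineError("config needs a 'simulate' or 'session' block")
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        _fail("simulate", e)

    segments = _validate_segments(
        config.get("segments", {"full": list(bundle.events.segment)}),
        bundle.events.segment,
    )

    # -- stage 2: descriptors -------------------------------------------
    if "describe" in config:
        try:
            tables = {
                label: compute_descriptors(bundle.events, seg, condition=label)
                for label, seg in segments.items()
            }
            _write(pd.concat(tables.values()).reset_index(), "descriptors.csv")
            results = []
            if "spontaneous" in tables and "task" in tables:
                for m in METRICS:
                    results.append(
                        compare_paired(tables["spontaneous"], tables["task"], m)
                    )
                adjust_family(results)
            _write(pd.DataFrame([r.as_dict() for r in results]), "stats.csv")
            manifest["stages_completed"].append("describe")
        except Exception as e:  # noqa: BLE001
            _fail("describe", e)

    # -- stage 3: alignment ---------------------------------------------
    if "align" in config:
        try:
            if bundle.trials is None or bundle.traces is None:
                raise PipelineError("align stage needs trials and traces")
            acfg = AlignmentConfig(**config["align"])
            epochs = extract_aligned_epochs(bundle.traces, bundle.trials, acfg)
            mod = modulation_test(epochs, acfg)
            mags = magnitude_comparisons(mod)
            _write(mod.tests, "modulation.csv")
            _write(mod.categories, "categories.csv")
            _write(pd.DataFrame([r.as_dict() for r in mags]), "magnitude_stats.csv")
            manifest["exclusions"]["align_dropped_trials"] = epochs.exclusions
            manifest["exclusions"]["align_excluded_conditions"] = (
                mod.excluded_conditions
            )
            manifest["stages_completed"].append("align")
        except Exception as e:  # noqa: BLE001
            _fail("align", e)

    # -- stage 4: coactivation ------------------------------------------
    if "coactivation" in config:
        try:
            ccfg = dict(config["coactivation"])
            rng = np.random.default_rng(stage_seeds["coactivation"])
            prop_rows = []
            for label, seg in segments.items():
                res = coactivation_analysis(
                    bundle.events,
                    bundle.cell_map,
                    segment=seg,
                    bin_width_s=ccfg.get("bin_width_s", 0.2),
                    lookahead_bins=ccfg.get("lookahead_bins", 4),
                    n_shuffles=ccfg.get("n_shuffles", 1000),
                    threshold=ccfg.get("threshold", 1.96),
                    rng=rng,
                )
                _write(res["pairs"].table, f"zjaccard_{label}.csv")
                if res.get("distance_table") is not None:
                    _write(res["distance_table"], f"distance_z_{label}.csv")
                n_invalid = int((~res["pairs"].table["valid"]).sum())
                manifest["exclusions"][f"coactivation_invalid_pairs_{label}"] = n_invalid
                prop_rows.append(
                    dict(
                        segment=label,
                        proportion_synchronized=res["proportion"],
                        n_valid_pairs=int(len(res["pairs"].valid)),
                        n_bins=res["n_bins"],
                    )
                )
            _write(pd.DataFrame(prop_rows), "proportions.csv")
            manifest["stages_completed"].append("coactivation")
        except Exception as e:  # noqa: BLE001
            _fail("coactivation", e)

    # -- stage 5: sequences ---------------------------------------------
    if "sequences" in config:
        try:
            scfg = SequenceConfig(**config["sequences"])
            rng = np.random.default_rng(stage_seeds["sequences"])
            seq_rows, sum_rows, all_motifs = [], [], []
            for label, seg in segments.items():
                sub = bundle.events.restrict(seg)
                if sub.duration_s + 1e-9 < scfg.window_s:
                    manifest["exclusions"][f"sequences_skipped_{label}"] = (
                        f"segment shorter than {scfg.window_s} s window"
                    )
                    continue
                for summary, motifs in detect_sequences_windowed(
                    sub, scfg, rng=rng, label=label
                ):
                    assert validate_occurrences(motifs, scfg)
                    for m in motifs:
                        seq_rows.append(
                            dict(
                                segment=summary.label,
                                motif="->".join(map(str, m.cells)),
                                order=m.order,
                                count=m.count,
                                null_q=m.null_q,
                                significant=m.significant,
                                subsumed=m.subsumed,
                                occurrence_starts=";".join(
                                    f"{o[0]:.3f}" for o in m.occurrence_times
                                ),
                            )
                        )
                    sum_rows.append(
                        dict(
                            segment=summary.label,
                            n_cells=summary.n_cells,
                            n_significant=summary.n_significant,
                            normalized_n=summary.normalized_n,
                            proportion_cells=summary.proportion_cells_in_sequences,
                            median_repetitions=(
                                float(np.median(summary.repetitions))
                                if summary.repetitions
                                else 0.0
                            ),
                        )
                    )
                    all_motifs.extend(motifs)
            _write(
                pd.DataFrame(
                    seq_rows,
                    columns=[
                        "segment", "motif", "order", "count", "null_q",
                        "significant", "subsumed", "occurrence_starts",
                    ],
                ),
                "sequences.csv",
            )
            _write(
                pd.DataFrame(
                    sum_rows,
                    columns=[
                        "segment", "n_cells", "n_significant", "normalized_n",
                        "proportion_cells", "median_repetitions",
                    ],
                ),
                "sequence_summary.csv",
            )
            if bundle.cell_map is not None:
                spatial = sequence_spatial_distribution(all_motifs, bundle.cell_map)
                rows = [
                    dict(group="all", distance=d) for d in spatial["all_distances"]
                ] + [
                    dict(group="members", distance=d)
                    for d in spatial["member_distances"]
                ]
                _write(pd.DataFrame(rows, columns=["group", "distance"]), "spatial.csv")
                manifest["sequence_spatial_ks"] = spatial["ks"]
            manifest["stages_completed"].append("sequences")
        except Exception as e:  # noqa: BLE001
            _fail("sequences", e)

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n"
    )
    return manifest
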