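"""Run the whole pipeline from one config and inspect the manifest.

Simulates a session with a spontaneous and a task segment, then runs
descriptors, alignment, coactivation, and sequence detection, writing
per-stage CSVs and a reproducibility manifest under ./pipeline_demo/.
"""

import json

import casim

config = dict(
    seed=5,
    out_dir="pipeline_demo",
    simulate=dict(
        n_cells=15,
        duration_s=1250.0,
        base_rate_hz=0.05,
        task="one_target",
        n_trials=80,
        task_start_s=600.0,
        tuning_spec=[dict(cell=0, preferred_direction="left", rate_gain=8.0)],
        motif_spec=[dict(cells=[1, 2, 3], step_lags_s=[0.5, 0.5], n_plants=6)],
    ),
    segments=dict(spontaneous=[0.0, 600.0], task=[600.0, 1250.0]),
    describe={},
    align={},
    coactivation=dict(n_shuffles=1000),
    sequences=dict(n_shuffles=1000),
)

manifest = casim.run_pipeline(config)
print("stages completed:", ", ".join(manifest["stages_completed"]))
print("outputs:", ", ".join(manifest["outputs"]))
print("exclusions:", json.dumps(manifest["exclusions"], indent=2))
print("(the manifest plus the seed reproduce this run byte-for-byte; "
      "rerun with the same config to verify)")
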