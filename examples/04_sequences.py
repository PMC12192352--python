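"""Detect precisely timed multi-cell event sequences.

Plants a three-cell motif (0.5 s steps, 6 repetitions) in a 10-min window
of sparse background activity and tests every recurring ordered motif
against a 1,000-replicate circular-shift null.
"""

import numpy as np

import casim

cfg = casim.SimConfig(
    n_cells=20,
    duration_s=600.0,
    base_rate_hz=0.05,
    motif_spec=[casim.MotifSpec((0, 1, 2), step_lags_s=(0.5, 0.5), n_plants=6)],
    seed=4,
    make_traces=False,
)
bundle = casim.generate_session(cfg)

motifs = casim.detect_sequences(
    bundle.events, casim.SequenceConfig(), rng=np.random.default_rng(40)
)
significant = [m for m in motifs if m.significant]
summary = casim.summarize_sequences(motifs, bundle.events.n_cells)

planted = tuple(bundle.ground_truth.motifs[0]["cells"])
print(f"planted motif {'->'.join(planted)}, 6 repetitions")
shown = sorted(significant, key=lambda m: (m.cells != planted, -m.count))[:8]
for m in shown:
    tag = " (planted)" if m.cells == planted else ""
    print(f"  {'->'.join(str(c) for c in m.cells):24s} "
          f"count {m.count:2d}  null q95 {m.null_q:.0f}{tag}")
print()
print(f"{summary.n_significant} significant sequences among "
      f"{summary.n_cells} cells ({summary.normalized_n:.2f} per cell); "
      f"{summary.proportion_cells_in_sequences:.0%} of cells participate")
print("(significant = at least 4 repetitions and more than 95% of "
      "circular-shift shuffles)")
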