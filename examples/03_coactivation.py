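"""Z-Jaccard coactivation with a circular-shift null.

Plants one common-input pair among independent cells, bins events at
0.2 s, forward-smooths (1 s coincidence window), and standardises each
pair's Jaccard index against 1,000 circular rotations of one row.
"""

import numpy as np

import casim

cfg = casim.SimConfig(
    n_cells=10,
    duration_s=600.0,
    base_rate_hz=0.1,
    synchrony_spec=[casim.SynchronySpec((0, 1), shared_rate_hz=0.1)],
    seed=3,
    make_traces=False,
)
bundle = casim.generate_session(cfg)

res = casim.coactivation_analysis(
    bundle.events, bundle.cell_map, rng=np.random.default_rng(30)
)
table = res["pairs"].table.sort_values("z", ascending=False)

print(table.head(5)[["cell_a", "cell_b", "jaccard", "z"]].to_string(index=False))
print()
print(f"planted pair: {bundle.ground_truth.synchrony_pairs[0]}")
print(f"synchronized proportion: {res['proportion']:.3f} "
      "(fraction of valid pairs with |Z-Jaccard| > 1.96; "
      "~0.05 expected from chance alone, plus the planted pair)")
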