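"""Trial alignment, baseline Z-scoring, and modulation classification.

For each successful trial, a 3-s epoch of the raw trace starting 1 s before
the aligned behavioral event (target onset, or movement onset for the
two-target task) is Z-scored against that trial's baseline — the first
second of the preceding inter-trial interval.  A cell is *modulated* in a
condition (target direction) when its mean Z in the event window (0-1 s
after the event) differs from the mean in the pre-window (the preceding
second) by a Wilcoxon signed-rank test across trials, with BH-FDR applied
across all cell x condition tests of the session.  Cells significant in
exactly one condition are *direction-related*; in two or more,
*non-direction-related*; in none, *not modulated*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import TraceMatrix, TrialTable
from .descriptors import StatResult, bh_fdr

CATEGORY_NOT_MODULATED = "not_modulated"
CATEGORY_DIRECTION = "direction_related"
CATEGORY_NON_DIRECTION = "non_direction_related"


@dataclass
class AlignmentConfig:
    """Epoch/window geometry and test level for trial alignment.

    Windows are in seconds relative to the aligned event.  The baseline is
    the first ``baseline_s`` of the inter-trial interval preceding each
    trial (ITIs are 2-3 s, so a 1 s baseline always exists).
    """

    align_event: str = "target_onset"  # or "movement_onset"
    epoch: tuple[float, float] = (-1.0, 2.0)
    baseline_s: float = 1.0
    event_window: tuple[float, float] = (0.0, 1.0)
    pre_window: tuple[float, float] = (-1.0, 0.0)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.epoch
        for w in (self.event_window, self.pre_window):
            if not (lo <= w[0] < w[1] <= hi):
                raise ValueError(f"window {w} outside epoch {self.epoch}")
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be > 0")
        if self.align_event not in ("target_onset", "movement_onset"):
            raise ValueError(f"unknown align_event {self.align_event!r}")


@dataclass
class EpochTensor:
    """Z-scored peri-event epochs: cells x trials x frames."""

    cells: list
    z: np.ndarray  # (C, n_trials, n_frames)
    directions: np.ndarray  # (n_trials,) str
    cfg: AlignmentConfig
    frame_rate_hz: float
    n_excluded: int = 0
    exclusions: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.z.shape[1]

    def epoch_times(self) -> np.ndarray:
        n = self.z.shape[2]
        return self.cfg.epoch[0] + np.arange(n) / self.frame_rate_hz

    def window_mean(self, window: tuple[float, float]) -> np.ndarray:
        """Mean Z per cell x trial over frames in ``[w0, w1)``."""
        t = self.epoch_times()
        sel = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
        return self.z[:, :, sel].mean(axis=2)


def extract_aligned_epochs(
    traces: TraceMatrix,
    trials: TrialTable,
    cfg: AlignmentConfig | None = None,
) -> EpochTensor:
    """Build the Z-scored epoch tensor from successful trials.

    Per trial and cell, Z = (x - mu) / sigma with mu, sigma the mean/SD of
    that cell's trace over the trial's baseline (first second of the
    preceding ITI).  Trials whose baseline SD is zero for any cell, or
    whose epoch/baseline falls outside the recording, are dropped and
    logged.
    """
    cfg = cfg or AlignmentConfig()
    fr = traces.frame_rate_hz
    ok_trials = trials.successful
    if len(ok_trials) == 0:
        raise ValueError("no successful trials to align")
    n_epoch = int(round((cfg.epoch[1] - cfg.epoch[0]) * fr))
    n_base = int(round(cfg.baseline_s * fr))
    n_frames = traces.n_frames
    data = traces.data
    kept_z, kept_dir, exclusions = [], [], []
    for row in ok_trials.itertuples(index=False):
        t_event = getattr(row, cfg.align_event + "_s")
        if t_event is None or (isinstance(t_event, float) and np.isnan(t_event)):
            exclusions.append(f"trial {row.trial_id}: no {cfg.align_event}")
            continue
        # nearest-frame mapping of continuous event times onto the 10 Hz grid
        i_event = int(round((t_event - traces.t0_s) * fr))
        i0 = i_event + int(round(cfg.epoch[0] * fr))
        i1 = i0 + n_epoch
        ib = int(round((row.iti_start_s - traces.t0_s) * fr))
        if i0 < 0 or i1 > n_frames or ib < 0 or ib + n_base > n_frames:
            exclusions.append(f"trial {row.trial_id}: epoch outside recording")
            continue
        base = data[:, ib : ib + n_base]
        mu = base.mean(axis=1)
        sd = base.std(axis=1, ddof=1)
        if np.any(sd == 0):
            exclusions.append(f"trial {row.trial_id}: zero baseline SD")
            continue
        kept_z.append((data[:, i0:i1] - mu[:, None]) / sd[:, None])
        kept_dir.append(row.direction)
    if not kept_z:
        raise ValueError("all successful trials were excluded")
    z = np.stack(kept_z, axis=1)
    return EpochTensor(
        list(traces.cells),
        z,
        np.array(kept_dir),
        cfg,
        fr,
        n_excluded=len(exclusions),
        exclusions=exclusions,
    )


@dataclass
class ModulationResult:
    """Per cell x condition modulation tests plus per-cell categories."""

    tests: pd.DataFrame  # cell_id, condition, pre_mean, event_mean, delta_z, p, p_adj, sign
    categories: pd.DataFrame  # cell_id, n_significant, category
    alpha: float
    excluded_conditions: list[str] = field(default_factory=list)


def modulation_test(
    epochs: EpochTensor, cfg: AlignmentConfig | None = None, min_trials: int = 5
) -> ModulationResult:
    """Wilcoxon signed-rank of event-window vs pre-window mean Z per trial.

    One test per cell x condition; BH-FDR is applied across all tests of
    the session (chamber level).  Conditions with fewer than ``min_trials``
    trials are excluded and reported.
    """
    cfg = cfg or epochs.cfg
    pre = epochs.window_mean(cfg.pre_window)
    ev = epochs.window_mean(cfg.event_window)
    conditions = sorted(set(epochs.directions))
    excluded = []
    rows = []
    for cond in conditions:
        sel = epochs.directions == cond
        if sel.sum() < min_trials:
            excluded.append(f"{cond}: only {int(sel.sum())} trials")
            continue
        for ci, cell in enumerate(epochs.cells):
            x = ev[ci, sel]
            y = pre[ci, sel]
            if np.all(x == y):
                p, statv = 1.0, 0.0
            else:
                res = stats.wilcoxon(
                    x, y, zero_method="wilcox", alternative="two-sided"
                )
                p, statv = float(res.pvalue), float(res.statistic)
            delta = float(np.mean(x) - np.mean(y))
            rows.append(
                dict(
                    cell_id=cell,
                    condition=cond,
                    pre_mean=float(np.mean(y)),
                    event_mean=float(np.mean(x)),
                    delta_z=delta,
                    statistic=statv,
                    p_value=p,
                    sign=int(np.sign(delta)),
                )
            )
    tests = pd.DataFrame(rows)
    if len(tests) == 0:
        raise ValueError("no condition had enough trials")
    tests["p_adjusted"] = bh_fdr(tests["p_value"].to_numpy())
    tests["significant"] = tests["p_adjusted"] < cfg.alpha
    categories = classify_cells(tests)
    return ModulationResult(tests, categories, cfg.alpha, excluded)


def classify_cells(tests: pd.DataFrame) -> pd.DataFrame:
    """Categorise cells by their per-condition significance pattern.

    0 significant conditions -> not modulated; exactly 1 ->
    direction-related; 2 or more -> non-direction-related.
    """
    rows = []
    for cell, grp in tests.groupby("cell_id", sort=False):
        k = int(grp["significant"].sum())
        cat = (
            CATEGORY_NOT_MODULATED
            if k == 0
            else CATEGORY_DIRECTION
            if k == 1
            else CATEGORY_NON_DIRECTION
        )
        rows.append(dict(cell_id=cell, n_significant=k, category=cat))
    return pd.DataFrame(rows)


def magnitude_comparisons(result: ModulationResult) -> list[StatResult]:
    """Compare |deltaZ| magnitudes of modulated responses.

    Increasing vs decreasing cells via Mann-Whitney rank-sum; across target
    positions via Kruskal-Wallis.  Magnitudes come from trial-averaged
    window means of significant cell x condition entries.  Empty groups
    skip the comparison with a note.
    """
    sig = result.tests[result.tests["significant"]]
    out: list[StatResult] = []
    mag = sig["delta_z"].abs().to_numpy()
    inc = mag[sig["sign"].to_numpy() > 0]
    dec = mag[sig["sign"].to_numpy() < 0]
    if inc.size >= 2 and dec.size >= 2:
        r = stats.mannwhitneyu(inc, dec, alternative="two-sided")
        out.append(
            StatResult(
                "mann_whitney", "abs_delta_z_incr_vs_decr",
                float(r.statistic), float(r.pvalue), None,
                int(inc.size + dec.size),
                "a>b" if np.median(inc) > np.median(dec) else "a<b",
            )
        )
    else:
        out.append(
            StatResult(
                "mann_whitney", "abs_delta_z_incr_vs_decr", np.nan, np.nan,
                None, int(inc.size + dec.size), "none",
                note="skipped: a sign group has < 2 entries",
            )
        )
    groups = [
        grp["delta_z"].abs().to_numpy()
        for _, grp in sig.groupby("condition", sort=True)
        if len(grp) >= 2
    ]
    if len(groups) >= 2:
        r = stats.kruskal(*groups)
        out.append(
            StatResult(
                "kruskal_wallis", "abs_delta_z_by_condition",
                float(r.statistic), float(r.pvalue), None,
                int(sum(g.size for g in groups)), "none",
            )
        )
    else:
        out.append(
            StatResult(
                "kruskal_wallis", "abs_delta_z_by_condition", np.nan, np.nan,
                None, 0, "none", note="skipped: fewer than 2 condition groups",
            )
        )
    return out
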