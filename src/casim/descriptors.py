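"""Per-cell calcium-event descriptors and condition/region comparisons.

Three descriptors summarise each cell's event train over a recording
segment: the event rate (events/s), the coefficient of variation of the
inter-event intervals (IEI CV; 1 for a homogeneous Poisson process), and
the mean deconvolved event amplitude.  Condition contrasts (spontaneous vs
task, same cells) use the two-sided Wilcoxon signed-rank test; region
contrasts (disjoint cell sets) use the Wilcoxon rank-sum (Mann-Whitney)
test; families of p-values are corrected with the Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import EventTrains

METRICS = ("event_rate", "iei_cv", "mean_amplitude")
#: Aliases accepted by the comparison functions.
_METRIC_ALIASES = {"rate": "event_rate", "amplitude": "mean_amplitude", "iei_cv": "iei_cv"}

UNDERPOWERED_N = 5  # fewer valid pairs/values than this flags the result


@dataclass
class StatResult:
    """One statistical comparison, before and after FDR adjustment."""

    test: str
    metric: str
    statistic: float
    p_value: float
    p_adjusted: float | None
    n: int
    direction: str  # "a>b", "a<b", or "none"
    underpowered: bool = False
    note: str = ""

    def as_dict(self) -> dict:
        return dict(
            test=self.test,
            metric=self.metric,
            statistic=self.statistic,
            p_value=self.p_value,
            p_adjusted=self.p_adjusted,
            n=self.n,
            direction=self.direction,
            underpowered=self.underpowered,
            note=self.note,
        )


def compute_descriptors(
    events: EventTrains,
    segment: tuple[float, float] | None = None,
    condition: str = "",
    region: str = "",
) -> pd.DataFrame:
    """Per-cell descriptor table over ``segment`` (default: full recording).

    Returns a DataFrame indexed by cell id with columns ``n_events``,
    ``event_rate``, ``iei_cv``, ``mean_amplitude``, ``condition``,
    ``region``.  The IEI CV uses the sample standard deviation (n-1) and is
    NaN below 3 events; the mean amplitude is NaN for silent cells.
    """
    if segment is not None:
        events = events.restrict(segment)
    duration = events.duration_s
    rows = []
    for c in events.cells:
        t = events.times[c]
        a = events.amplitudes[c]
        n = t.size
        if n >= 3:
            iei = np.diff(t)
            cv = float(np.std(iei, ddof=1) / np.mean(iei)) if np.mean(iei) > 0 else np.nan
        else:
            cv = np.nan
        rows.append(
            dict(
                cell_id=c,
                n_events=n,
                event_rate=n / duration,
                iei_cv=cv,
                mean_amplitude=float(np.mean(a)) if n else np.nan,
                condition=condition,
                region=region,
            )
        )
    return pd.DataFrame(rows).set_index("cell_id")


def _canon_metric(metric: str) -> str:
    m = _METRIC_ALIASES.get(metric, metric)
    if m not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return m


def compare_paired(a: pd.DataFrame, b: pd.DataFrame, metric: str) -> StatResult:
    """Two-sided Wilcoxon signed-rank on per-cell paired differences.

    ``a`` and ``b`` must cover the same cells (e.g., the same cells in the
    spontaneous and task conditions).  Cells with an undefined metric in
    either table are dropped and counted in ``note``.  Zero differences are
    dropped (Wilcoxon's convention); an all-zero difference vector returns
    p = 1 by convention.
    """
    m = _canon_metric(metric)
    if set(a.index) != set(b.index):
        raise ValueError("paired comparison requires identical cell sets")
    x = a[m].reindex(a.index).to_numpy(float)
    y = b[m].reindex(a.index).to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    note = f"dropped {dropped} cells with undefined {m}" if dropped else ""
    if n == 0 or np.all(x == y):
        stat, p = 0.0, 1.0
    else:
        res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    diff = float(np.median(x - y)) if n else 0.0
    direction = "a>b" if diff > 0 else ("a<b" if diff < 0 else "none")
    return StatResult(
        "wilcoxon_signed_rank", m, stat, p, None, n, direction,
        underpowered=n < UNDERPOWERED_N, note=note,
    )


def compare_unpaired(a: pd.DataFrame, b: pd.DataFrame, metric: str) -> StatResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) on per-cell values.

    For disjoint cell groups, e.g., M1 vs SMA cells in the same condition.
    """
    m = _canon_metric(metric)
    x = a[m].to_numpy(float)
    y = b[m].to_numpy(float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("compare_unpaired: empty group")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    diff = float(np.median(x) - np.median(y))
    direction = "a>b" if diff > 0 else ("a<b" if diff < 0 else "none")
    return StatResult(
        "wilcoxon_rank_sum", m, float(res.statistic), float(res.pvalue), None,
        int(x.size + y.size), direction,
        underpowered=min(x.size, y.size) < UNDERPOWERED_N,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_i = min_{j >= i} p_(j) * m / j`` clipped at 1, where ``p_(j)`` are
    the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[StatResult]) -> list[StatResult]:
    """Apply BH-FDR across a family of comparisons, in place; returns it."""
    if not results:
        return results
    adj = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def describe_conditions(
    events_by_condition: dict[str, EventTrains],
    segments: dict[str, tuple[float, float]] | None = None,
    region: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptor tables plus paired condition contrasts for one site.

    Computes the three descriptors per condition and, when both a
    ``spontaneous`` and a ``task`` condition are present, the paired
    signed-rank contrast per metric, FDR-corrected within the site family.
    Returns ``(descriptors, stats)`` DataFrames.
    """
    tables = {}
    for cond, ev in events_by_condition.items():
        seg = segments.get(cond) if segments else None
        tables[cond] = compute_descriptors(ev, seg, condition=cond, region=region)
    desc = pd.concat(tables.values()).reset_index()
    results: list[StatResult] = []
    if "spontaneous" in tables and "task" in tables:
        for m in METRICS:
            results.append(compare_paired(tables["spontaneous"], tables["task"], m))
        adjust_family(results)
    stats_df = pd.DataFrame([r.as_dict() for r in results])
    return desc, stats_df
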