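"""Population-level summaries and the rank-based two-sample comparison.

Fraction-localized curves are instantaneous: the fraction of cells whose
cleaned state is nuclear at each time point (a transient population peak, as
seen for Msn4p, is impossible under a cumulative reading).  Heatmap-ready
matrices order cells by time of first localization, censored cells last.

The Mann–Whitney U test asks whether one data set takes larger values than
another without assuming a distribution.  For small tie-free samples
(n1, n2 <= 8) the exact null distribution of U is computed here by the
standard counting recurrence over rank arrangements; larger or tied samples
fall back to the normal approximation with tie and continuity corrections
(delegated to scipy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .dynamics import CLASSES, CellMetrics, StateTrack, detect_states, moving_average
from .quantify import LocalizationTrajectory

__all__ = [
    "PopulationSummary",
    "UTestResult",
    "fraction_localized",
    "localization_matrix",
    "mann_whitney",
    "summarize_condition",
]

EXACT_MAX_N = 8  # exact enumeration up to 8 per group (12 870 arrangements)


@dataclass
class PopulationSummary:
    """Per-condition aggregate of per-cell metrics and state tracks."""

    label: str
    n_cells: int
    times: np.ndarray | None
    fraction_localized: np.ndarray | None
    total_nuclear_times: np.ndarray  # seconds, all cells
    first_localization_times: np.ndarray  # seconds, responders only
    n_responders: int
    n_censored: int
    median_total_nuclear_time: float
    median_first_localization_time: float | None  # None if no responders
    class_counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != self.n_cells:
            raise ValueError("class counts must sum to n_cells")
        if self.fraction_localized is not None:
            f = np.asarray(self.fraction_localized)
            if np.any(f < 0) or np.any(f > 1):
                raise ValueError("fraction_localized must lie in [0, 1]")


@dataclass(frozen=True)
class UTestResult:
    U: float  # U statistic of the sample hypothesized to be larger (y)
    n1: int
    n2: int
    p_value: float
    sidedness: str
    method: str  # "exact" or "normal_approx"


def _common_time_base(tracks: list[StateTrack]) -> tuple[np.ndarray, np.ndarray]:
    """States of all tracks on a shared time base.

    Tracks on different bases are resampled onto the coarsest one by taking,
    for each target time, the state of the most recent frame at or before it.
    """
    if not tracks:
        raise ValueError("empty population")
    bases = [t.times for t in tracks]
    if all(len(b) == len(bases[0]) and np.array_equal(b, bases[0]) for b in bases):
        return bases[0].copy(), np.stack([t.state for t in tracks])
    coarsest = max(tracks, key=lambda t: t.frame_interval).times
    end = min(float(t.times[-1]) for t in tracks)
    target = coarsest[coarsest <= end + 1e-9]
    states = []
    for t in tracks:
        idx = np.searchsorted(t.times, target + 1e-9) - 1
        idx = np.clip(idx, 0, len(t) - 1)
        states.append(t.state[idx])
    return target.copy(), np.stack(states)


def fraction_localized(
    tracks: list[StateTrack], smooth_window: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous fraction of cells in the nuclear state at each time point.

    ``smooth_window`` applies a display-only moving average (odd width); leave
    it None for anything that feeds further statistics.
    """
    times, states = _common_time_base(tracks)
    frac = states.mean(axis=0)
    if smooth_window is not None:
        frac = moving_average(frac, smooth_window)
    return times, frac


def first_localization_order(
    trajs: list[LocalizationTrajectory], params=None
) -> list[tuple[str, float | None]]:
    """(cell_id, first localization time) pairs sorted ascending, censored last."""
    from .dynamics import AnalysisParams, cell_metrics

    params = params or AnalysisParams()
    entries = []
    for traj in trajs:
        m = cell_metrics(detect_states(traj, params), params)
        entries.append((traj.cell_id, m.first_localization_time))
    entries.sort(key=lambda e: (e[1] is None, e[1] if e[1] is not None else 0.0, e[0]))
    return entries


def localization_matrix(
    trajs: list[LocalizationTrajectory], params=None
) -> tuple[pd.DataFrame, list[str]]:
    """Cells x time matrix of localization values for heatmap display.

    Rows are ordered by time of first localization (cells that never localize
    come last); the ordering is returned alongside the matrix.
    """
    if not trajs:
        raise ValueError("empty population")
    base = trajs[0].times
    for traj in trajs[1:]:
        if not np.array_equal(traj.times, base):
            raise ValueError("trajectories must share a time base")
    order = [cid for cid, _ in first_localization_order(trajs, params)]
    by_id = {t.cell_id: t for t in trajs}
    mat = pd.DataFrame(
        np.stack([by_id[cid].loc_value for cid in order]),
        index=pd.Index(order, name="cell_id"),
        columns=base,
    )
    return mat, order


@lru_cache(maxsize=64)
def _u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of arrangements giving each U value, tie-free null.

    c[u] counts subsets of ranks for the second sample with U statistic u;
    recurrence over whether the largest observation belongs to sample 2.
    Equivalent to enumerating all C(n1+n2, n2) arrangements.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_counts(n1 - 1, n2)  # largest value in sample 1
    b = _u_counts(n1, n2 - 1)  # largest value in sample 2: adds n1 to U
    size = n1 * n2 + 1
    out = [0] * size
    for u, c in enumerate(a):
        out[u] += c
    for u, c in enumerate(b):
        out[u + n1] += c
    return tuple(out)


def _exact_p(u: float, n1: int, n2: int, sided: str) -> float:
    counts = np.array(_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    us = np.arange(counts.size)
    if sided == "greater":
        return float(counts[us >= u].sum() / total)
    mid = n1 * n2 / 2.0
    return min(1.0, float(counts[np.abs(us - mid) >= abs(u - mid) - 1e-12].sum() / total))


def mann_whitney(x, y, sided: str = "greater") -> UTestResult:
    """Rank-based test of whether ``y`` takes larger values than ``x``.

    sided="greater" tests the alternative that y is stochastically greater
    than x (the usual one-sided reading of "does this data set take larger
    values than that one"); "two_sided" tests for any location shift.

    Tie-free samples with at most 8 observations per group get the exact null
    distribution; otherwise the normal approximation with continuity and tie
    corrections is used.  The reported U is the U statistic of ``y``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("greater", "two_sided"):
        raise ValueError("sided must be 'greater' or 'two_sided'")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    u_y = float(ranks[n1:].sum() - n2 * (n2 + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties:
        p = _exact_p(u_y, n1, n2, sided)
        method = "exact"
    else:
        alternative = "less" if sided == "greater" else "two-sided"
        res = sstats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
        p = float(min(res.pvalue, 1.0))
        method = "normal_approx"
    p = max(p, np.finfo(float).tiny)
    return UTestResult(U=u_y, n1=n1, n2=n2, p_value=p, sidedness=sided, method=method)


def summarize_condition(
    metrics: list[CellMetrics],
    tracks: list[StateTrack] | None = None,
    label: str = "",
) -> PopulationSummary:
    """Aggregate per-cell metrics (and, if given, tracks) for one condition.

    The median time to first localization is computed over responders only —
    censored cells are counted and reported, never imputed — while the median
    total nuclear time runs over all cells.
    """
    if not metrics:
        raise ValueError("empty population")
    totals = np.array([m.total_nuclear_time for m in metrics])
    firsts = np.array(
        [m.first_localization_time for m in metrics if m.responded], dtype=float
    )
    n_resp = int(firsts.size)
    counts = {c: 0 for c in CLASSES}
    for m in metrics:
        counts[m.classification] += 1
    times = frac = None
    if tracks is not None:
        times, frac = fraction_localized(tracks)
    return PopulationSummary(
        label=label,
        n_cells=len(metrics),
        times=times,
        fraction_localized=frac,
        total_nuclear_times=totals,
        first_localization_times=firsts,
        n_responders=n_resp,
        n_censored=len(metrics) - n_resp,
        median_total_nuclear_time=float(np.median(totals)),
        median_first_localization_time=float(np.median(firsts)) if n_resp else None,
        class_counts=counts,
    )
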