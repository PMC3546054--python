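"""Localization dynamics: binary state detection and per-cell metrics.

A localization trajectory is turned into a binary nuclear/cytoplasmic state
track in three steps: a centred 5-frame moving average, a strictly-above
threshold at 0.28, and a run-length cleanup in which nuclear and non-nuclear
episodes shorter than 5 frames (~20 s at 4 s/frame) are flipped.  Short runs
are removed nuclear-first, then short gaps are filled; runs touching a record
boundary are exempt (a recording often starts or ends mid-episode), and the
two passes are iterated to a fixed point so the result is idempotent.

Per-cell metrics follow: whether the cell responded within the observation
window, time to first nuclear localization (censored for non-responders),
total nuclear time, event count, and a three-way classification —
no_response / only_oscillating / permanent nuclear localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantify import LocalizationTrajectory

__all__ = [
    "AnalysisParams",
    "StateTrack",
    "CellMetrics",
    "moving_average",
    "binarize",
    "clean_runs",
    "detect_states",
    "cell_metrics",
    "classify_trajectory",
]

NO_RESPONSE = "no_response"
ONLY_OSCILLATING = "only_oscillating"
PERMANENT = "permanent"
CLASSES = (NO_RESPONSE, ONLY_OSCILLATING, PERMANENT)


@dataclass(frozen=True)
class AnalysisParams:
    """Signal-analysis parameters.

    window : moving-average width in frames (odd).
    threshold : localization value above which a frame counts as nuclear.
    min_run : shortest episode, in frames, that survives cleanup.
    observation_window : seconds of record over which metrics are computed.
    permanence_tail : a final nuclear run at least this long (seconds)
        classifies the cell as permanently localized.
    """

    window: int = 5
    threshold: float = 0.28
    min_run: int = 5
    observation_window: float = 3600.0
    permanence_tail: float = 600.0

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.observation_window <= 0:
            raise ValueError("observation_window must be > 0")
        if self.permanence_tail <= 0:
            raise ValueError("permanence_tail must be > 0")


@dataclass
class StateTrack:
    """Cleaned binary per-frame state (1 = nuclear) with the parameters used."""

    cell_id: str
    times: np.ndarray
    state: np.ndarray
    provenance: AnalysisParams

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.times.shape != self.state.shape:
            raise ValueError("times and state must have equal length")
        if not np.all((self.state == 0) | (self.state == 1)):
            raise ValueError("state must be binary")

    def __len__(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        if len(self) < 2:
            raise ValueError("frame interval undefined for a single-frame track")
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class CellMetrics:
    cell_id: str
    responded: bool
    first_localization_time: float | None  # seconds; None = censored
    total_nuclear_time: float  # seconds within the observation window
    n_events: int
    classification: str


def moving_average(loc_values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; at the boundaries the window is truncated to the
    frames that exist (no padding values are invented)."""
    x = np.asarray(loc_values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > x.size:
        raise ValueError(f"window ({window}) longer than series ({x.size})")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def binarize(filtered: np.ndarray, threshold: float) -> np.ndarray:
    """1 where strictly above the threshold, else 0."""
    return (np.asarray(filtered, dtype=float) > threshold).astype(np.int8)


def _runs(b: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of a binary array as (start, stop, value), stop exclusive."""
    if b.size == 0:
        return []
    change = np.flatnonzero(np.diff(b)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [b.size]))
    return [(int(s), int(e), int(b[s])) for s, e in zip(starts, stops)]


def clean_runs(binary: np.ndarray, min_run: int) -> np.ndarray:
    """Flip episodes shorter than ``min_run`` frames.

    Short nuclear runs are set to 0 first, then short non-nuclear runs in the
    updated signal are set to 1.  Runs touching either record boundary are
    exempt.  The two passes repeat until nothing changes, so the operation is
    idempotent and never leaves an interior run shorter than ``min_run``.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    b = np.asarray(binary).astype(np.int8).copy()
    n = b.size
    for _ in range(n + 1):
        changed = False
        for target in (1, 0):  # remove short nuclear runs, then fill short gaps
            for start, stop, value in _runs(b):
                if value != target or stop - start >= min_run:
                    continue
                if start == 0 or stop == n:  # boundary runs exempt
                    continue
                b[start:stop] = 1 - target
                changed = True
        if not changed:
            break
    return b


def detect_states(
    traj: LocalizationTrajectory, params: AnalysisParams = AnalysisParams()
) -> StateTrack:
    """Full detection pipeline: moving average -> binarize -> clean_runs."""
    if len(traj) < params.window:
        raise ValueError(
            f"trajectory {traj.cell_id!r} has {len(traj)} frames, "
            f"shorter than the {params.window}-frame filter window"
        )
    filtered = moving_average(traj.loc_value, params.window)
    state = clean_runs(binarize(filtered, params.threshold), params.min_run)
    return StateTrack(traj.cell_id, traj.times.copy(), state, params)


def _nuclear_runs(track: StateTrack) -> list[tuple[int, int]]:
    return [(s, e) for s, e, v in _runs(track.state) if v == 1]


def cell_metrics(track: StateTrack, params: AnalysisParams | None = None) -> CellMetrics:
    """Per-cell summary over the observation window.

    Each frame covers [t, t + dt); frames starting inside the window count.
    An event straddling the window end counts as an event, but only its
    within-window frames contribute to the total nuclear time.  The
    classification is computed on the within-window part of the track, so
    no_response coincides exactly with "did not respond in the window".
    """
    if params is None:
        params = track.provenance
    t0 = float(track.times[0])
    dt = track.frame_interval
    in_window = (track.times - t0) < params.observation_window

    total = float(np.sum(track.state[in_window]) * dt)
    total = min(total, params.observation_window)

    runs = [(s, e) for s, e in _nuclear_runs(track) if in_window[s]]
    n_events = len(runs)
    responded = n_events >= 1
    first = float(track.times[runs[0][0]] - t0) if responded else None

    n_in = int(np.sum(in_window))
    sub = StateTrack(track.cell_id, track.times[:n_in], track.state[:n_in], params)
    tail = min(params.permanence_tail, (n_in - 1) * dt + dt)
    classification = classify_trajectory(sub, permanence_tail=tail)

    return CellMetrics(
        cell_id=track.cell_id,
        responded=responded,
        first_localization_time=first,
        total_nuclear_time=total,
        n_events=n_events,
        classification=classification,
    )


def classify_trajectory(track: StateTrack, permanence_tail: float = 600.0) -> str:
    """Three-way trajectory class.

    permanent : the record ends inside a nuclear run that spans at least the
        last ``permanence_tail`` seconds;
    only_oscillating : at least one nuclear event, but not permanent;
    no_response : no nuclear event at all.
    """
    dt = track.frame_interval
    record_span = len(track) * dt
    if record_span < permanence_tail:
        raise ValueError(
            f"record ({record_span:.0f} s) shorter than permanence_tail "
            f"({permanence_tail:.0f} s)"
        )
    runs = _runs(track.state)
    if not any(v == 1 for _, _, v in runs):
        return NO_RESPONSE
    start, stop, value = runs[-1]
    if value == 1 and (stop - start) * dt >= permanence_tail:
        return PERMANENT
    return ONLY_OSCILLATING
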