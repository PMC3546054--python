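"""Ground-truthed synthetic data for the shuttling-analysis pipeline.

The generator emulates the statistical structure of light-stress time-lapse
experiments on immobilized yeast expressing a GFP-tagged transcription factor:
frames every ~4 s for 60-150 min, populations of order 100 cells, and three
trajectory archetypes —

* no_response : the factor stays cytoplasmic for the whole record;
* oscillating : bursts of nuclear localization, typically 2-3 min long,
  generated as a renewal process (exponential inter-burst gaps, uniform burst
  lengths);
* permanent : after a stochastic lag the factor enters the nucleus and stays
  there to the end of the record.  Lags are log-normal (positive support,
  right-skewed), parameterized by their median and log-scale sd.

A trajectory is the baseline localization value (~0 when cytoplasmic) or the
nuclear value (0.8 by default, comfortably above the 0.28 detection threshold)
per the true state, plus optional additive Gaussian noise.  The renderer draws
the same truth as disc-shaped cells with an interior disc nucleus whose
intensity is multiplied by a gain while the state is nuclear, so the whole
image pipeline can be validated frame-by-frame against stored ground truth.

All randomness flows from the scenario seed through one named generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .quantify import CellRegion, ExpressionTrace, ImageStack, LocalizationTrajectory

__all__ = [
    "ARCHETYPES",
    "SimScenario",
    "GroundTruth",
    "RenderLayout",
    "grid_layout",
    "simulate_population",
    "render_frames",
    "simulate_expression",
]

ARCHETYPES = ("no_response", "oscillating", "permanent")


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one synthetic condition.

    archetype_weights follow the order of ``ARCHETYPES``:
    (no_response, oscillating, permanent).  lag_median / lag_log_sd set the
    log-normal distribution of the permanent-entry lag, in seconds.
    burst_rate is in events per minute; burst durations are uniform on
    burst_duration_range (seconds).  noise_sd is the additive Gaussian noise
    on the localization value (also the relative pixel noise scale when
    rendering).
    """

    n_cells: int = 100
    frame_interval: float = 4.0
    duration: float = 3600.0
    archetype_weights: tuple[float, float, float] = (0.2, 0.5, 0.3)
    lag_median: float = 1140.0  # 19 min
    lag_log_sd: float = 0.4
    burst_rate: float = 0.3
    burst_duration_range: tuple[float, float] = (120.0, 180.0)
    baseline_loc: float = 0.0
    nuclear_loc: float = 0.8
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        w = self.archetype_weights
        if len(w) != len(ARCHETYPES) or any(x < 0 for x in w):
            raise ValueError("archetype_weights must be three non-negative numbers")
        if not math.isclose(sum(w), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("archetype_weights must sum to 1")
        lo, hi = self.burst_duration_range
        if not (0 < lo <= hi):
            raise ValueError("burst_duration_range must satisfy 0 < low <= high")
        if self.lag_median <= 0:
            raise ValueError("lag_median must be > 0")
        if self.lag_log_sd < 0:
            raise ValueError("lag_log_sd must be >= 0")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class GroundTruth:
    """Stored truth of a simulated population."""

    archetypes: list[str]
    states: np.ndarray  # (n_cells, n_frames) int8
    entry_times: np.ndarray  # seconds; NaN for non-permanent cells

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.entry_times = np.asarray(self.entry_times, dtype=float)
        n = len(self.archetypes)
        if self.states.shape[0] != n or self.entry_times.shape != (n,):
            raise ValueError("ground-truth fields must agree in cell count")


def _cell_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"cell_{i:0{width}d}" for i in range(1, n + 1)]


def simulate_population(
    scenario: SimScenario,
) -> tuple[list[LocalizationTrajectory], GroundTruth]:
    """Draw a population of localization trajectories with stored ground truth.

    Identical scenarios (same seed) give bit-identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    n_frames = scenario.n_frames
    dt = scenario.frame_interval
    times = scenario.times

    labels = [
        ARCHETYPES[i]
        for i in rng.choice(len(ARCHETYPES), size=scenario.n_cells,
                            p=scenario.archetype_weights)
    ]
    states = np.zeros((scenario.n_cells, n_frames), dtype=np.int8)
    entry = np.full(scenario.n_cells, np.nan)

    for i, label in enumerate(labels):
        if label == "permanent":
            lag = scenario.lag_median * math.exp(
                scenario.lag_log_sd * rng.standard_normal()
            )
            entry[i] = lag
            frame = int(math.ceil(lag / dt))
            if frame < n_frames:
                states[i, frame:] = 1
        elif label == "oscillating":
            if scenario.burst_rate > 0:
                t = 0.0
                mean_gap = 60.0 / scenario.burst_rate
                lo, hi = scenario.burst_duration_range
                while t < scenario.duration:
                    t += rng.exponential(mean_gap)
                    length = rng.uniform(lo, hi)
                    a = int(math.ceil(t / dt))
                    b = int(math.ceil((t + length) / dt))
                    if a < n_frames:
                        states[i, a:min(b, n_frames)] = 1
                    t += length

    amplitude = scenario.nuclear_loc - scenario.baseline_loc
    loc = scenario.baseline_loc + amplitude * states.astype(float)
    if scenario.noise_sd > 0:
        loc = loc + rng.normal(0.0, scenario.noise_sd, size=loc.shape)

    trajs = [
        LocalizationTrajectory(cid, times.copy(), loc[i])
        for i, cid in enumerate(_cell_ids(scenario.n_cells))
    ]
    return trajs, GroundTruth(labels, states, entry)


@dataclass(frozen=True)
class RenderLayout:
    """Geometry and photometry of a rendered stack.

    Cells are filled discs of ``cell_radius`` pixels with an interior disc
    nucleus of ``nucleus_radius`` at ``nucleus_offset`` from the cell centre.
    While a cell's true state is nuclear its nucleus pixels are multiplied by
    ``nuclear_gain`` (gain 1.8 yields a localization value of 0.8).
    """

    shape: tuple[int, int]
    centers: tuple[tuple[int, int], ...]
    cell_radius: float = 7.0
    nucleus_radius: float = 3.0
    nucleus_offset: tuple[int, int] = (0, 0)
    background_intensity: float = 100.0
    cytosol_intensity: float = 400.0
    nuclear_gain: float = 1.8

    def __post_init__(self) -> None:
        h, w = self.shape
        r = self.cell_radius
        for cr, cc in self.centers:
            if not (r <= cr <= h - 1 - r and r <= cc <= w - 1 - r):
                raise ValueError(f"cell at {(cr, cc)} extends outside the image")
        centers = np.array(self.centers, dtype=float)
        if len(centers) > 1:
            d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() <= 2 * r:
                raise ValueError("cell regions overlap")
        dr, dc = self.nucleus_offset
        if math.hypot(dr, dc) + self.nucleus_radius > self.cell_radius:
            raise ValueError("nucleus region lies outside its cell region")
        if _disc_size(self.cell_radius) <= 120:
            raise ValueError("every cell region must have more than 120 pixels")
        if self.nuclear_gain <= 0 or self.cytosol_intensity <= 0:
            raise ValueError("intensities and gain must be positive")


def _disc_size(radius: float) -> int:
    r = int(math.floor(radius))
    return sum(
        1
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= radius * radius
    )


def _disc_pixels(centre: tuple[int, int], radius: float) -> tuple[np.ndarray, np.ndarray]:
    cr, cc = centre
    r = int(math.floor(radius))
    rows, cols = [], []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if dr * dr + dc * dc <= radius * radius:
                rows.append(cr + dr)
                cols.append(cc + dc)
    return np.array(rows, dtype=np.intp), np.array(cols, dtype=np.intp)


def grid_layout(
    n_cells: int,
    cell_radius: float = 7.0,
    nucleus_radius: float = 3.0,
    spacing: int | None = None,
    **kwargs,
) -> RenderLayout:
    """Arrange ``n_cells`` non-overlapping cells on a square grid."""
    spacing = spacing or int(2 * cell_radius + 3)
    per_side = int(math.ceil(math.sqrt(n_cells)))
    margin = int(math.ceil(cell_radius)) + 1
    side = margin * 2 + (per_side - 1) * spacing
    centers = tuple(
        (margin + spacing * (i // per_side), margin + spacing * (i % per_side))
        for i in range(n_cells)
    )
    return RenderLayout(
        shape=(side, side),
        centers=centers,
        cell_radius=cell_radius,
        nucleus_radius=nucleus_radius,
        **kwargs,
    )


def render_frames(
    truth: GroundTruth,
    layout: RenderLayout,
    scenario: SimScenario,
    pixel_noise: bool = False,
) -> tuple[ImageStack, list[CellRegion]]:
    """Draw an image stack realizing the ground truth on the given layout.

    Each frame shows every cell at the cytosol intensity with its nucleus
    pixels multiplied by the nuclear gain whenever the true state is nuclear.
    With ``pixel_noise`` a scaled-Poisson (shot-like) noise is applied whose
    relative sd at the cytosol intensity equals ``scenario.noise_sd``.
    """
    n_cells, n_frames = truth.states.shape
    if len(layout.centers) != n_cells:
        raise ValueError("layout and truth disagree in cell count")
    if n_frames != scenario.n_frames:
        raise ValueError("truth and scenario disagree in frame count")

    cell_px = [_disc_pixels(c, layout.cell_radius) for c in layout.centers]
    off = layout.nucleus_offset
    nuc_px = [
        _disc_pixels((c[0] + off[0], c[1] + off[1]), layout.nucleus_radius)
        for c in layout.centers
    ]

    base = np.full(layout.shape, layout.background_intensity)
    for rows, cols in cell_px:
        base[rows, cols] = layout.cytosol_intensity

    frames = np.repeat(base[None], n_frames, axis=0)
    gain_extra = layout.cytosol_intensity * (layout.nuclear_gain - 1.0)
    for i in range(n_cells):
        nuclear_at = np.flatnonzero(truth.states[i])
        if nuclear_at.size:
            rows, cols = nuc_px[i]
            frames[np.ix_(nuclear_at, rows, cols)] += gain_extra

    if pixel_noise and scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed + 1)
        # Poisson photon statistics scaled so relative sd at the cytosol
        # intensity matches noise_sd: lambda = counts / q, q chosen per pixel.
        q = scenario.noise_sd**2 * layout.cytosol_intensity
        frames = rng.poisson(frames / q).astype(float) * q

    stack = ImageStack(frames, scenario.times)
    regions = [
        CellRegion(cid, *cell_px[i]) for i, cid in enumerate(_cell_ids(n_cells))
    ]
    return stack, regions


def simulate_expression(
    n_cells: int,
    induction: str,
    duration: float = 18000.0,
    seed: int = 0,
    sample_interval: float = 600.0,
    lag: float = 2400.0,
    tau: float = 3600.0,
    amplitude: float = 100.0,
    amplitude_cv: float = 0.3,
    noise_sd: float = 0.0,
) -> list[ExpressionTrace]:
    """Per-cell reporter-expression time courses.

    Emulates a 40-min illumination followed by sampling every 10 min for 5 h:
    induced cells rise after a lag along a saturating exponential of time
    constant ``tau`` toward a per-cell amplitude (log-normal across cells,
    coefficient of variation ``amplitude_cv``); uninduced cells stay flat at
    zero background-subtracted response.  Noise is additive Gaussian per
    sample (off by default).
    """
    if induction not in ("induced", "uninduced"):
        raise ValueError("induction must be 'induced' or 'uninduced'")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if duration < sample_interval:
        raise ValueError("duration must cover at least one sampling interval")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + 1e-9, sample_interval)
    traces = []
    sigma_log = math.sqrt(math.log(1.0 + amplitude_cv**2))
    for cid in _cell_ids(n_cells):
        if induction == "induced":
            a = amplitude * math.exp(
                sigma_log * rng.standard_normal() - sigma_log**2 / 2
            )
            resp = a * (1.0 - np.exp(-np.maximum(times - lag, 0.0) / tau))
        else:
            resp = np.zeros_like(times)
        if noise_sd > 0:
            resp = resp + rng.normal(0.0, noise_sd, size=times.shape)
        traces.append(ExpressionTrace(cid, times.copy(), resp))
    return traces
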