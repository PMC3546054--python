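# Methods

## Measurement model

The observable is a single-channel fluorescence stack of immobilized cells
with per-frame timestamps. Cell regions are supplied as labelled masks and
treated as constant over time (immobilized cells; no tracking, no contour
detection — both are out of scope). Within each region and frame:

1. the frame is smoothed with a Gaussian of `sigma` pixels (default 2,
   `scipy.ndimage.gaussian_filter`, `mode="nearest"`);
2. the nucleus is the brightest in-region pixel of the smoothed frame plus
   all in-region pixels at Euclidean distance ≤ `radius` (default 3; an
   unclipped disc has 29 pixels). Ties for the brightest pixel are broken in
   row-major order, deterministically;
3. the cytosol is the `k` brightest remaining in-region pixels (default 90),
   again by smoothed intensity with row-major tie-breaks at the k-th value.
   If fewer than `k` pixels remain, all are used and a warning is counted;
4. the localization value is `median(I_nuc)/median(I_cyt) − 1`, with the
   medians taken on the **original** intensities by default. The smoothed
   frame serves only as the selection substrate; measuring on it instead
   (`measure_on="smoothed"`) is supported but biases medians toward the blur
   scale. The ratio is invariant under global intensity rescaling, which the
   tests assert to 1e-12.

The "3-pixel radius" is interpreted as Euclidean distance including the
centre; chessboard or city-block discs would be less standard for an
isotropic nucleus. The nucleus search is restricted to the cell region.

The reporter-expression readout is simpler: per frame, each cell's mean
intensity minus the mean of a user-chosen cell-free background rectangle,
averaged over cells. Whether such a response should additionally be
normalized to its value at t = 0 is genuinely open; both modes exist and the
absolute difference is the default.

## State detection

Localization trajectories are converted to binary nuclear/cytoplasmic tracks
by a centred moving average of `window` frames (default 5; truncated at the
record boundaries rather than padded), a strictly-above threshold (default
0.28), and a run-length cleanup that flips episodes shorter than `min_run`
frames (default 5, ~20 s at 4 s/frame). The cleanup order is: short nuclear
runs removed first, then short gaps filled in the updated signal. Runs
touching either record boundary are exempt, since recordings routinely start
or end mid-episode; the pair of passes is iterated to a fixed point, making
the operation idempotent and guaranteeing no interior run shorter than
`min_run` (verified exhaustively over all binary signals up to length 14).

For a clean step of amplitude at least twice the threshold, the centred
`w`-frame mean crosses the threshold within ⌈w/2⌉ frames of the true onset;
with the defaults the detector is empirically exact to ±1 frame.

## Per-cell metrics and classification

Within an observation window (default 3600 s): `responded` means at least
one nuclear run starts in the window; `first_localization_time` is the time
of that run's first frame and is **censored** (reported as missing, never
imputed) otherwise; `total_nuclear_time` counts in-window nuclear frames
times the frame interval; events are maximal nuclear runs starting in the
window, and an event straddling the window end counts once but contributes
only its in-window frames. Classification is three-way: `permanent` if the
record (restricted to the window) ends inside a nuclear run spanning at
least `permanence_tail` seconds (default 600 — "sustained to the end" is not
otherwise quantified, so this is a configurable design choice),
`only_oscillating` if the cell responded but is not permanent, `no_response`
otherwise. Computing the classification on the windowed track keeps
`no_response` exactly equivalent to "not responded".

Population medians of time-to-first-localization are taken over responders
only, with the censored count reported alongside: at weak stimulation only a
minority responds within the record, and a face-value median over all cells
would be meaningless. Medians of total nuclear time run over all cells.

## Two-sample comparison

"Does condition B take larger values than condition A" is tested with the
Mann–Whitney U test, one-sided by default. For tie-free samples with at most
8 observations per group the exact null distribution of U is computed by the
standard counting recurrence (equivalent to enumerating all C(n1+n2, n2)
rank arrangements, at most 12 870 at the cutoff); larger or tied samples use
the normal approximation with continuity and tie corrections. Across 1000
random tie-free 8-vs-8 samples the two routes agree within |Δp| ≈ 0.011.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:
4 s frame interval, 60–150 min records, populations of order 100 cells, and
three archetypes — no response; oscillation bursts 120–180 s long generated
as a renewal process (exponential inter-burst gaps at `burst_rate` per
minute — only the typical burst duration is empirically constrained, the
renewal form is a modelling choice); and permanent entry after a log-normal
lag parameterized by its median (default 19 min) and log-sd (default 0.4,
chosen once as a realistic population spread; the real lag distribution is
only known to be right-skewed and to broaden at weak stimulation). The
default archetype mixture (0.2 / 0.5 / 0.3) emulates a strongly stimulated
population in which most cells respond and a subpopulation localizes
permanently. Trajectories are baseline (0) or nuclear (0.8, comfortably
above the 0.28 threshold; nucleus-to-cytosol ratios therefore span 1.0–1.8)
per the true state plus optional additive Gaussian noise.

The renderer draws each cell as a filled disc (radius 7 px, 149 pixels, so
at least 90 cytosolic pixels always remain after removing a 29-pixel
nucleus) with a concentric disc nucleus whose pixels are multiplied by
`nuclear_gain` (default 1.8) while the true state is nuclear. Optional pixel
noise is scaled-Poisson, calibrated so the relative sd at the cytosol
intensity equals the scenario's `noise_sd`. The renderer makes no attempt at
vacuoles, brightfield, photobleaching or segmentation difficulty — it
validates the intensity-to-metric chain, not contour finding — so passing
round-trip tests demonstrate correctness of the quantification pipeline, not
robustness to real segmentation error. All randomness flows from the
scenario seed through one `numpy.random.Generator`.

The expression generator produces flat traces (uninduced) or saturating
exponentials after a lag (induced; per-cell amplitudes log-normal), sampled
every 10 min for 5 h after a 40-min induction.

## Problem sizes and numerical choices

Validation runs use the population scale of the underlying experiments:
oracle checks on 1000 random regions, 500 random step onsets, exhaustive
run-cleanup verification to length 14, 1000 U-test trials, lag-recovery on
200-cell populations (records of 60 min for 7 and 19 min medians and 150 min
for the 32 min median, mirroring the longer follow-up used experimentally at
slow conditions so censoring does not bias the responders-only median), and
a 100-cell, 900-frame rendered stack for the full round trip. Noise-free
renderer/extractor agreement is asserted to 1e-9; table round trips are
bit-exact (values are written with shortest round-tripping repr; spreadsheet
import, being a foreign parser, is asserted to 1e-12 relative).

## Limitations

Cell contours must be supplied; there is no drift, bleaching, or focus
model; the burst renewal process and log-normal lag are conventions, not
fitted models; censoring is reported but not given a survival-analysis
treatment; no multiple-testing correction is applied across condition pairs.
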