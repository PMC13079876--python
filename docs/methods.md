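# Methods

This note documents the models and procedures implemented in
`fuccitrack`, the parameters that matter, the numerical choices behind
them, and what the synthetic data does and does not establish.

## Reference curve

A reference cycle is the average FUCCI intensity trajectory over one full
cell cycle, indexed by cycle percentage. `build_reference_curve` takes
full-cycle (mitosis-to-mitosis) tracks, maps each track's frames linearly
onto 0–100%, resamples every channel onto a common percentage grid by
linear interpolation (default 101 points, i.e. 1 point per percent), and
averages point-wise. The linear frame→percentage mapping assumes
approximately uniform progression within each source track; tracks of
different durations are brought into register purely through the
percentage axis, so the reference needs no absolute-time calibration.
An optional frame interval (minutes) is carried as metadata so pseudotime
can be converted to absolute time by multiplying with the cycle duration.
The averaging is robust to the number of source tracks — a single clean
track already defines a usable reference; more tracks reduce
cell-to-cell idiosyncrasy.

## Signal preparation

The alignment compares intensity *dynamics*, not absolute levels.
Per-channel preparation is: centered moving average (window shrinking at
the track boundaries), amplitude normalization, first difference. The
smoothing window default is 15 frames: at the default study conditions
(100-frame cycle, noise 5% of the dynamic range) this is the point where
noise-induced warping of the DTW path stops dominating without blurring
the phase transitions; it is a configuration knob (`AlignmentConfig.window`)
and should be scaled with the frame rate.

Amplitude normalization is where the key design freedom lies, and the
package implements four schemes (`AlignmentConfig.normalization`):

- **`windowed_pooled` (default).** Channels are mean-centered
  individually, but all channels of a track share one scale — the RMS of
  the per-channel standard deviations. The reference is re-normalized
  *per candidate window of the query's length*, with the bit-identical
  operator chain the query receives (including the shrinking-edge
  smoothing), and the best window start is selected by a batched dynamic
  program before the exact alignment runs on the winning window. Three
  properties motivate this default. (i) A query that is an exact
  reference slice attains distance exactly zero — the zero law holds all
  the way through `align_track`, not just at the feature level. (ii)
  Per-nucleus expression gain cancels, while the relative amplitude
  *between* the two channels — which encodes cycle stage — survives.
  (iii) A channel that is quiet over the query's window stays quiet.
  Under plain global z-scoring, a short query covering a low-variance
  part of the cycle has its faint trends amplified into full-swing
  shapes that match unrelated reference regions; in simulation this
  degrades pseudotime recovery from ~2 to ~8–12 percentage points RMSE
  and reproduces, in miniature, the known failure mode where cells with
  an extended G1 are mapped to the end of the cycle.
- **`windowed`** — as above but each channel z-scored independently per
  window (loses the inter-channel amplitude ratio).
- **`pooled`** — pooled scaling with a single global reference
  normalization.
- **`global`** — plain per-channel z-scoring of the query and of the
  whole reference; the most literal transform chain, kept for
  comparison.

## Subsequence DTW

`subsequence_dtw` aligns the full query against a free reference window
(open begin/end on the reference, closed on the query) with steps
{(1,0), (0,1), (1,1)} at unit weight. The local cost is the *squared*
Euclidean distance between feature vectors and the reported distance is
the square root of the accumulated cost — the true Euclidean distance
between the warped sequences. Squared costs matter beyond convention:
they penalize bad value matches quadratically, so a well-matching track
aligns near-diagonally while a non-conforming track is pushed into
visible time-axis warping, which is what makes the path-shape distortion
score informative.

Ties are broken deterministically: among equal-cost paths, fewer
non-diagonal steps win, then the earliest reference start, then the
earliest reference end; among equal predecessor costs the diagonal step
is preferred. This makes the distortion score a pure function of the
inputs.

The reference is tiled twice end-to-start (percentage continuing
100→200 ≡ 0→100) so queries straddling mitosis can match across the
wrap; pseudotime is reported modulo 100.

## Pseudotime

Features are first differences, so feature index `j` spans reference
points `j` and `j+1`; a path pair `(i, j)` associates query frame `i`
with point `j` and frame `i+1` with point `j+1`. Each frame's pseudotime
is the mean percentage of its associated reference points. It is not
forced monotone — local plateaus are a faithful readout of the warp —
but always lies within the matched window's span. On an exact reference
slice the assignment is exactly linear.

## Time distortion and arrest

`time_distortion` counts the non-diagonal steps of the optimal path —
expansions (0,1) plus compressions (1,0) — and
`relative_time_distortion` divides by the query length so tracks of
different lengths are comparable. `flag_arrest` thresholds this score;
the default threshold of 5.0 reproduces a published manual choice for
one cell line but is dataset-dependent. `suggest_arrest_threshold`
automates the histogram split: it cuts at the largest multiplicative gap
between consecutive sorted scores (geometric midpoint), which is
reliable exactly when the population is clearly bimodal.

Two caveats, established on synthetic populations and documented rather
than hidden:

- The step count of a *cost-optimal* path is only weakly informative for
  tracks whose signal is essentially structureless (e.g. a long-saturated
  arrested cell whose only dynamics are noise): warping occurs only where
  it lowers cost, so such tracks can receive mid-range distortion scores.
  Across seeded 20+20 normal/arrested populations the distortion score
  separates with AUC 0.98–1.0.
- The alignment distance per frame (`normalized_distance`) separates the
  same populations by a 2.5–25× margin on every seed tested, because a
  non-conforming track simply cannot match any reference window well. For
  short tracks it is the recommended non-conformity screen, and the
  end-to-end workflow uses it; the distortion score remains the primary,
  interpretable time-axis statistic.

Zero-variance (DARK) tracks are reported as *unalignable* — never as
arrested — and `align_tracks` carries this as a per-track status instead
of aborting a batch.

## Phase classification

`classify_intensity` implements the standard relative threshold: a
channel is "on" above 10% of its maximum signal
(`ClassifierConfig.relative_threshold`), and the on/off combination maps
to G1 (cyan only), G1/S (both), S/G2/M (magenta only) or DARK (neither).
DARK is an explicit outcome because both channels genuinely switch off
around mitosis; forcing a phase there would manufacture errors. The
maximum's scope is per track by default, with a per-dataset option.

`classify_tracks` adds dataset-scope baseline correction: the darkest
per-channel mask mean over the whole dataset (typically a nucleus passing
through mitosis) is subtracted before thresholding. Real movies carry a
non-specific nuclear baseline (autofluorescence, camera offset); without
correction the 10% rule never switches a channel off. Whether the
threshold applies to raw or corrected means is not standardized in the
field; correction is this package's documented choice for movie-level
work.

`map_phases` translates phase names between sensor conventions through
the shared color-combination key: the two-color appearance is G1/S under
the FUCCI convention but G2/M under PIP-FUCCI; magenta-only is S/G2/M
under FUCCI and S under PIP-FUCCI; G1 coincides; DARK maps to DARK.

## Segmentation and classification evaluation

Masks are matched one-to-one by maximizing total IoU (Hungarian
assignment on the thresholded IoU matrix); pairs below the threshold are
discarded. At IoU ≥ 0.5 the matching is unambiguous (two masks cannot
both overlap one object that strongly), which is why the package's
weighted assignment agrees exactly with a maximum-cardinality oracle
there. Accuracy (average precision) is `TP/(TP+FN+FP)`, precision
`TP/(TP+FP)`, and the FP ratio is FP over predicted masks.

Per-phase confusion matrices are indexed (predicted × ground truth).
Precision entries are normalized over matched masks of the predicted
class only; accuracy entries additionally count the unmatched
ground-truth masks of the column's class (FN) and the unmatched predicted
masks of the row's class (FP) in the denominator, so segmentation errors
propagate into the per-class accuracy. Rows without support are reported
as undefined (NaN), never as zero. DARK masks are excluded — a near-dark
nucleus carries no color information to classify.

The SNR of a movie is, per FUCCI channel, the background-corrected mean
in-mask intensity divided by the in-mask standard deviation (background =
mean over all non-mask pixels of the frame), maximized over the two
channels. It is invariant under positive affine intensity transforms by
construction. Note the in-mask standard deviation pools all masks, so it
contains the biological cycle-stage spread as well as pixel noise — a
high SNR under this estimator implies a bright nuclear pedestal relative
to that spread.

## Synthetic data

`CycleModel` drives per-track simulation: piecewise-linear intensity
profiles versus cycle percentage, a 100-frame cycle split 40/15/45%
(G1 / G1-S / S-G2-M) by default, a ±3% near-dark window at mitosis,
Gaussian intensity noise (default 5% of the dynamic range), optional
spectral bleed-through into cyan, and photobleaching (default 0.15% per
frame — a mild, realistic acquisition drift). The default profiles are a
minimal stylized reading of typical two-color reporter kinetics: a
saturating cyan rise through G1 with a steep fall across G1/S, a
decelerating magenta accumulation peaking late in the cycle with a sharp
mitotic drop, and intensity crossings placed so the 10% classifier
boundaries coincide with the configured phase fractions. Breakpoints are
spaced so the slope keeps changing — constant-slope stretches longer than
a typical query window would make window placement unidentifiable for
*any* dynamics-based method. They are a stand-in, not a measured curve
for any particular cell line.

Arrested cells progress at `arrest_speed` (default 0.15×) of the normal
pace until a late-G1 plateau (default 35%), then hold: a checkpoint-
arrested cell still slowly accumulates the G1 reporter rather than
freezing instantly, and population draws start arrested cells within G1
(a cell arrested at the G1 checkpoint cannot sit in S/G2/M).

`render_movie` draws nuclei as ellipses on seeded random walks, fills
the cyan/magenta channels from the track intensities, optionally adds a
cytoplasmic (tubulin-like) annulus with a nucleus-shaped void and
bleed-through into cyan, and — when a target SNR is requested — solves
for a uniform nuclear baseline and an additive Gaussian pixel noise such
that the SNR estimator on the rendered output hits the target (bisection
on the closed-form estimator applied to the noiseless render; a small
global pedestal keeps zero-clipping negligible). All stochastic draws
flow through a single seed; renders are bit-reproducible.

What the simulator does *not* emulate: photorealistic PSF/optics,
Poisson (shot) noise statistics, mitotic rounding and nuclear shape
change, confluent packing with touching nuclei, segmentation errors
(ground-truth masks are exact), and tracking errors. Passing tests on
synthetic data therefore establish the correctness and calibration of
the analysis chain under controlled conditions — not performance on any
acquired dataset, where segmentation quality and sensor idiosyncrasies
dominate.

## Problem sizes and defaults used in the acceptance checks

- DTW oracle suite: 100 random pairs, query ≤ 8, reference ≤ 12.
- Zero law: 50 random exact-slice cases on 100-interval references.
- Pseudotime recovery: 50 tracks, 100-frame cycle, 30-frame windows,
  noise σ = 5% of dynamic range; circular RMSE target < 5 points.
- Arrest separation: 20 normal + 20 arrested tracks of 100 frames at the
  same noise.
- Matching oracle: 50 random 64×64 label-image pairs, ≤ 10 objects each.
- End-to-end movie: 10 nuclei, 60 frames, 256×256, target SNR 4,
  tubulin channel with 5% bleed-through, 20% arrest fraction.

## Known limitations

- Dynamics-only alignment carries no absolute-intensity information; a
  track whose dynamics mimic a different cycle region at a different pace
  can be mis-staged. The distortion and distance scores exist to flag
  exactly these cases; report them alongside any pseudotime.
- The distortion threshold (default 5.0) does not transfer between
  datasets, sampling rates, or reference grids; derive it from the
  score histogram of each dataset.
- Gap-closed (interpolated) spots have no mask and contribute no
  measured intensity; their values are linearly interpolated in time,
  which slightly smooths real dynamics across gaps.
- The per-track classifier scope fails on tracks that never express one
  channel (the threshold is then relative to noise); use the dataset
  scope for short or arrested tracks.
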