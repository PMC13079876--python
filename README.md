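# fuccitrack

Quantify cell-cycle progression from tracked two-color FUCCI reporter
movies. The FUCCI sensor marks cell-cycle phases by color combination —
cyan-only in G1, both colors across the G1/S transition, magenta-only in
S/G2/M, with both channels near-dark around mitosis. `fuccitrack` turns
segmented, tracked FUCCI time-lapse data into:

- **cell-cycle pseudotime** — the position of each cell on a 0–100% cycle
  axis, inferred by aligning its nuclear intensity track to a reference
  cycle with subsequence dynamic time warping (DTW), so that *partial*
  tracks (that do not span a whole cycle) can still be staged;
- **an arrest score** — the *relative time distortion* of the optimal
  warping path, which is small for cells following the reference cycle and
  large for non-conforming cells such as G1-arrested ones;
- **phase calls** — the classic intensity-threshold classifier (a channel
  is "on" above 10% of its maximum) plus translation between sensor
  conventions (FUCCI ↔ PIP-FUCCI);
- **evaluation metrics** for instance segmentations and classifiers —
  IoU-matched accuracy `TP/(TP+FN+FP)`, precision `TP/(TP+FP)`, per-phase
  confusion matrices, and the in-mask/background SNR estimator;
- **a synthetic movie generator** producing multichannel FUCCI time-lapses
  with ground-truth masks, tracks, phases and cycle percentages, so every
  step of the pipeline is testable without any acquired data.

It is aimed at labs doing live-cell FUCCI imaging who already have
segmentation masks and tracking results (tracker XML export) and want
reproducible cycle staging and arrest screening downstream.

## The method

Let `r(p)` be the reference curve: mean cyan/magenta nuclear intensity as
a function of cycle percentage `p ∈ [0, 100]`, averaged from full-cycle
(mitosis-to-mitosis) tracks resampled onto a common percentage grid. A
query track `q(t)`, `t = 1..n` frames, is prepared per channel by
smoothing (centered moving average), amplitude normalization, and first
differencing, and the same operator chain is applied to the reference.
Subsequence DTW then finds the monotone warping path minimizing the
Euclidean distance between the warped query and a reference window, open
at both ends on the reference and closed on the query:

    D(q, r) = min over windows [s,e] and paths π of sqrt( Σ_(i,j)∈π ‖q̃_i − r̃_j‖² )

The matched reference percentages give each frame its pseudotime. The
number of non-diagonal steps in the optimal path (expansions plus
compressions of the time axis), divided by the track length, is the
**relative time distortion**; cells above a threshold (default 5.0,
dataset-dependent — derive your own with `suggest_arrest_threshold`) are
flagged as arrested. The alignment distance per frame
(`AlignmentResult.normalized_distance`) is also reported: it measures how
well the track's *dynamics* match the reference at all and is the most
robust screen for non-conforming cells on short tracks.

Because the alignment runs on normalized derivatives it is invariant to
per-nucleus expression level — and therefore blind to absolute
intensities, a documented limitation: always check the distortion and
distance scores before trusting a pseudotime.

## Worked example

```python
import numpy as np
import fuccitrack as ft

# reference cycle from noiseless full-cycle tracks
model = ft.CycleModel(noise_sigma=0.0, bleaching=0.0)
full_cycle, _ = ft.simulate_fucci_track(model, 0.0, 101)
reference = ft.build_reference_curve([full_cycle])

# a noisy 40-frame track starting at 30% of the cycle, and a G1-arrested one
noisy = ft.CycleModel(noise_sigma=0.05, seed=0)
rng = np.random.default_rng(0)
normal, truth = ft.simulate_fucci_track(noisy, 30.0, 40, rng=rng)
arrested, _ = ft.simulate_fucci_track(noisy, 12.0, 40, arrested=True, rng=rng)

for name, track in [("normal", normal), ("arrested", arrested)]:
    r = ft.align_track(track, reference)
    print(f"{name}: pseudotime[0..4] = {np.round(r.pseudotime[:5], 1)}")
    print(f"{name}: relative time distortion = {r.relative_time_distortion:.3f}, "
          f"distance/frame = {r.normalized_distance:.4f}")
```

prints

```
normal: pseudotime[0..4] = [33.  33.5 33.5 33.5 34. ]
normal: relative time distortion = 0.250, distance/frame = 0.0027
arrested: pseudotime[0..4] = [12.  12.5 12.5 12.5 13. ]
arrested: relative time distortion = 0.625, distance/frame = 0.0188
```

The normal track is staged within ~3 percentage points of its true cycle
position throughout, with a near-diagonal warp (low distortion) and a
tight match (low distance). The arrested track — whose G1 reporter rises
an order of magnitude slower than the reference pace — needs 2.5× the
warping and matches 7× worse; on a population, the two score
distributions form the two modes that `suggest_arrest_threshold` splits.

The same workflow runs from the shell on real or simulated data:

```
fucci simulate movie --seed 1 --frames 60 --n-nuclei 10 --target-snr 4 \
      --tubulin --arrest-fraction 0.2 --out-dir movie/
fucci extract  --images movie/images.tif --labels movie/labels.tif \
      --tracks movie/tracks.xml --out intensities.csv
fucci classify --tracks intensities.csv --out phases.csv
fucci align    --tracks intensities.csv --reference ref.csv --threshold 5 \
      --out alignment.csv
```

`fucci eval-seg`, `fucci snr`, `fucci dapi-equiv`, `fucci merge-masks` and
`fucci filter-crops` cover segmentation evaluation and the classic
preprocessing operators; see `fucci --help`.

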