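# Methods

`lfiaquant` quantifies multi-test-line lateral flow immunoassay (LFIA)
strips from grayscale photographs. A valid strip carries one dark control
line (C) that always develops, and up to three test lines (T1–T3) at fixed
spacing whose darkness grows with analyte concentration. The pipeline
locates the four lines, reads a background-corrected intensity feature, and
converts it to concentration through a fitted standard curve.

## Detection model and assumptions

The strip is assumed pre-cropped to the membrane window, landscape, with
the control line in the left half (a fixed imaging jig makes this a
protocol guarantee; `load_grayscale` additionally mirrors the image when
the darkest column cluster sits in the right half). Lines are vertical,
darker than the membrane, and effectively constant along the row
direction, so the image is well summarized by its column-sum profile
`S_j = Σ_i I_{i,j}`.

Stages, all operating on an 8-bit grayscale matrix:

1. **Median denoising.** A `k x k` median filter (default `k = 5`,
   edge-replicated) removes impulse and shot noise while keeping line
   edges. Denoising runs first: the control-line segmentation of stage 2
   keeps a run of columns only ~30 gray levels deeper than the profile
   minimum, and on noisy images single-column fluctuations split that run
   below the minimum-width gate, failing otherwise valid strips.
2. **Control line.** The column profile of the left half is binarized at
   `(MinValue + I) · H`, where `MinValue` is the darkest column's mean
   intensity and `I = 30` gray levels. This threshold is "just deep
   enough" to keep only the darkest line. The darkest contiguous
   below-threshold run is the control line, accepted when wider than 5
   columns with a positive right edge. A run spanning the whole left half
   means the image has no contrast and is rejected. (A mirror-product
   formulation of this step — multiplying the binary mask by its own
   left-half reflection — annihilates any line that is not centered on the
   half's midline, so the run itself is used directly.)
3. **Adaptive binarization (diagnostic).** The image is thresholded at
   `factor · mean`, starting at factor 1.0 and decreasing by 0.05 down to
   0.5 until the mask's SNR reaches 0.75; a final 3×3-cross morphological
   opening cleans the mask when the loop fails. SNR is defined as the
   fraction of foreground pixels lying in column runs wider than the
   minimum control width — 1.0 for a mask whose foreground is all genuine
   lines. The mask and SNR are reported for QC; line positions come from
   stage 4.
4. **Candidate test lines.** On the inverted image (`255 − I`, lines are
   peaks) a binary mask at `1.5 × mean` is collapsed to a per-column
   foreground flag; maximal runs of flagged columns give the `head`/`end`
   edge lists. A symmetry response is computed alongside:
   `D = I_left ⊙ I_mirror` and `c_vec[k] = Σ_x D[x,k] · S_inv[x]`, with
   the contraction index running over the shared range `min(H, W)` (for
   landscape strips, all rows). The literal index pairing of this
   contraction is ambiguous in the underlying description; the triple-loop
   reading implemented here is frozen by an exact brute-force oracle test
   and only serves to rank candidate positions inside imputation windows.
5. **Refinement.** Runs whose width differs from the control run's by more
   than 4× in either direction are discarded (no published constant; 4×
   tolerates faint-vs-dark width variation while rejecting speckle).
   Adjacent runs separated by less than `2 × (0.25 · expected_gap)` are
   fused as fragments of one line. `expected_gap` is the assay's designed
   line spacing, a configuration input.
6. **Finalization.** Exactly four regions come out. Each detected run is
   assigned to its nearest nominal slot `control_center + m · gap`
   (m = 1..3, within half a gap); the strongest run per slot wins. Missing
   test lines are imputed at their nominal position, searched over a
   window widened by three control widths and snapped to the local
   `c_vec` maximum. Every output region is a nominal-width window centered
   on the detected (or imputed) line center: a thresholded run's width
   varies with line darkness, while the printed line width is fixed by the
   assay, so width-normalized windows make head/end positions comparable
   across faint and dark lines and let a blank strip report zero features
   instead of an error.

## Feature readout

Each region's inverted sub-image is blurred with a sampled, sum-normalized
Gaussian kernel (σ = 2 px, radius ⌈3σ⌉, reflect-padded — constants pass
through unchanged). The region signal is the maximum of the blurred
region's per-column mean profile. For an ideal vertical line the
column-mean equals the per-pixel ridge value, so the two readouts agree on
clean strips; the column mean averages H pixels and is therefore far less
biased by texture-noise extremes, which is what keeps a blank strip's Y1
within ±0.02 of zero. A Gaussian line of cross-section width `s` blurred
with width `σ` keeps a fraction `s/√(s²+σ²)` of its amplitude; this closed
form anchors the readout tests.

`ARG` is the mean inverted intensity over all columns outside the four
regions (full image height). Signals below ARG are replaced by ARG, making

    Y1 = (T1 + T2 + T3 − 3·ARG) / C ≥ 0,     Y2 = (T1 − ARG) / C ≥ 0.

Both are ratios to the control signal and hence invariant under global
intensity scaling.

## Calibration

The standard curve is an ε-SVR (RBF kernel) from Y1 to concentration.
Concentration spans 0–1500 μg/mL, so the regression target is
`log10(1 + c)`, back-transformed and clipped at zero before any statistic.
Hyperparameters are chosen by exhaustive deterministic grid search —
penalty ∈ {1, 10, 100, 1000}, γ ∈ {0.01, 0.1, 1, 10},
ε ∈ {0.001, 0.01, 0.1} — minimizing training `SS_res` on the original
scale; ties keep the first combination in product order. Goodness of fit
is `R² = 1 − SS_res/SS_tot` on the original concentration scale, computed
on the training pairs (in-sample, matching how such curves are usually
reported). Models serialize to JSON as (training pairs + chosen
hyperparameters); refitting on load is deterministic, so reloaded models
predict bit-identically.

Note that replicate scatter bounds the in-sample R² of any Y1→c function:
the packaged reference table contains near-identical Y1 values at 800,
1000 and 1300 μg/mL, which caps its 65-pair training R² at ≈ 0.91 for this
grid. Fitting the 13 per-concentration means instead reaches R² > 0.999.

Band accuracy follows the assay's three strata (low 0–50, medium 80–500,
high 800–1500 μg/mL): a prediction is correct when its relative error is
≤ 20% (configurable); a zero truth is scored on absolute error against
20% of the low band's upper edge. The 20% tolerance is this package's
operational definition of a "correct" quantitative reading — no standard
one exists for LFIA readers.

## Synthetic strips

The generator renders what the detection stages assume: a flat membrane at
gray level 220 with N(0, 3²) texture, Gaussian-profile vertical lines
(cross-section σ = 4 px) subtracted from it — control amplitude 120 at
column 90, test lines at 120-column spacing with amplitudes
`(1.0, 0.8, 0.6) × a(c)`, where `a(c) = 110·c/(300 + c)` is a Hill-type
response chosen so synthetic Y1 spans ≈ 0–1.4 over 0–1500 μg/mL, the same
numeric regime as real readings. Default images are 200×600 px, about the
cropped-membrane resolution of a phone photograph. Ground truth records
each line's center, amplitude, and nominal edges (center ± 2σ, matching
the finalizer's nominal window). Noise models: salt-and-pepper (pixel →
0/255 with probability level/2 each, default density 0.05), additive
Gaussian (default σ = 10), and Poisson shot noise (pixel →
`Poisson(v·s)/s`, default scale 1). All randomness flows through one
`numpy` Generator per call; identical specs render bit-identical strips.

What the generator does *not* emulate: illumination gradients, perspective
and rotation, membrane defects, color. Passing tests therefore demonstrate
the pipeline's numerical and geometric correctness and its noise
robustness, not performance on uncontrolled photographs.

## Experiment harnesses and problem sizes

- *Position recovery*: 50 seeded strips with every line amplitude ≥ 40
  gray levels (concentrations ≥ 520 μg/mL); all four lines must land
  within ±2 columns of ground truth (100% control, ≥ 98% test lines).
- *Band robustness*: the standard curve is calibrated on clean synthetic
  strips (3 replicates × 13 design concentrations), then 20 noisy strips
  per band — cycling the three noise models at default levels — are
  predicted and scored. Darker lines survive noise better, so accuracy is
  ordered high ≥ medium ≥ low.
- *Hill-recovery property*: 20 replicate calibration sets (n = 65) with 3%
  multiplicative replicate scatter must fit with R² > 0.95 in ≥ 19/20
  runs. On the concentration scale, feature noise amplifies through the
  flat saturating branch of the response, so concentration-scale R² is
  much more noise-sensitive than it may appear (the same mechanism that
  caps the reference-table fit above).

## Numerical choices and degenerate inputs

- Grayscale conversion is Rec.601 luminance, rounded to integers.
- Coordinates are 0-based; head/end intervals are inclusive on both ends.
- `MinValue` is kept on the per-pixel scale so the `I = 30` offset is a
  gray-level increment.
- Tie-breaks: equal-strength candidate runs keep the leftmost; flat
  imputation windows keep the nominal center.
- Constant images: no control line (nothing segmented); empty transition
  lists are legal and flow into imputation; an all-background mask from
  adaptive binarization is legal.
- A failed strip raises a typed `StripAnalysisError`; the batch pipeline
  converts it into a per-image failure report and continues.

## Known limitations

- The width-similarity (4×), merge-fraction (0.25), SNR definition and
  factor-loop bounds (1.0 → 0.5) are this package's own concrete choices
  for steps whose published description gives no constants.
- The finalizer trusts the configured geometry; a strip whose physical
  line spacing differs from `expected_gap` by more than half a gap will
  have test lines imputed at wrong positions rather than rejected.
- In-sample R² overstates predictive performance when replicate scatter is
  large; no cross-validation or prediction intervals are provided.
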