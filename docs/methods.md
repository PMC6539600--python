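# Methods

## Signal model and feature definitions

The analysis object is the palm-centre lateral position Cp(x), a real
series in mm sampled at fs = 40 /s for 15 s (n = 600). SDH texture features
need discrete levels, so the series is first quantized:

    k(l) = round((x(l) − min x) / Δ),     Δ = bin width, default 0.1 mm.

Anchoring the offset at the per-recording minimum keeps levels non-negative
and bounds the de-quantization error by Δ/2; because the difference
histogram depends only on level differences, contrast and homogeneity are
invariant to any constant shift of the raw signal (exactly so for shifts
that are multiples of Δ, to within one level otherwise). Δ = 0.1 mm
preserves the sensor's sub-millimetre resolution while keeping histogram
supports small; it is configurable everywhere.

Sum and difference vectors at displacement M (default 1) are computed once
over the full series, and windows of N consecutive entries are then taken
with stride 1 (maximal overlap; configurable) — difference vector first,
windows second, matching the order in which the procedure is defined. Each
window's counts are divided by N, giving normalized histograms ĥS, ĥD, and
the nine features are:

| feature | formula (μ = ½ Σ j ĥS(j)) | units |
|---|---|---|
| mean | μ | levels |
| variance | ½(Σ (j−2μ)² ĥS + Σ k² ĥD) | levels² |
| energy | (Σ ĥS²)(Σ ĥD²) | — |
| correlation | ½(Σ (j−2μ)² ĥS − Σ k² ĥD) | levels² |
| entropy | −Σ ĥS ln ĥS − Σ ĥD ln ĥD | nats |
| contrast | Σ k² ĥD(k) | levels² |
| homogeneity | Σ ĥD(k)/(1+\|k\|) | — |
| cluster shade | Σ (j−2μ)³ ĥS | levels³ |
| cluster prominence | Σ (j−2μ)⁴ ĥS | levels⁴ |

Numerical conventions: 0·log 0 := 0; entropy uses the natural log (the base
only rescales). An exact algebraic identity links the moments:
contrast = variance − correlation, which the test suite asserts for every
window. Useful limits: a constant window gives contrast 0, homogeneity 1,
entropy 0, energy 1; for a sinusoid of amplitude A and frequency f with
Δ ≪ A and a window spanning many periods,
contrast·Δ² → 2A²sin²(πf/fs) — verified to well under 5%.

The homogeneity denominator is written 1+l in some descriptions of the
1-D adaptation, which is undefined at l = −1 for signed differences. Two
readings keep the weight in (0, 1]: magnitude-based 1/(1+|l|) (the default
here) and squared 1/(1+l²) (the form in the original 2-D treatment); both
are exposed via `kernel=` and neither is asserted as the original authors'
exact choice.

## Synthetic cohort

Real clinic recordings are private, so the generator produces captures in
the same 40-channel schema:

* palm x = task trajectory + A·sin(2πft + φ) + N(0, σ²); f ~ U(4, 6) Hz
  and φ drawn once per recording; the task trajectory is a 10 s plateau
  followed by a C¹ smoothstep ramp of 100 mm (sign set by hand).
* level amplitudes A: 0.2 / 1.5 / 4.0 mm for levels 0/1/2. No amplitude
  statistics exist for the study population; these are free parameters
  chosen once so that level 0 (normal micro-movement) and level 1
  (earliest visible tremor) lie close while level 2 is clearly separated,
  reproducing the clinical difficulty ordering. Sensor noise σ = 0.05 mm
  reflects the depth sensor's sub-millimetre accuracy.
* fingertips follow the palm rigidly at fixed offsets (only palm channels
  are analysed downstream); palm y/z are constant plus noise, so tremor
  lives on x only; velocities are forward differences × fs; the rotation
  quaternion is identity.

The default composition reproduces the clinic table: per (level, gender,
hand) counts 7/6, 5/4 (level 0 F/M right/left), 2/3, 4/5 (level 1), 0/0,
1/2 (level 2), plus one male level-3 right hand that exists only as a
metadata manifest entry and is removed by the exclusion step — 39 simulated
recordings. Per-recording seeds derive from the master seed via
`SeedSequence([master, index])`.

What the simulator does *not* model: re-emergent tremor latency, amplitude
fluctuation over the capture, frequency drift, tracking dropouts, task
errors, or gender effects. Consequently, passing pipeline tests show that
the method recovers a stationary additive oscillation whose variance grows
with class label — they do not certify clinical performance, where class
overlap is far larger. On this synthetic cohort the classifier saturates
near accuracy 1.0 at large windows; the informative checks are the ordering
ones (accuracy non-decreasing with window size, tremor axis beating the
quiet axes), not the absolute level.

## Evaluation protocol

Windows from all retained recordings and both hands are pooled (left/right
are never mirrored) and labeled with their recording's tremor level.
Balancing undersamples to the smallest class before the 70/30 split, in
that order. The default split is window-level, as in the study protocol;
because overlapping windows of one recording are strongly correlated, this
split leaks recording identity across sides and inflates absolute accuracy.
A recording-level grouping (all windows of a recording on one side) is
provided as the leakage-safe alternative; the package offers both and
asserts neither as the original study's behaviour.

Classifiers: bagged trees = scikit-learn `BaggingClassifier` over unlimited-
depth decision trees, 30 learners, bootstrap size = train size; "fine"
k-nearest-neighbour = k = 1, Euclidean distance, with features standardized
before the distance — the nine features span ~12 orders of magnitude
(cluster prominence is a fourth moment of integer levels), so unscaled
Euclidean distance would be determined by a single feature; `standardize=False`
restores raw distances. k and the learner count are configurable since the
original presets' hyperparameters are not published.

Metrics are computed from the 3×3 confusion matrix: overall accuracy and
one-vs-rest precision, sensitivity, specificity per class; 0/0 ratios are
reported as NaN, never as 0. Repetitions re-balance, re-split and re-train
with seeds derived as `SeedSequence([master, rep])`; summaries report
min/mean/max per metric.

## Experiments and problem sizes

* Coordinate selection (window 125, all nine features per channel) compares
  Cp(x), Cp(y), Cp(z) and Cp(x,y,z) across registered classifiers; 5
  repetitions per cell by default (the repetition count for this stage is
  not published; 5 keeps the table stable at modest cost).
* Feature sweep evaluates each single feature over a window grid for both
  classifiers; 3 repetitions per cell by default.
* Window sweep evaluates chosen feature sets (default: contrast and
  homogeneity separately) over the grid with the full metric battery, 30
  repetitions, and produces a focal-size report at 149/299/449 — the grid
  quartiles. The full grid is the 250 odd sizes 3..501 (the unique uniform
  grid with the published count and range; the exact spacing is inferred,
  not stated).

Every sweep cell's seed is a SHA-256 hash of (master seed, window size,
feature set, classifier) reduced mod 2³¹, so any sub-grid reproduces the
corresponding cells of a larger run exactly.

The acceptance script and test suite run reduced problem sizes chosen as
the package's defaults for desk-scale verification: the 39-recording
default cohort, sweep grid {9, 49, 149, 299, 449} with 10 repetitions, and
5 repetitions for coordinate selection.

## Known limitations

* Absolute accuracies on the synthetic cohort are near-perfect and say
  nothing quantitative about clinical data; only orderings transfer.
* The window-level split's leakage is reported, not corrected, to keep the
  default protocol faithful.
* Quantization of the clinical pipeline (whether and at what resolution the
  original analysis discretized positions) is unknown; results here are
  stated per bin width.
* M > 1 displacements are supported but unswept.
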