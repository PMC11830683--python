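# Methods

`cappheno` measures shiitake cap phenotypes from single-cap photographs and
predicts cap weight from those phenotypes. This note records the models and
procedures implemented, the parameters that matter, the calibration choices
made where the design was open, and what the synthetic benchmark does and
does not demonstrate.

## Segmentation: KD-seeded K-means ("KD-Kmeans")

Each frame shows one cap on a uniform coloured backdrop (deep red or deep
green). Pixels are clustered in RGB space with k = 2 K-means. Initial
centres come from a median-split KD-tree over the pixel colours (leaf size
32): leaf mean colours are candidates and a greedy farthest-point sweep
picks the k most spread ones, seeded deterministically from the candidate
farthest from the global mean. Lloyd iterations run to zero label changes
(cap 100); an emptied cluster is reseeded with the point farthest from its
assigned centre. For tiny inputs (≤ 16 points) the KD seeding degenerates
to one leaf, so the solver instead restarts Lloyd from every k-subset of
the points and keeps the lowest inertia; K-means remains a local search,
and rare adversarial tiny configurations can still end a hair above the
global optimum.

The background cluster is the one owning the majority of image-border
pixels (a tie is an error, not a guess). The other cluster is reduced to
its largest 8-connected component and its holes are filled — dark surface
cracks cluster with the background and would otherwise puncture the mask.

## Edge extraction (classical chain)

Grayscale (BT.601 weights, rounded half-up) → Gaussian blur → Sobel
gradient magnitude → texture suppression → threshold (Otsu on a 256-bin
histogram of normalised magnitudes, strict `>`) → Moore boundary tracing →
small-area elimination. The surviving outer contours, rasterised, are the
final one-pixel edge map; their number is the contour count. Each surviving
edge pixel also carries a confidence in [0.2, 1] ranking it by its
(suppressed) gradient magnitude, which is what threshold-sweeping
evaluation consumes.

Parameter defaults and why:

- **Blur σ = 1.0, kernel 5 × 5.** The evaluation tolerance is 0.75 % of
  the image diagonal (≈ 2.7 px at 256 px frames); a wider blur delocalises
  the boundary ridge past that tolerance, costing F-score with no noise
  benefit at the noise levels modelled.
- **min_area = 400 px² at the 512 × 512 reference, scaled by image area.**
  Residual texture blobs measure ≤ ~260 px² (512² scale); the smallest
  plausible cap is > 20 000 px². 400 sits an order of magnitude from both.
- **Otsu by default**; a fixed threshold is available (`method="fixed"`).

Contours are traced by Moore boundary following with Jacob's stopping
criterion, starting at the topmost-then-leftmost pixel, clockwise; thin
sections are traversed out and back so every chain is a closed cycle.
Holes yield separate inner contours.

## Texture suppression (LBP + half-Gaussian)

Dried caps carry radial cracks whose gradient response rivals the true
boundary. The suppression weight is

    w(s) = 1                                  s ≤ τ
         = exp(−(s − τ)² / (2 σ_s²))          s > τ

applied multiplicatively to the gradient map, where `s` is the local
texture score: the fraction of non-uniform LBP codes (more than two
circular 0/1 transitions) in an odd window (default 9 × 9).

Two calibration facts shaped the defaults, both measurable with the
package itself:

1. Radius-1 LBP is threshold-free: any noise flips its bits, and clean
   straight lines (crack walls, cap boundary) produce *uniform* codes. Raw
   or blurred grayscale therefore cannot separate cracks from anything.
   The LBP input is instead a **quantised bottom-hat transform**: greyscale
   closing (9 × 9) minus the image isolates dark structures thinner than
   the footprint, and floor-division by 40 intensity steps — above the
   ~4 σ bottom-hat amplitude of pixel noise, below the crack contrast —
   leaves smooth regions and step edges *exactly* constant (LBP-uniform,
   score 0) and cracks as multi-level speckle.
2. The non-uniform-fraction score is bounded well below 1: a pixel that is
   a local extremum always codes uniform (all ties count as ≥), so even
   ideal dense texture saturates near 0.5. The weight must therefore roll
   off over the observed crack-score range (≈ 0.15–0.35) while staying at
   identity for the boundary and background (score exactly 0 on the
   bottom-hat input). Defaults: **τ = 0.05, σ_s = 0.10**.

Measured on cracked fixtures (noise σ = 8, 12 cracks), suppression removes
65–75 % of the gradient mass strictly interior to the cap while changing
the boundary-band mass by < 1 %.

## Trait measurement

Eleven traits per cap, from the mask and its outer contour:

- **Area**: shoelace area of the contour polygon; for pixel chains the
  exact lattice-polygon correction (+B/2 + 1, Pick's theorem) is applied so
  the value equals the enclosed pixel count. `corrected=False` gives the
  plain shoelace value.
- **Perimeter**: closed polygon arc length; unit/diagonal lattice steps are
  scaled by Kulpa's factor π(1+√2)/8, removing the ~5 % chain-length bias
  of digitised smooth boundaries (measured +4.9 % on an r = 50 circle raw,
  −0.5 % corrected). True polygon edges are never rescaled.
- **External rectangle**: minimum-area enclosing rotated rectangle via
  rotating calipers on the convex hull; length ≥ width by convention.
- **Roundness**: width/length of that rectangle, in (0, 1]. (The trait
  table's "ratio of length to width" is implemented in the bounded
  orientation-free form, the only reading consistent with its reported
  0.57–0.9 range at near-equal mean length and width.)
- **Long/short axis**: the moment-equivalent ellipse, 4·√(eigenvalues of
  the pixel-coordinate covariance) — deterministic and closed-form
  testable, unlike boundary ellipse fitting.
- **Colour means**: R/G/B channel means over the mask; the greyscale mean
  is the BT.601 luminance of those means (identically the mean per-pixel
  luminance, computed unrounded).
- **Calibration**: lengths × f, areas × f², with f = 0.043 mm/px by
  default (the rig's derived conversion factor); the pixel-unit record
  stays attached to every calibrated phenotype.

A caveat on the external rectangle: for mildly eccentric caps at
orientations ≈ 15–25° off-lattice, the minimum-area rectangle of the
*digitised* region can genuinely sit at a different angle than the
continuous ellipse's (2a × 2b) box (lattice truncation shaves ~2 px off
axis-aligned extents), deviating up to ~3 % in length. This is a property
of digitisation, not an estimator error.

## Edge-quality evaluation

Correspondence-based scoring: predicted edge pixels match ground-truth
pixels one-to-one within a distance tolerance (default 0.75 % of the image
diagonal, the BSDS convention), by maximum-cardinality bipartite matching
on the tolerance graph (Hopcroft–Karp); matched = TP, unmatched predicted
= FP, unmatched truth = FN. P = TP/(TP+FP), R = TP/(TP+FN), F their
harmonic mean with the zero convention.

Dataset summaries: ODS is the F of pooled counts at the single best
threshold; OIS averages each image's own best-threshold F; AP is the
trapezoidal area under the recall-sorted precision envelope. Probability
maps are swept over 99 evenly spaced thresholds; boolean maps are scored
at their single implicit threshold. Note that OIS ≥ ODS is a property of
threshold adaptation, not a theorem: with a single threshold OIS is a mean
of per-image F while ODS is a ratio of pooled sums, and the pooled value
can exceed the mean by a hair (Simpson-style aggregation). On
confidence-valued predictions the inequality holds with margin.

## Weight model

Trait–weight Pearson correlations rank the eleven traits; traits with
|r| < 0.01 are excluded. The fixed nested input groups are
M1 = {Area, Perimeter, External rectangular width, Long axis} ⊃ M2 ⊃
M3 = {Area, Perimeter} ⊃ M4 = {Perimeter}; a data-driven mode nests the
top four traits of the table at hand instead.

The regressor is an RBF-kernel ε-SVR on min–max-normalised features and
target. Hyperparameters (C, γ, ε) are tuned by the canonical Grey Wolf
Optimizer — wolves move toward the three current best under an exploration
coefficient decaying linearly 2 → 0 — minimising mean 5-fold CV RMSE, in
log10 space over C ∈ [10⁻², 10³], γ ∈ [10⁻⁴, 10], ε ∈ [10⁻³, 1]. Defaults
are 20 wolves × 100 iterations; tests and the acceptance script use
15 × 25, which on the recovery problem loses nothing measurable (the
objective landscape is smooth and the optimum basin wide). The final model
refits on all data at the best triple; CV metrics are recorded on the
normalised scale, with RMSE also restated in grams. Models serialise to
JSON (group, normalisation, hyperparameters, support vectors, dual
coefficients, intercept) and reload into an exact RBF predictor.

The LSTM-family models (LSTM, BiLSTM, Optuna-tuned LSTM, WOA-BiLSTM with
attention) are registered plug-in slots that raise until an implementation
is registered; no architecture or sequence construction for tabular input
is defined for them here.

## Synthetic data: what it emulates and what it does not

**Frames.** One rotated elliptical cap per frame on a uniform backdrop
(deep red (140, 30, 30) or deep green (15, 85, 35), both ≈ 50 luminance
steps below the default cap colour (150, 100, 60)); optional radial cracks
drawn strictly interior to the ellipse scaled by 0.88, as 7 px-wide rough
seams of 3-level per-pixel speckle (0 / half / full of the 90-step
contrast); i.i.d. Gaussian channel noise clipped to [0, 255]. Ground truth
is exact: the mask, its thin boundary (mask pixels with an orthogonal
background neighbour — one pixel wide and 8-connected as a path), and an
analytic phenotype (area πab, Ramanujan perimeter
π[3(a+b) − √((3a+b)(a+3b))], axes 2a/2b, oriented box 2a × 2b, colour
means of the painted pixels).

Not modelled: lighting gradients, shadows, specular highlights, non-
elliptical cap outlines, background contamination. Passing the edge
benchmark therefore demonstrates the chain's behaviour under controlled
noise and texture, not performance on field imagery.

**Tables.** The 686-sample phenotype–weight table is emulated with a
latent cap-size factor: each trait is an affine map of
a_f·s + √(1−a_f²)·u_f (s shared, u_f independent standard normals), with
ranges read as ±3 σ bands of the published per-trait min/max. Weight is an
exactly linear combination of the traits (default: unit-variance
coefficients 1.0 on Perimeter and 0.75 on Area) rescaled to mean 125 g,
SD 25 g, plus Gaussian noise (default 10 g). Independent features cannot
reproduce the published correlation profile — the squared correlations sum
past one — which is why the latent factor exists. The population
feature–weight correlations have a closed form (exposed as
`population_feature_weight_correlations`) and the default loadings were
set once so the population ordering mirrors the published ranking
(Perimeter 0.91 > Area 0.90 > Greyscale mean 0.74 > …), with the two
excluded traits (Roundness, Short axis) given near-zero loadings. At
n = 686 the sampling noise on a near-zero correlation is ≈ 0.04, so the
"|r| < 0.01" exclusion reproduces in population values, not reliably in
any single sample.

**Recovery condition.** The parameter-recovery benchmark uses n = 500,
weight = 0.5·Area + 0.5·Perimeter (unit-variance scale) with noise equal
to 3 % of the weight span; the noise ceiling puts the best attainable
held-out R² near 0.97, and the tuned SVR reaches 0.96–0.97 across seeds.

## Problem sizes

The edge benchmark runs 20 frames at 256 px in the test suite and 512 px
(the generator's default frame size) in the acceptance script; frames are
generated at the hard condition (noise σ = 8, 12 cracks). The weight-model
recovery uses n = 500 with 5-fold CV and a 15 × 25 GWO budget. The trait-
summary standard-score reproduction is closed-form arithmetic on the
published 686-sample summary cells.

## Known limitations

- The deep six-block edge backbone is forward-only (NumPy): it validates
  the topology (cluster-mask channel into blocks 1–2, suppression on
  block-2 features, side outputs fused by averaging, sigmoid output) and
  errors explicitly without a weight bag; no training loop is provided.
- Multi-cap scenes, illumination correction, and photorealistic cap
  rendering are out of scope.
- Roundness/short-axis exclusion and the Table-style trait summary carry
  the caveats noted above; one published roundness standard-score cell is
  internally inconsistent with its own mean/max/SD (1.34 printed vs 1.30
  recomputed) and is reported as recomputed, never forced.
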