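# Methods

## Problem and scope

`shgtex` implements a texture-based analysis of two-channel two-photon
microscopy images of esophageal tissue sections: SHG (collagen
architecture of the extracellular matrix) and TPF (layered tissue
structures). The scientific question is whether GLCM texture statistics of
these channels separate diagnostic classes — primary squamous cell
carcinoma (SCC), primary high-grade dysplasia (HGD), and metachronous HGD
arising after either — and the analysis chain is: channel handling and
quantization → co-occurrence matrices at four angles → six Haralick
features per angle → cleaning → group statistics → linear-SVM
classification under stratified 9-fold cross-validation. Optical
acquisition, image stitching (beyond planning the tile grid), fiber
segmentation and histopathological interpretation are out of scope.

## Co-occurrence model

Images are quantized to `levels` gray bins with the uniform monotone map
`floor(v·levels/256)`; the default `levels = 64` balances matrix sparsity
against sensitivity (at 512² with 64 levels the matrix has ~4096 cells fed
by ~2.6·10⁵ pairs). The GLCM for distance `d` (default 1) and angle θ
counts ordered pixel pairs at the offsets (row, col): 0° → (0, +d),
45° → (−d, +d), 90° → (−d, 0), 135° → (−d, −d), in row-major coordinates
with the origin top-left. Counts are symmetrized (both orders) and
normalized to sum to one, making the two marginals equal — which is why
the correlation feature needs only one marginal mean/variance. Pairs that
leave the image or touch a masked pixel are skipped; a geometry with no
valid pairs yields an explicit degenerate matrix (`n_pairs = 0`) and
feature extraction on it raises rather than silently emitting zeros.

Conventions worth stating because they are easy to get wrong:

* A constant image has σ² = 0; its correlation is defined as 1 (a constant
  texture is perfectly self-correlated). A documented convention beats an
  exception in the middle of a batch run.
* Energy is reported as √ASM *and* ASM separately — both appear as
  distinct features downstream, six features in total.
* Under transposition the symmetrized diagonal offsets map to themselves:
  transpose swaps 0°/90° but leaves 45° and 135° invariant; the 45°↔135°
  exchange comes from a left-right mirror. The test suite asserts exactly
  this symmetry family.
* Whole-image features only; no sliding window.

Pair counting is implemented in-package (vectorized shifted-slice
`bincount`) because exclusion masks must be honored per pixel;
`skimage.feature.graycomatrix` (no mask support) serves as an independent
cross-check in tests, alongside a brute-force enumeration oracle. When
comparing with skimage note its diagonal offsets point down-right /
down-left, i.e. its 45° equals our 135° after symmetrization.

## Statistical analysis

Each (image, channel, angle) is one datapoint; angles are never averaged.
Cleaning drops rows with non-finite features, then applies per-class
(channel × group × diagnosis), per-feature Tukey fences
`[Q1 − k·IQR, Q3 + k·IQR]` with `k = 3` ("extreme" outliers; `k` is
config). IQR fences were chosen because the six features span four orders
of magnitude and a scale-free rule treats them identically. Cleaning is a
single pass; it is idempotent on realistic data but is not a mathematical
fixpoint (re-fencing a trimmed sample can in principle flag new points),
and on very small classes (n ≲ 10) the fences are tight enough to flag
legitimate draws — the audit log exists precisely so such removals are
visible. Whether fences should be computed per class or globally is not
externally fixed; per-class was chosen so that a class with genuinely
higher texture values is not decimated by another's fences.

Group summaries report per-feature mean, SD, n, and a two-sided Welch
t-test with conventional star codes. The choice of test is a documented
stand-in (the underlying study reports stars and SD bars without naming a
test); Welch avoids the equal-variance assumption. Stars are per-feature
and uncorrected, matching the apparent convention; a Holm-adjusted column
is emitted alongside for transparency. No mixed-effects modeling of
patient-level correlation is attempted — angle-level records are treated
as independent, which overstates effective n on real data (see
limitations).

## Classification

Four pairwise models: within group 1 (primary SCC vs. metachronous HGD),
within group 2 (primary HGD vs. metachronous HGD), first diagnoses across
groups, second diagnoses across groups; each on both channels. Features
are z-scored per fold with training-fold statistics only (GLCM features
differ by orders of magnitude and linear SVMs are scale-sensitive), then a
soft-margin linear SVM (`SVC(kernel="linear")`, `C = 1` default) is
fitted. Stratified 9-fold CV (`k` configurable) keeps per-fold class
proportions within one sample of the global ones; fold assignment is
seeded and recorded. Per fold: accuracy, ROC curve (thresholds over unique
scores, ties grouped into diagonal segments), trapezoidal AUC, and the
2×2 confusion matrix. The best fold is the accuracy argmax (ties to the
lower index) and the across-fold mean is reported with it.

The CV unit is the per-angle datapoint by default, which reproduces the
study-design datapoint counts but lets angles of one image straddle a
train/test split — an optimistic choice on real data. Grouped modes
(`"image"`, `"patient"`, via `StratifiedGroupKFold`) are provided for
leakage-sensitive analyses; the default stays ungrouped to match the
design being reimplemented.

## Synthetic data generator

The generator exists so every downstream stage is testable without the
(non-distributable) patient images. The SHG-like channel renders
anti-aliased line-segment fibers with a Gaussian cross-profile; fiber
count is Poisson (`fiber_density` per 100×100 px), orientations are
wrapped-normal around a dominant angle with sd `(1 − coherence)·90°`, and
rendering is additive, so incoherent fields accumulate bright crossings —
lower uniformity — while parallel fields stay even. The TPF-like channel
is a smooth band stack (layers parallel to the dominant orientation) with
speckle, and with probability `artifact_prob` a saturated edge blob that
is also returned as an exclusion mask. Output is 8-bit, 512×512 by
default, matching PMT-digitized acquisitions. Everything is seeded;
regeneration is bit-identical (per-class child seeds derive from the
master seed and a CRC of the class key, so adding a class does not
perturb the others).

The default study emulates the reimplemented dataset's shape: 24 primary
SCC and 30 metachronous HGD images in group 1 (nine patients), 21 + 21 in
group 2 (three patients) — i.e. 96 / 120 / 84 / 84 SHG datapoints after
4-angle extraction. Class parameters encode the qualitative findings the
synthetic classes must reproduce: SCC least coherent (0.2), highest
contrast (1.2) and noise; group-1 metachronous HGD most ordered (0.8);
primary HGD 0.7; group-2 metachronous HGD distinctly less ordered (0.45)
than group 1's, reflecting the reported asymmetry between the two
metachronous lesions. These were fixed from that qualitative description,
not tuned to classifier output.

What the generator does *not* emulate: optical point-spread functions,
polarization physics, layered mucosal anatomy, patient-level biological
variance, or staining variation. Consequently the synthetic classes are
much more homogeneous than patient tissue: cross-validated accuracies on
the default study saturate near 100%, where the real-data analogues sit at
68–92%. Passing tests demonstrate that the pipeline detects the texture
differences it is pointed at, not that those accuracies transfer to
tissue. A genuinely informative synthetic regime is the coherence-only
one: with density/contrast/noise held equal, per-angle datapoints make
orientation coherence a weak linear signal (a coherent class's records
straddle the incoherent class's feature range across angles), and CV
accuracy rises only gently and monotonically with the coherence gap.

## Numerical and design choices

* Quantization default 64 levels, distance d = 1, both config-surfaced
  (the source analysis does not state either).
* Channel convention for RGB merges: SHG = green, TPF = red (display
  convention of the imaging); per-channel grayscale input bypasses
  splitting.
* Artifact masking is a threshold-plus-minimum-area rule
  (8-connectivity), a reproducible stand-in for a manual exclusion step.
* Tile-grid planning is arithmetic only (row-major abutting tiles); a
  15×15 plan of 400 µm tiles is 225 acquisitions over 6×6 mm.
* `TextureSVM` wraps scaler + SVC in one estimator so CV can never leak
  test statistics into standardization; duplication of training data is
  equivalent to doubling C (unnormalized slack sum), exactly invariant
  only in the separable case.
* AUC is trapezoidal over the tie-grouped ROC and equals the
  concordant-pair (Mann–Whitney) statistic exactly, which the tests
  assert against a brute-force pair counter.
* Pipeline runs write every table/report plus a SHA-256 manifest; reruns
  with the same config reproduce metric files byte-for-byte.

## Problem sizes used in the test suite

Structural and oracle tests run on small random images (≤ 20×20, ≤ 8
levels). Simulation tests use the native 512×512 field: the default
four-class study (96 images per channel) for the high-separability check,
a balanced 100-image two-class set (400 datapoints) for the
permutation-null check, and 16 + 16 images per gap level for the
coherence-monotonicity check. The full suite completes in well under a
minute on one CPU.

## Known limitations

* Per-angle datapoints are pseudo-replicates of one image; the default
  ungrouped CV reproduces the original design but optimistically biases
  accuracy on real data. Use `grouping="image"` or `"patient"` for honest
  generalization estimates.
* The Welch t-test treats records as independent (same caveat).
* Single co-occurrence distance; no multi-scale aggregation.
* The synthetic TPF channel is a texture stand-in, not a model of
  fluorophore distribution; TPF-channel results on synthetic data say
  nothing about real TPF contrast.
* 8-bit input is assumed throughout; 16-bit acquisitions must be scaled
  before ingestion.
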