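# Methods

This note records the model, the synthetic data conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Pipeline

Per image, in order: (1) spatial median filter, (2) per-pixel median
normalisation, (3) noisy-band removal; then background and
not-everywhere-present classes are dropped, annotated pixels are
flattened in row-major order, and (4) first-order derivative features
are taken. Step 4 is an ablation switch (`PipelineConfig.derivative`);
with it off the classifier consumes normalised spectra directly.

* **Median filter.** "Window size of one pixel" in the source
  methodology is read as *radius* 1, i.e. a 3×3 window — a literal 1×1
  window is the identity and would make the step pointless. Radius and
  border handling ({reflect, nearest}, default reflect) are
  configurable; the filter acts on each band independently.
* **Median normalisation.** Each spectrum is divided by its own
  median, so the output median is exactly 1; a zero or non-finite
  median is an error naming the offending pixel. This cancels any
  multiplicative illumination factor exactly.
* **Band removal.** The published removal ranges mix 0- and 1-based
  conventions (a 128-band cube has no index 128). They are normalised
  to the unique 0-based triple {0–4, 47–49, 121–127} of sizes
  5 + 3 + 7 = 15 that leaves exactly 113 bands. The spec is
  user-overridable. All band indices in this package are 0-based.
* **Derivatives.** Plain neighbouring-band differences, no division by
  wavelength spacing; units are Δreflectance per band step.
  Derivatives run straight across removal gaps — supply a gapless
  removal spec if that is unacceptable for your sensor.

## Classifiers

ν-SVM, C-SVM and KNN are backed by scikit-learn (the margin
optimisation is deliberately delegated — the contribution here is
everything around it); the linear SVM uses the liblinear-style
`LinearSVC` with hinge or squared-hinge loss. The MLP is scikit-learn's
`MLPClassifier` with plain SGD (the simplest consistent reading of
"backpropagation"), ReLU activation and Glorot-uniform initialisation;
dropout is not supported by that backend, so only `dropout=0` is
accepted and the default MLP grid omits the 0.5 option. Multiclass SVM
strategy is the backend default (one-vs-one). The determinism contract
— identical (config, data, seed) gives identical predictions — holds
for every family, including the MLP.

The ν-SVM is the GA's target because ν ∈ (0, 1] is bounded (an upper
bound on the training-error fraction, a lower bound on the
support-vector fraction), which suits a fixed-range gene; C is
unbounded above.

## Genetic optimiser

Chromosome = 5 model genes (kernel ∈ {RBF, polynomial, sigmoid},
ν ∈ [0.001, 0.4], d ∈ {1…5}, γ ∈ [0.001, 5], c₀ ∈ [0.01, 10]) + one
bit per feature band. The band-gene count equals the *post-extraction*
feature count (112 with derivatives on, 113 with them off) — it is
data-driven, never hard-coded, which resolves the tension between a
113-gene published layout and 112 derivative features.

Loop: tournament selection (size 3, with replacement, ties to the
first encountered), crossover with probability 0.8 per adjacent pair,
mutation with probability 0.8 per individual, one-individual elitism.
Defaults: population 200, 100 epochs. Choices made where the design
was open:

* Uniform crossover is the default (the settings table outranks the
  one-point schematic); per-gene swap probability 0.5; `one_point`
  available via `GAParams.crossover_method`.
* Mutation modifies exactly one gene: a band bit flips; a discrete
  model gene (kernel, degree) is redrawn excluding its current value;
  a continuous gene is redrawn uniformly. Genes with a degenerate
  (single-value) range are excluded from the draw — degenerate ranges
  are how the tiny discrete spaces for exhaustive-enumeration checks
  are built.
* Genes irrelevant to the chosen kernel (e.g. d under RBF) are carried
  silently and ignored at decode, keeping the chromosome fixed-length.
* An all-zero band mask scores 0% fitness rather than being repaired;
  repair would bias selected-band counts.
* CV folds are frozen once per run, so fitness is a static function of
  the chromosome and the elitism invariant (non-decreasing best) is
  exact, not merely probable. Fitness values are memoised per gene
  tuple.
* A chromosome whose SVM fit fails (e.g. an infeasible ν under class
  imbalance) scores 0%.

Grid search shares the identical fitness implementation
(`model_selection.evaluate_config`); with the same folds, a GA
chromosome with all bands selected scores exactly what grid search
scores for the equivalent configuration. Continuous grid ranges are
discretised as 7-point logarithmic grids (linear for ν); integer
parameters are enumerated exhaustively; all grids are overridable.

## Scenarios

* **HTC**: per-class, per-image uniform sample (default: the global
  minimum class count) trains; all other annotated pixels test;
  stratified 10-fold CV for model selection.
* **HIC**: 250/class from each frame image trains; every annotated
  comparison pixel tests. Model selection uses the inverted 10-fold
  scheme — train on one fold subsampled to 10/class, test on the other
  nine — implemented literally as published, though a conventional
  k-fold reading cannot be ruled out.
* **HICVS**: comparison pixels split 80/20 into test/validation,
  stratified by (class, day) with floor rounding; model selection
  trains on nine folds and scores on the validation set; the final
  model never sees a comparison pixel at training time and is
  evaluated on the test partition only.

Accuracy is the fold-averaged fraction correct × 100 (micro accuracy
per fold — with balanced classes the only single-number reading of a
TP/TN ratio in the multiclass case). Final models are retrained on the
whole training set; evaluation repeats (default 5) redraw the
classifier's internal randomness under derived seeds — the split
itself is an input and stays fixed. Per-day keys follow the `F(1)`,
`E(7)` convention.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the blood study: 7 images
(frame days {1, 1a, 7, 21}; comparison days {1, 7, 21}), 6 annotated
classes from the label set {1, 2, 3, 5, 6, 7}, 128 bands over
377–1046 nm, 10× noise in the designated noisy ranges, per-image
illumination scaling, day drift (a global tilt for every class plus
oxidation-like attenuation of the blood dips), and a comparison-scene
domain gap implemented as convex mixing of each class blob with a
random smooth background spectrum, weight ~ U(0.1, 0.4), plus stronger
illumination variation (U(0.7, 1.3) vs U(0.95, 1.05)).

Signatures are Gaussian mixtures in wavelength, deterministic per
class id; only the 542/576 nm blood dips are biologically anchored.
Classes are laid out as horizontal strips (spatial blobs, exact pixel
counts). Defaults: 1,000 pixels/class (the real per-image counts are
unpublished; only the minimum, 989, is known), noise σ = 0.01
reflectance units.

Consequences: passing tests show the *pipeline and optimiser logic*
are correct and that the qualitative scenario ordering follows from a
frame/comparison domain gap; they do not reproduce, and cannot be read
as, the absolute accuracies on the real camera data, whose noise,
spectral mixing and class geometry are far richer.

In known-informative-band mode all classes share one base curve and
differ only on a chosen subset S. Band-recovery experiments use noise
σ = 0.35 in this mode: the level is chosen so cross-validated accuracy
keeps improving as more of S is selected (at low noise three bands
already saturate fitness at 100%, and a wrapper selector then has no
gradient to prefer the rest of S — saturation, not selection failure).

## Problem sizes

Unit and acceptance tests run on scaled-down studies — 40×40 images
with 150 pixels/class, GA populations of 10–30 over 6–50 epochs — and
the acceptance script mirrors those sizes, except the sampler
arithmetic checks, which use full-scale class counts (989/class over
96×96 images) so the canonical 41,538 / 6,000 row counts appear
literally. Scenario accuracies and band-recovery rates are means over
5 derived seeds; the HICVS-vs-HIC comparison in particular is a small
mean effect and is asserted on the seed mean, not per seed.

## Known limitations

* The ENVI reader handles plain BSQ/BIL/BIP uncompressed pairs with
  standard headers only; the portable `.npz` fixture format is
  authoritative for tests.
* No spatial–spectral or semi-supervised classifiers, no domain
  adaptation, no physically based scene rendering.
* Grid-search resolutions for continuous ranges are this package's
  defaults, not recovered from any published experiment; computation
  times are out of scope.
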