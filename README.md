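# hsi-evoselect

Simultaneous model and band selection for hyperspectral classification
of blood and visually similar substances, using a genetic algorithm
wrapped around a ν-SVM.

## The problem

A hyperspectral camera records a reflectance spectrum (here 128 bands
over 377–1046 nm) at every pixel. In a forensic setting one wants to
distinguish blood from look-alike substances (artificial blood, tomato
concentrate, paints) pixel by pixel. Blood is identifiable mainly
through the haemoglobin α/β absorption bands near 576 and 542 nm, but
the spectra drift with substance age, illumination and background
material, so a classifier trained on one scene often degrades on
another. Two questions drive the design:

1. Can a genetic algorithm (GA) that selects the classifier's kernel,
   its parameters and a subset of spectral bands *simultaneously* beat
   a classic grid search (GS)?
2. Under which train/test regimes does that advantage appear —
   transductive (train and test pixels from the same images) or
   inductive (train on laboratory "frame" scenes, test on field-like
   "comparison" scenes)?

## The method

Pixels are preprocessed with a 3×3 spatial median filter, divided by
their per-pixel median (cancelling multiplicative illumination), and
stripped of the noisy band ranges {0–4, 47–49, 121–127} (0-based),
leaving 113 bands; first-order derivatives `x'[i] = x[i+1] − x[i]`
(112 features) emphasise spectral shape.

The GA individual is a chromosome of 5 model genes and one bit per
band:

| gene | range |
|------|-------|
| kernel K | {RBF, polynomial, sigmoid} |
| ν | [0.001, 0.4] |
| degree d | {1…5} |
| γ | [0.001, 5] |
| c₀ | [0.01, 10] |
| band b₁…b_d | {selected, not selected} |

decoded to a ν-SVM `f(x) = sgn(Σᵢ yᵢβᵢK(x, xᵢ) + b)` restricted to the
selected bands. Fitness is fold-averaged cross-validated accuracy
`(1/N) Σ_folds (fraction correct) × 100%`. Evolution uses a population
of 200 for 100 epochs (defaults), tournament selection of size 3,
uniform crossover (p = 0.8), single-gene mutation (p = 0.8) and a
one-individual elitist carryover. Grid-search baselines (C-SVM, linear
SVM, ν-SVM, KNN, MLP) share the same fitness but never select bands.

Three scenarios: **HTC** (transductive; stratified 10-fold CV),
**HIC** (inductive; 10 folds, each iteration training on a single fold
subsampled to 10 examples/class), and **HICVS** (inductive with a
validation set drawn from the test-scene distribution, used only for
model selection). A synthetic scene generator reproduces the study's
structure — 7 images (frame days {1, 1a, 7, 21}, comparison days
{1, 7, 21}), haemoglobin dips, day drift, illumination scaling, noisy
bands and a comparison-scene domain gap — so the whole pipeline runs
without any dataset download.

## Worked example

```bash
python examples/scenario_comparison.py
```

prints (abridged):

```
HTC    seed 0: 98.65%  bands 69/112  [E(1)=95.6, ... F(7)=99.7]
HIC    seed 0: 91.37%  bands 71/112  [E(1)=88.0, E(21)=86.7, E(7)=99.4]
HICVS  seed 0: 90.56%  bands 65/112  [E(1)=91.2, E(21)=83.3, E(7)=97.1]

HTC    mean over 3 seeds: 97.59%
HIC    mean over 3 seeds: 89.43%
HICVS  mean over 3 seeds: 89.29%
```

HTC is highest because train and test pixels share scenes; HIC drops
by the domain gap; the HICVS gain over HIC is a small mean effect
across seeds. In every run the GA keeps only ~55–65% of the bands
(`bands 69/112`), i.e. it nearly halves the feature dimensionality
without losing accuracy. The other examples demonstrate preprocessing
(`preprocess_and_features.py`), band recovery with a known informative
subset (`ga_band_selection.py`) and the grid-search baselines
(`grid_search_baseline.py`).

A thin CLI wraps the same calls:

```bash
hsi-evoselect synth --seed 3 --out study/          # write fixture cubes
hsi-evoselect run --scenario hic --optimiser ga --seed 1 --out out/
```

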