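# Methods

`flyvep` implements a complete in-silico version of a spatiotemporal SSVEP
genotyping assay for *Drosophila*: a phenomenological signal generator
standing in for the electrophysiology rig, a coherent frequency-domain
feature extractor, a shrinkage-regularized linear discriminant with
bootstrap significance testing, and a multidimensional-scaling similarity
map. This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic experiments do
and do not establish.

## Stimulus design and signal model

The design grid crosses 8 reversal (temporal) frequencies
{1, 2, 4, 6, 8, 12, 18, 36} Hz with 8 spatial frequencies
{0.014 … 1.76} cpd — 64 conditions, each an 11-s trial repeated 10 times
per animal in randomized order, 20 animals per genotype by default.

A contrast-reversing grating drives polarity-insensitive neural responses
at twice the reversal frequency (2F). The generator synthesizes each trial
as

```
v(t) = g_fly · [ A2(sf, tf) · cos(2π·2F·t + φ) + A1 · cos(2π·F·t + φ/2) ] + ε(t)
```

* `A2` comes from the genotype's **tuning surface**, a separable product
  `gain · T(tf) · S(sf) · B(sf) · D(tf)`:
  - `T` — log-Gaussian temporal bandpass, centre `tf_peak_hz` (6 Hz for
    wild-type-like presets), SD `tf_bandwidth_oct` octaves (default 1.5);
  - `S` — logistic spatial low-pass with half-height `sf_cutoff_cpd`
    (≈0.88 cpd for controls), exponent 3 in the frequency ratio;
  - `B` — `low_sf_boost` at the two lowest spatial frequencies, 1
    elsewhere (the early-onset-PD signature: elevated responses at low
    spatial frequency);
  - `D` — `low_tf_drop` at the lowest temporal frequency (slight
    responsivity drop of early-onset-PD models at very low temporal
    frequencies).
  The real tuning surfaces are empirical heat maps; the separable form is
  the simplest shape that reproduces their bandpass-by-lowpass structure.
* `A1 = f1_weight(sf) · A2` is the first-harmonic admixture.
  `f1_weight` is a descending logistic in log spatial frequency with half
  point 0.05 cpd and slope 4: photoreceptors track the reversal itself
  (1F) only while the whole display shares one polarity, i.e. at very low
  spatial frequency; pooled photoreceptor energy shifts to 2F above that.
  The exact crossover is not identifiable from published figures; 0.05 cpd
  places 1F dominance strictly below the second-lowest grid frequency.
* `ε(t)` is additive noise with amplitude spectrum
  `noise_amp / f^noise_alpha` (defaults 5 µV·component⁻¹, α = 1),
  synthesized as a sum of cosines with fresh uniform random phases per
  trial — the construction guarantees the property the analysis relies
  on: non-stimulus-locked energy has random phase across bins and cancels
  under coherent averaging as 1/√N. Components are synthesized up to
  150 Hz; the 1/f envelope makes the omitted band negligible against the
  smallest signals. With the default gain of ~6 µV this puts single-bin
  SNR near 2 at the tuning peak and below 1 off-peak, so raw bins look
  noisy while the 100-bin coherent average recovers clean surfaces —
  the regime the assay is designed for.
* `g_fly` is a per-animal log-normal gain with mean 1 and coefficient of
  variation `fly_cv` (default 0.2), the dominant between-animal nuisance.

Sampling rate defaults to 1000 Hz. Every analysis frequency
(2F ∈ {2 … 72} Hz) then falls exactly on an integer-Hz bin of a 1-s
window and every reversal cycle fits the bin exactly, so rectangular
windows are leakage-free and no taper is needed or used.

Ten presets ship with the package: four control-like white-eyed strains,
four early-onset-PD-like mutants (`low_sf_boost` 1.8–2.4, `low_tf_drop`
0.75–0.8, slightly higher gain), one late-onset-PD-like genotype
(temporal peak shifted down to 3.5 Hz at control gain) and one
general-neurodegeneration-like genotype (broadened tuning, peak 9 Hz).
All preset numbers are free parameters chosen for realistic effect
sizes — they are not measurements, and no classification accuracy
obtained on them is a prediction of accuracy on real recordings.

Cohorts are lazy: a `Cohort` stores specs, per-fly gains and per-trial
seed streams (derived from one root seed via `SeedSequence` spawn keys)
and regenerates any trial bit-identically on demand. Materializing a
default two-genotype cohort would otherwise cost gigabytes.

## Feature extraction

Each trial is cut into eleven 1-s bins; the first is discarded (onset
transient). For each condition, all remaining bins of all repetitions
enter one flat complex mean of their FFT coefficients (equal weights;
per-trial means of means would be identical here because every trial
contributes the same bin count, and the flat mean is the more natural
pooling). The feature is the modulus at 2F, scaled so a cosine of
amplitude A yields exactly A. Phase is retained in the intermediate
`SpectralEstimate` for diagnostics but never enters the feature vector.
The 64 amplitudes in canonical order (spatial frequency ascending outer,
temporal frequency ascending inner) form one row of the feature table.

## Classification

`ShrinkageLDA` is a linear discriminant with two regularizers:

* `gamma ∈ [0, 1]` blends the pooled within-class covariance
  (denominator n − K) toward its diagonal. Any positive gamma makes the
  covariance nonsingular even at n < p.
* `delta ≥ 0` eliminates feature j when `max_k |C_kj| ≤ delta`, with
  `C = Σ_γ⁻¹ (μ_k − μ̄)` and `μ̄` the unweighted mean of class means.
  The surviving count is the reported "number of components".

Scores are `s_k(x) = x'Σ_γ⁻¹μ_k − ½μ_k'Σ_γ⁻¹μ_k + log π_k` over retained
features, with empirical priors and deterministic tie-breaks (first class
label in sorted order). At n = 40, p = 64 the unregularized covariance is
always singular (rank ≤ 38); raw-data analyses therefore run in an
explicit `singular='pinv'` mode that uses an eigenvalue-based
pseudo-inverse and stamps the covariance rank and a `raw_mode` flag into
every report. How the original raw-data fits handled this is not
documentable from published text; the pseudo-inverse is the conventional
minimum-norm choice.

`optimize_regularization` grid-searches gamma over {0, 0.1, …, 1} and,
per gamma, delta over 10 quantiles of the full-data coefficient
magnitudes (0 up to the maximum), minimizing stratified 10-fold
cross-validated misclassification; ties prefer fewer components, then
larger gamma. Pairwise analyses optimize per genotype pair; the n-way
analysis optimizes once on the whole ensemble.

### Bootstrap significance

Each of `n_iter` iterations resamples flies with replacement within class
(class sizes preserved), computes a cross-validated loss on the resample,
and records accuracy = 1 − loss. Defaults: 10,000 iterations for headline
analyses, 1,000 in the test suite and report layer.

Fold construction needs care on a resample. Two naive schemes are
miscalibrated under the null: leaving out one *row* lets duplicate copies
of the test fly remain in training (optimistic), while leaving out one
*fly* with all its copies unbalances the training classes and weights
test flies by their copy count (pessimistic — a size-biased test fly has
removed more of its own class). The implemented scheme holds out exactly
one fly per class per fold (classes with fewer distinct flies in a
resample recycle some), trains on everything else, and scores each
held-out fly once on its original feature row. Under a no-effect null
this is calibrated: the expected bootstrap-mean accuracy equals the
chance level exactly, which the test suite verifies empirically across
datasets. For any *single* dataset the bootstrap mean still fluctuates
around chance by a few percentage points — that is the real chance
separation between two small cohorts, not an estimator defect — so
calibration checks average several independently simulated cohort pairs.

Two bootstrap estimators ship, because they answer different questions:

* `bootstrap_accuracy` — the classical procedure used by the report
  layer: hyperparameters are selected once on the full sample, then each
  resample is scored by cross-validation at those fixed (γ, δ). This
  mirrors the optimize-then-bootstrap workflow of published SSVEP
  classification analyses, but it carries a known optimism under weak
  effects: the evaluated flies contributed to hyperparameter selection,
  and the selected features memorize part of the sample's chance
  structure (empirically ≈ +4 points at the two-class null with n = 40,
  p = 64).
* `oob_bootstrap_accuracy` — the calibration-grade estimator: every
  iteration re-runs the (γ, δ) grid search on the resample alone, trains
  on the resample, and scores only the out-of-bag flies, which neither
  selection nor training ever saw. Under a no-effect null its expectation
  is the chance level exactly (the held-out flies are independent of the
  model, so per-class assignment probabilities sum to one); accuracy is
  macro-averaged over classes to keep that argument exact under random
  out-of-bag class counts. Chance-calibration experiments use this
  estimator.

Significance follows the printed 1% bootstrap criterion with its
asymmetric boundaries: two-class results are above chance when fewer
than 1% of bootstrap accuracies are ≤ 0.5; K-way results when fewer than
1% are < 1/K.

A resample whose cross-validation cannot be fitted (degenerate class,
all features eliminated) is redrawn, the retry counted; more than 1%
retries flags the report unstable. Point accuracy is plain leave-one-out
on the original sample (n refits, one row out each), per the classical
definition; note plain LOO is mildly pessimistic under weak effects,
which is why the bootstrap mean, not the point estimate, carries the
calibration statements.

### Bootstrap distribution shape

Bootstrap accuracy distributions are checked for unimodality with
Hartigan's dip statistic, implemented in `flyvep.stats` (no installed
library provides it) and validated against exact anchors and a
linear-programming oracle at small n. The p-value is Monte-Carlo
calibrated against same-size uniform samples. Accuracies live on a ~1/n
grid, so the test adds seeded uniform jitter of half a grid step first;
without it the dip statistic responds to the grid, not the shape.

## Similarity analysis

Genotype mean feature vectors → pairwise distances (plain Euclidean by
default; correlation distance 1 − r available for sensitivity analysis —
the published description mixes both vocabularies, and Euclidean is the
operative term) → nonmetric MDS (Kruskal stress-1 via SMACOF, sklearn
implementation) initialized from the classical-scaling solution so the
embedding is deterministic; random restarts are available behind a seed.
Convergence failure is reported, never silent. Embeddings are defined
only up to rotation/reflection/translation/scale; all tests compare after
Procrustes alignment. Convex-hull separation reports, for every embedded
genotype, which foreign class hulls contain it; collinear 3-point classes
degrade to segments (containment on the segment counts as inside),
singletons to points.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full pipeline at sizes
chosen to finish in minutes on one CPU while keeping every scientific
property measurable: chance calibration uses the full 20-fly, 10-rep
cohorts with the out-of-bag bootstrap (five replicate cohort pairs in the
test suite and eight in the acceptance script, 1,000 iterations each; one
200-fly cohort with 500 iterations for the ten-class check — averaging
replicates tightens the estimate of a quantity whose per-cohort-pair
spread is inherently a few points); the effect-size sweep uses 10-fly,
3-rep cohorts at four gain
ratios × 10 seeds with fixed gamma = 0.5 (the sweep isolates effect size,
so the grid search is deliberately bypassed); hull-separation uses
8-genotype panels at 4 flies × 2 reps over 20 seeds.

## Known limitations

* The generator is phenomenological: no photoreceptor biophysics, no
  stimulus rendering, no intermodulation terms, genotype-constant
  response phase, separable tuning surfaces, and stationary 1/f noise.
  Passing tests establish that the *analysis chain* is correct and
  calibrated, not that real genotypes are separable at any particular
  accuracy; published accuracies depend on unreleased recordings and are
  out of scope here.
* Preset effect sizes are invented. Between-genotype distances, hull
  separation and pairwise accuracies on synthetic panels say nothing
  quantitative about real mutant lines.
* The bootstrap treats flies as exchangeable within genotype; real
  recording sessions pair flies on a shared rig, a dependence the
  generator does not model.
* Nonmetric MDS of 10 points in 2-D can have local stress minima; the
  classical-scaling init makes results deterministic but not provably
  global.
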