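# Methods

`maskmvpa` implements the analysis machinery for backward-masking
experiments that dissociate feedforward from recurrent visual
processing: an early mask (stimulus–mask ISI on the order of 17 ms)
curtails recurrent activity while sparing the feedforward sweep, a late
mask (ISI ~600 ms) leaves both intact. Every stage operates on
multivariate response patterns and is verifiable against the package's
own synthetic-data generator, so the full chain can be tested without
any real recordings.

## Decoding model

Object identity is decoded pairwise with linear support-vector machines
(libsvm backend via scikit-learn, `C = 1`, no per-fold feature scaling —
inputs are expected to be noise-normalized). For each condition cell,
trials are randomly grouped into `n_bins = 4` equally sized bins and
averaged into pseudo-trials (surplus trials dropped uniformly at
random; with 53 trials per cell this means bins of 13 and one dropped
trial). Leave-one-pseudo-trial-out cross-validation trains on three
pseudo-trials per class and tests on the held-out one. Accuracies for
all K(K−1)/2 pairs are arranged into a symmetric K×K percent-correct
matrix with an undefined diagonal; its off-diagonal mean is the
grand-average accuracy, and the matrix doubles as the neural RDM for
RSA. The whole procedure is repeated (default 100 times) with fresh
random pseudo-trial assignments and averaged.

Cross-condition decoding keeps the fold structure but draws the
training pseudo-trials from one masking condition and the test
pseudo-trial from the other, averaging both directions; binning is
re-drawn independently per direction and repetition. Temporal
generalization trains at each time point and tests at all time points;
because train/test directions carry no meaning the matrix is
symmetrized by averaging with its transpose.

fMRI decoding follows the same recipe with pseudo-runs instead of
pseudo-trials: 12 runs are randomly grouped into 4 bins of 3, averaged,
and cross-validated leave-one-pseudo-run-out, either on ROI voxel
patterns or on searchlight spheres (Euclidean radius in voxel units,
default 4, center included, truncated at mask edges).

## Time-frequency decomposition

Complex Morlet wavelets span 4–100 Hz in 50 logarithmically spaced
steps. The temporal FWHM of the Gaussian envelope is scheduled
log-linearly from 500 ms (4 Hz) to 20 ms (100 Hz); by the Fourier
uncertainty relation the corresponding spectral FWHM measured on the
*power* spectrum is `4 ln 2 / (π · FWHM_t · √2)` ≈ 1 Hz and ≈ 31 Hz at
the endpoints. (Measuring on the amplitude spectrum instead would give
√2-larger values and break the 1–31 Hz correspondence, which is why the
power-spectrum convention is adopted.) Kernels are truncated at ±3
envelope SDs and normalized to unit energy so white-noise power is flat
across the bank. Power is the coefficient magnitude; phase features are
the unit-normalized cosine and sine components, concatenated across
channels (128 features for a 64-channel montage). Epochs must be longer
than the widest kernel — generate −600…1200 ms epochs at 2 ms steps and
crop to the window of interest after the transform (reflect padding is
available but off by default). The output time axis is downsampled to
20 ms steps.

## Noise normalization

Multivariate noise normalization whitens the channel dimension with
`Σ^{-1/2}`, where `Σ` is the within-cell residual covariance (trials
minus their condition-cell mean), pooled over cells and time points and
regularized with Ledoit–Wolf analytic shrinkage toward the scaled
identity. Pooling over time points (rather than whitening per time
point) is a deliberate choice: one transform per subject/session keeps
within- and cross-condition comparisons commensurable and the estimate
well conditioned even with rank-deficient sensor data.

## GLM with per-voxel HRF selection

Condition responses (betas) are estimated by ordinary least squares
with condition onsets convolved against each member of a parametric HRF
family — double-gamma kernels with peak latency graded linearly from
3 s to 9 s in 20 steps, peak-normalized. Per voxel, the member with the
lowest mean squared residual over the whole series is selected (ties
break to the lowest index, i.e. the earliest peak); nuisance regressors
are shared across candidate GLMs. A parametric family stands in for an
empirical HRF library so the selection logic is fully testable: at high
SNR selection accuracy is 100% and degrades monotonically with noise.

## RSA, noise ceilings, commonality

Model RDMs use `1 − Pearson r` between item feature patterns; brain
RDMs are the decoding-accuracy matrices. RDMs are compared by Spearman
correlation of their lower triangles. Noise ceilings: the lower bound
correlates each subject's RDM with the mean of the *other* subjects'
RDMs, the upper bound with the mean including the subject, both
averaged over subjects. Commonality analysis partitions the target
RDM's rank-regression R² between two predictor RDMs:
`C = R²(a) + R²(b) − R²(a,b)` on rank-transformed lower-triangle
vectors, so `C + unique_a + unique_b = R²(a,b)` holds identically and C
may be negative (suppression). Rank transformation keeps the
commonality step consistent with the Spearman comparisons of standard
RSA.

## Resampling statistics

All group inference is sign-permutation based: each subject's effect
(accuracy − 50, correlation, shared variance, or condition difference)
is multiplied by a random ±1 and the group mean recomputed, default
10,000 permutations with the identity flip always included so
`p ≥ 1/n_perm`. Cluster-based correction computes, for the observed
data and every permutation, per-point p-values within the pointwise
permutation null, thresholds at a cluster definition threshold of
p < 0.005, groups supra-threshold points by orthogonal adjacency (2/4/6
neighbours in 1/2/3 dimensions — conservative, no diagonals), and scores
clusters by size; the familywise p of an observed cluster is the
fraction of permutations whose *maximum* cluster size reaches it, with
clusters significant at p < 0.05. Small unrelated families use
Benjamini–Hochberg FDR at q = 0.05 (statsmodels backend). Peak-latency
uncertainty uses 1,000 bootstrap resamples of participants, reporting
the 2.5–97.5 percentile interval of the group-mean curve's argmax (ties
break to the earliest coordinate — relevant because bootstrap argmax
distributions do hit ties). Paired peak shifts between conditions are
tested two-tailed by within-subject label reassignment (equivalently a
sign flip of the paired differences), with effect size Hedges' g: the
paired standardized mean difference times the small-sample correction
`1 − 3/(4(n−1)−1)`.

## Stimulus subset selection

A genetic algorithm searches for the size-k stimulus subset whose two
reference sub-RDMs (e.g. early visual cortex and IT) have minimal
absolute Spearman correlation, making the two processing stages
representationally dissociable. Individuals are boolean membership
vectors; tournament selection (size 3), uniform crossover, bit-flip
mutation at rate 0.02 with repair back to exactly k members, elitism of
2, population 200, 500 generations. These hyperparameters are the
package's own defaults (no reference values exist); elitism guarantees
a non-increasing best objective, and on small instances (choose 4 of 8)
the algorithm recovers the exhaustive minimum.

## Synthetic data generator

No generative model of the real recordings exists, so the generator's
components are explicit stand-ins that encode the phenomena the
analyses are meant to detect:

- **Feedforward component**: Gaussian temporal envelope (default peak
  120 ms, FWHM 80 ms), identical in both masking conditions, with
  object-specific channel patterns — a transient code that supports
  early decoding and narrow temporal generalization.
- **Recurrent component**: sigmoidal onset at 150 ms, 400 ms plateau,
  amplitude 1.0 under the late mask and 0.2 under the early mask — the
  core manipulation: masking truncates sustained processing. A
  `cross_condition_overlap` parameter interpolates between identical
  (1) and orthogonal (0) representational geometries across masking
  conditions, giving planted-truth constructions for cross-decoding
  oracles.
- **Oscillatory component**: stimulus-locked cosine (default 10 Hz,
  amplitude 0, i.e. off) with evenly spaced object-specific phases;
  when enabled, a classifier trained at one time and tested half a
  cycle later sees the code sign-flipped, reproducing below-chance
  off-diagonal generalization by construction.
- **Noise**: temporally white, spatially correlated Gaussian
  (exponential channel correlation, length 5 channels, SD 1). Real EEG
  noise is neither white nor stationary; white-plus-spatial is
  sufficient for the property tests the generator serves. A per-subject
  jitter (SD 0.3) around population-level condition patterns makes
  group statistics and noise ceilings meaningful.
- **Model RDMs**: two independent random feature bases define two
  near-orthogonal endpoint RDMs; layer l mixes them convexly with
  weight descending from 1 to 0, so geometry shifts smoothly with depth
  and adjacent layers correlate more than distant ones.
- **fMRI patterns**: per ROI and masking condition, voxel patterns are
  linear read-outs of the latent features of a designated model layer
  (default: EVC → an early layer under both masks; LOC → a mid layer
  under the early mask and the deepest layer under the late mask,
  emulating a recurrence-driven shift toward high-complexity features).
  An orthonormal read-out variant preserves pattern geometry exactly
  for noiseless oracles. The default design yields 96 condition betas
  per run (24 objects × 2 masks × 2 presentations) over 12 runs.
- **fMRI time series**: event trains convolved per voxel with an
  assigned member of the HRF family plus white noise — the recovery
  fixture for HRF selection.

What passing tests on these data do **not** show: robustness to real
EEG artifacts (eye movements, drifts, 1/f noise), realistic volume
conduction or BOLD physiology, or any empirical claim about actual
recurrent processing. They show that the analysis chain is correct: it
recovers planted structure, stays at chance on null data, and its
statistics are calibrated.

## Problem sizes and numerical choices

Tests and the reproduction script run scaled-down designs chosen to
keep Monte-Carlo error well inside the asserted tolerances: the
null-chance check uses 8 objects × 12 trials/cell × 64 channels at
20 ms resolution with 5 repetitions (standard error of the grand
average ≈ 0.5 points against a ±1.5 band); familywise-error validation
uses 200 null simulations × 500 permutations on a 25-point grid;
planted-effect checks use 4–8 objects with noiseless or low-noise
truths so the oracle predictions are sharp. Degenerate inputs are
handled explicitly: zero-power time-frequency coefficients flag their
phase as undefined (NaN); flat bootstrap curves warn and return the
full-domain interval; all-zero GLM series select kernel index 0 with
zero betas; empty supra-threshold sets yield an empty cluster list, not
an error. Determinism is end-to-end: every public sampler takes a seed
or Generator, and the pipeline derives named per-stage substreams from
the single config seed.

## Known limitations

- The generator's components are additive and linear; interactions
  between feedforward and recurrent processing are not modeled.
- Searchlight decoding is a straightforward per-center loop; large
  volumes at radius 4 are slow (the reference analyses ran on
  HPC-scale resources).
- The commonality implementation covers exactly two predictors, the
  variant the pipeline needs.
- Epoch containers hold dense float64 arrays in memory; very large
  time-frequency sets should be processed per frequency.
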