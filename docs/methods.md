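# Methods

`grapholearn` re-implements, as a tested and reusable pipeline, the
computational analysis of a word-learning fMRI experiment contrasting
late-blind and sighted adults who learned spoken foreign words either while
handwriting them or with the hand at rest.  Because the original images and
recall tables are not publicly deposited, the package pairs every analysis
stage with a synthetic-experiment generator that plants known effects, so the
whole chain can be validated by recovering its own ground truth.

## The experimental model being emulated

Two groups (12 blind, 18 sighted participants) learn two 20-word lists (40
words total) in two conditions (writing vs. no-writing), each session
containing a study period and an immediately following test period, scanned
with TR 3.5 s; recall is measured immediately and again one week later.
Three stimulus-level dissimilarity structures are defined over the word list:

* **motor RDM** — `|s_i − s_j| / (s_i + s_j)` for total handwriting stroke
  counts `s`, capturing the motor effort geometry of writing each word;
* **syllabic RDM** — one minus the proportion of shared syllables relative to
  the two words' summed syllable counts;
* **semantic RDM** — one minus a taxonomy similarity of the words' concepts,
  Wu–Palmer by default: `sim(a,b) = 2·depth(LCS) / (depth(a)+depth(b))`.

Neural RDMs are `1 − ρ_Spearman` between word-level multivoxel beta patterns;
their rank correlation with each theoretical RDM, Fisher-z transformed, is
the unit of second-level RSA inference.

### Conventions that needed fixing

* **Syllable overlap counting.** Read literally, "shared syllables over the
  summed syllable count" gives a self-dissimilarity of 0.5 for identical
  words.  We count each matched syllable in *both* words (twice the multiset
  intersection), so identical words score 0 — the identity axiom a
  dissimilarity needs for neural comparison.  Matching is position-free
  (multiset).
* **Taxonomy root depth is 1**, so Wu–Palmer similarity is positive even when
  the lowest common subsumer is the root.  The semantic measure is a config
  switch (`wu_palmer` or `path`); no corpus-based (information-content)
  measures are offered.
* **Fisher z at |ρ| = 1** is capped at `atanh(1 − 1e−12)`.
* **Searchlight radius "two voxels"** means centre-to-centre Euclidean
  distance ≤ 2 in voxel units — a 33-voxel sphere — not city-block distance.
  Sphere membership is intersected with the gray-matter mask; centres whose
  sphere falls below `min_voxels` (default 10) are skipped and left NaN.

## First-level GLM

The canonical HRF is a difference of two gamma densities with dispersion
1 s.  We parameterise shapes as `delay + 1` so the positive lobe's mode falls
exactly at `peak_delay_s` (default 6 s) and the undershoot's at 16 s, with a
1:6 undershoot ratio and 32 s support; the sampled kernel is peak-normalised.
Designs contain one HRF-convolved regressor per condition or per word
(boxcars on a TR/16 grid), optional temporal-derivative columns, six motion
parameters, a discrete-cosine drift basis up to `1/(2·120 s)` Hz
(`floor(2T/high_pass) + 1` columns including the constant), and an intercept.

A Gaussian temporal smoothing kernel (FWHM 4 s) is applied to the task and
motion columns at design time and to the data at fit time — a matched-filter
contract; mismatched filtering of data and model would bias betas.  Because
the synthetic generator builds its signal with the same convolution code, a
noiseless run is an exact linear model of the fitted design and the GLM
recovers planted amplitudes to ~1e−12 (the validation suite asserts 1e−8).
Word-level betas come from a single model containing all word regressors;
spatial smoothing (FWHM in mm, σ converted through the affine, rejecting
sheared affines) is available for univariate group maps but never applied to
RSA inputs.

## Second-level inference

All factorial designs here are 2×2(×2) with two-level factors, so the
classical split-plot ANOVA is computed exactly through per-participant
contrast scores: each within-effect subset yields a signed cell-mean score;
within effects are tests of the scores' grand mean, `effect × group` terms
are two-sample comparisons, and every statistic is F(1, N−2) (F(1, N−1)
without a between factor).  With unequal group sizes (12 vs 18) the engine
uses *unweighted* (Type-III-style) marginal means, the convention of
`car::Anova(type = 3)` and ARTool; `pingouin.mixed_anova` serves as the
independent oracle in the tests (exact agreement on balanced designs and on
the between/interaction effects of unbalanced ones — its within main effect
uses weighted SS and differs by design).  The same contrast-score arithmetic
runs over a trailing voxel axis for second-level maps, with signed
z-equivalents derived from the one-df F's p-value.

Family-wise error control is permutation-based, replacing the original
random-field-theory machinery: cluster-extent FWE compares each
suprathreshold cluster (26-connectivity, voxel p < 0.001 two-sided by
default) with the permutation distribution of the maximum cluster size (sign
flips for one-sample contrasts, group relabelling for group differences);
small-volume correction uses the max-|t| permutation distribution restricted
to the ROI.  The observed labelling is counted in its own null, so p-values
are exact and never zero.  ROI geometry: spheres snap their centre to the
nearest voxel and keep voxels within the mm radius (a 5 mm sphere on a 2 mm
grid has 81 voxels); the hippocampus mask is split into anterior/middle/
posterior thirds along the y axis by contiguous slice bins with voxel counts
as equal as possible, ties resolved toward the anterior bin.

## PPI

The seed signal is the principal eigenvariate of the seed ROI (first left
singular vector of the column-centred time-by-voxel matrix, rescaled to the
mean voxel SD, sign-aligned with the mean series).  The interaction regressor
is the element-by-element product of the mean-centred seed and the
mean-centred psychological contrast (period × condition coding whose weights
must sum to zero), standardised to unit variance so the interaction beta is
invariant to seed rescaling.  No hemodynamic deconvolution is applied — the
product is formed directly on the BOLD-level signal, as the analysis being
re-implemented describes; a deconvolution variant is out of scope.  The
first-level PPI model includes both main-effect columns, making the
interaction estimate orthogonal to planted main effects in expectation;
second-level condition × group inference reuses the mixed-ANOVA engine plus
the permutation ROI tests.

## Aligned-rank-transform ANOVA

Recall accuracies are percentages of 20 items with severe ceiling
compression, so the factorial analysis is nonparametric.  For each effect,
responses are aligned — the observation's full-factorial cell mean is
subtracted and the effect's own inclusion–exclusion estimate (from observed
marginal means) is added back — then ranked with average ranks, and the
split-plot ANOVA on ranks supplies that effect's F only.  This plain
Wobbrock-style alignment is pinned by an algebraic oracle: with a single
balanced within factor it reduces exactly to the rank ANOVA of `y − ȳ`.  The
aligned responses sum to zero exactly; the "stripped-effect F ≈ 0" check on
the unranked aligned data is reported as a diagnostic (it is exact only up to
participant-level noise, since participant effects are deliberately not part
of the alignment).  Partial η² is `F·df1 / (F·df1 + df2)`.

The inverse transform applied beforehand is `y → 1/(y + c)` with a
configurable offset (default c = 1) guarding accuracy 0; the plain reciprocal
(c = 0) is equally admissible and both are exercised where printed statistics
are compared, because the original report does not state its exact formula.
Assumption checks are Shapiro–Wilk on cell residuals and Brown–Forsythe
Levene across cells.  Post-hoc analysis runs the 2×2 within-participant ART
per group, descending to per-timing condition tests when the interaction is
significant at α = 0.05.

**Calibration.** On raw (unranked) null data the engine's type-I error is
exact (0.051 at 4000 simulations).  The full ART procedure is very close to
nominal but mildly conservative for the within main effects at the study's
n = 30: reference rates at 10 000 null simulations are condition 0.047,
timing 0.043, group 0.051, condition:timing 0.049, condition:group 0.050,
timing:group 0.050, three-way 0.051.  This conservatism is a property of
rank-based alignment at small n, not of the implementation — a
participant-adjusted alignment variant measured no better (0.044/0.036 for
the two within effects).  A consequence is that a single 1000-simulation
binomial check of "exactly 0.05" per effect occasionally lands outside its
95% band, as one pinned-seed draw in the acceptance suite does.

## The synthetic generator — what it emulates and what it does not

Defaults mirror the study conditions: 40 words in two lists of 20, 2–5
syllables from a 48-token syllabary, 12 + 18 participants, TR 3.5 s with one
stimulus per TR presented three times per trial, a 40×48×40 grid at 2 mm
isotropic with an MNI-like centre-origin affine.  Stroke counts are uniform
on [2, 20] and syllable lengths uniform on [2, 5] — per-word statistics of
the real stimuli are unpublished, so these are generic plausible ranges
chosen once.  Patterns encoding a target RDM are drawn by double-centring
`1 − RDM` into a Gram matrix, clipping negative eigenvalues, sampling
word-correlated Gaussian patterns with that covariance (normalised to unit
average voxel variance), mixing with white patterns by `fidelity`, and adding
white measurement noise; "SNR 10" in the validation experiments means
`noise_sd = 0.1` on the unit-variance structured part.  BOLD runs add
HRF-convolved, pattern-scaled responses inside each ROI, a smooth latent
signal shared by a seed and a target ROI whose target coupling is multiplied
by `1 + connectivity_gain` during the test period of the designated
(group, condition) cell, white + AR(1) noise (φ = 0.3 — a minimal temporally
correlated stand-in for unknown real noise structure), a baseline of 100, and
six smooth motion nuisance series.

Behaviour is binomial on 20 items with a logistic model containing
effect-coded main effects and interactions of timing, condition and group
plus a participant random intercept (SD 0.4 logits); defaults qualitatively
mirror the reported pattern (dominant timing effect, condition × group
crossover).  The binomial floor/ceiling behaviour is what makes the data
non-normal and heteroscedastic, reproducing the motivation for ART.

Not emulated: speech responses, scanner artifacts, susceptibility
distortion, motion-induced image displacement (motion enters only as
nuisance regressors), realignment/normalisation (data are born in the common
grid), and real anatomy (ROIs are boxes or spheres; the "hippocampus" of the
splitting test is any user-supplied mask).  Passing tests therefore
demonstrate correctness of the *analysis machinery* under the planted model,
not robustness to real-data artefacts.

## Problem sizes in tests and validation

The validation experiments run the study's stimulus and sample dimensions on
deliberately small grids chosen as adequate for their question: pattern-level
selectivity on 100-voxel ROIs (100 seeds), group searchlight localisation on
a 7³ grid with 4 participants and 40 words (100 seeds), PPI detection with
6 + 6 participants on an 8³ grid (100 seeds, 200 null simulations), FDR and
Mantel calibration at 500 simulations, ART calibration at 1000 (with 10 000
as the reference run quoted above).  The demo pipeline uses 8 words, 4 + 4
participants and a 12³ grid so the full synth → GLM → PPI → RSA → behaviour
chain executes in a few seconds.

## Numerical choices and degenerate inputs

OLS uses `lstsq`; all-zero voxel series yield beta 0 with flagged variance.
Rank-deficient designs raise a collinearity error naming the offending
columns.  Constant pattern rows make the neural RDM undefined and raise an
error naming the word.  Mantel and all permutation p-values use the
+1-smoothed estimator.  Ties anywhere in ranking use average ranks; exact
ties in ART aligned responses mean the affine-invariance of F holds exactly
in real arithmetic but only to ~1e−4 absolute under floating point (ulp-level
perturbations can re-split a tie group).  Every random draw flows from one
integer seed through SHA-256-derived `SeedSequence` spawn keys, so identical
seeds give bit-identical tables and volumes on one platform.

## Known limitations

* The flexible-factorial covariance structure of the original second-level
  model is unknown; the split-plot engine here makes the standard
  compound-symmetry assumptions (harmless for two-level factors) and no
  claim is made of reproducing the original voxel statistics.
* ART within-effects are mildly conservative at n = 30 (see calibration).
* The Mantel test permutes one matrix's labels only — appropriate for the
  simple (two-matrix) test used here, with no partial-Mantel variant.
* The searchlight computes Spearman sphere-level correlations by default
  (Pearson is a switch); the original report is ambiguous on this point.
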