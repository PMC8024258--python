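# grapholearn

A tested, reusable re-implementation of the computational analysis behind a
word-learning fMRI study of handwriting in late-blind and sighted adults:
representational similarity analysis (RSA) over motor, syllabic and semantic
stimulus geometries, psychophysiological-interaction (PPI) connectivity from
a premotor seed, first- and second-level GLMs with permutation family-wise
error control, and aligned-rank-transform (ART) factorial ANOVA of recall
accuracy — all exercised end-to-end on a synthetic experiment generator with
planted, recoverable ground truth.

It is written for cognitive-neuroimaging researchers who want the analysis
logic of such a study as an inspectable library: every formula the analysis
depends on is a small tested function, and every inferential stage can be
validated by planting an effect and measuring how often it is recovered.

## The models at the core

**Stimulus RDMs.** For words *i, j* with stroke counts *s* and syllable
multisets *Y*:

- motor: `d(i,j) = |s_i − s_j| / (s_i + s_j)`
- syllabic: `d(i,j) = 1 − 2|Y_i ∩ Y_j| / (|Y_i| + |Y_j|)`
- semantic: `d(i,j) = 1 − 2·depth(LCS) / (depth(c_i) + depth(c_j))`
  (Wu–Palmer on a single-rooted taxonomy, root depth 1)

**Neural RDMs and RSA.** `d(i,j) = 1 − ρ_Spearman(β_i, β_j)` over word-level
multivoxel betas; Spearman of its lower triangle against each stimulus RDM,
Fisher-z transformed, enters a 2×2 mixed ANOVA (learning condition within
participants, group between), with BH-FDR across ROIs, or a radius-2-voxel
(33-voxel) searchlight.

**GLM.** Voxelwise OLS on a design of double-gamma-HRF-convolved regressors
(peak 6 s, undershoot 16 s, ratio 6), temporal derivative, six motion
parameters, a 120 s discrete-cosine high-pass set and a matched 4 s temporal
smoothing filter applied to data and design alike.

**PPI.** Interaction regressor = centred seed eigenvariate ⊙ centred
period × condition contrast; its voxelwise beta indexes context-dependent
coupling, tested for condition × group structure.

**ART.** For each effect of the 2 (condition) × 2 (timing) × 2 (group) mixed
design: subtract every estimated effect except the one of interest, rank the
aligned responses, run the split-plot ANOVA on ranks, keep that effect's
F(1, N−2); accuracies are inverse-transformed (`1/(y+1)`) first.

## Worked example

Generate a synthetic behavioral experiment at the study's dimensions
(12 blind + 18 sighted, binomial accuracy on 20 items with planted effects),
check assumptions, and run the ART ANOVA:

```python
from grapholearn.synth import generate_behavior
from grapholearn.art import art_anova, assumption_checks, inverse_transform

table = generate_behavior(n_blind=12, n_sighted=18, seed=7)
print(assumption_checks(table))
res = art_anova(table.assign(accuracy=inverse_transform(table["accuracy"].to_numpy())))
print(res.summary())
```

```
{'shapiro_p': 0.00101..., 'levene_p': 0.137...}
Aligned-rank-transform ANOVA (30 participants)
  condition                    F(1,28) =     9.44  eta^2 = 0.25  p = 0.00468
  timing                       F(1,28) =   320.04  eta^2 = 0.92  p = 7.39e-17
  group                        F(1,28) =    13.62  eta^2 = 0.33  p = 0.000957
  condition:timing             F(1,28) =     6.48  eta^2 = 0.19  p = 0.0167
  condition:group              F(1,28) =    51.52  eta^2 = 0.65  p = 8.22e-08
  timing:group                 F(1,28) =     7.72  eta^2 = 0.22  p = 0.00966
  condition:timing:group       F(1,28) =    34.67  eta^2 = 0.55  p = 2.47e-06
  alignment check: max stripped-effect F = 7.91e-01
```

The Shapiro–Wilk p shows the ceiling-compressed accuracies are non-normal
(which is why the analysis is rank-based); the F table recovers the planted
structure — a dominant timing effect and a strong condition × group
crossover, the study's key behavioral signature.

Planted-pattern RSA in three lines: patterns encoding the motor RDM at
fidelity 1 with SNR 10 are identified against the two rival RDMs,

```python
from grapholearn.synth import generate_stimuli, plant_patterns
from grapholearn.rdm import motor_rdm, syllabic_rdm, semantic_rdm
from grapholearn.rsa import neural_rdm, rdm_similarity

stim, tax = generate_stimuli(n_words=40, seed=7)
pat = plant_patterns(motor_rdm(stim), n_voxels=100, fidelity=1.0, noise_sd=0.1, seed=7)
for name, rdm in [("motor", motor_rdm(stim)), ("syllabic", syllabic_rdm(stim)),
                  ("semantic", semantic_rdm(stim, tax))]:
    rho, z = rdm_similarity(neural_rdm(pat), rdm)
    print(f"{name:>9}: rho = {rho:+.3f}, z = {z:+.3f}")
```

```
    motor: rho = +0.856, z = +1.277
 syllabic: rho = +0.039, z = +0.039
 semantic: rho = +0.000, z = +0.000
```

The full synthetic pipeline (synth → GLM → PPI → RSA → behaviour, with a run
manifest of per-stage checksums) runs from the CLI:

```bash
grapholearn all --out demo_out --seed 1
```

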