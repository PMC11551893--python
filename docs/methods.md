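# Methods

## The generative pattern model

All analyses operate on *pattern datasets*: one beta-weight-like activation
vector over P voxels per condition per run, where the conditions cross two
sequence orders, two sequence timings, and two trial phases (preparation,
production). The simulator draws, per subject and phase,

```
y_ijk = s_i + t_j + i_ij + r_k + e_ijk
```

with `s_1, s_2` (order), `t_1, t_2` (timing), `i_11..i_22` (integration),
`r_1..r_K` (run effect) and per-row noise `e` all independent zero-mean
normal vectors over the voxels. Defaults: P = 160 voxels, K = 6 runs,
24 subjects, `var_s = var_t = var_i = var_r = 1` (only variance *ratios*
matter downstream, so the common signal variance is fixed at 1 and noise is
set from a target SNR).

Choices where the design was genuinely open:

* **Run effect shared across phases.** One `r_k` per run is added to both
  phases' rows, because both phase regressors are estimated from the same
  imaging run.
* **Phase regimes.** With `switch=False` the production phase reuses the
  preparation draws of `s/t/i`, multiplied by `prod_scale`; with
  `switch=True` production draws fresh components. A uniform `phase_offset`
  (default 5, i.e. 5 component SDs) is added to every production voxel so
  that the leading principal component of the geometry reflects phase, as
  in real data where activity levels change strongly between phases.
* **Noise granularity.** Noise is white per pattern row (no spatial
  correlation beyond what the shared components induce); the prewhitening
  stage is still exercised meaningfully because the *residual* covariance it
  estimates includes the run effect and finite-sample structure.
* **One row per condition per run** — the granularity of GLM beta weights,
  not of single trials.

**SNR definition and matching.** The SNR estimator is the cross-run
covariance (over voxels) of a condition's patterns, averaged over conditions
and run pairs — an unbiased estimate of `var_s + var_t + var_i` — divided by
the within-condition across-run residual variance, which estimates
`var_r + var_e` (run effect and noise are indistinguishable across runs
within a condition). `SimulationConfig.from_snr(snr_prep, snr_prod)` sets
`var_e = signal/snr_prep − var_r` and scales the production signal by
`sqrt(snr_prod/snr_prep)`, so both measured phase SNRs hit their targets
exactly in expectation. Calibration tests recover a target ratio of 0.5
within ±10% over 200 simulated subjects.

## Decoding

Gaussian LDA with equal priors and one covariance pooled across classes,
shrunk toward its diagonal: `Σ = (1−λ)S + λ diag(S)`. The default intensity
comes from an analytic (Schäfer–Strimmer-style) estimator on the pooled
within-class residuals, floored at 0.01 so the matrix stays invertible even
in degenerate small-sample layouts; passing `shrinkage=0` explicitly lets a
singular covariance raise, as a signal to regularize. Ties in the decision
rule go to the lowest class index (deterministic, seed-independent).

Fold schemes on a K-run design, per phase:

* **order** — train on both orders under one timing level, K−1 runs
  (2(K−1) rows); test on both orders under the *other* timing level in the
  held-out run. 2K folds (12 for K = 6).
* **timing** — the mirror image.
* **integrated** — leave-one-run-out, 4 classes, on the per-run two-way
  interaction residuals `y_ij − mean_i· − mean_·j + mean_··` (computed per
  run and phase; the grand mean is added back so the operation is the exact
  2×2 ANOVA interaction projection).

Correct counts are pooled across folds into one accuracy and one binomial z
per subject and decoder (chance 1/2 factorized, 1/4 integrated). Group
inference is a one-sided one-sample t-test of z against 0, Bonferroni
factor 6 (2 phases × 3 decoders) in the pipeline report.

**A structural ceiling worth knowing.** The interaction residual of any 2×2
design is rank one with cell signs (+,−,−,+): within a run, the two
sequences sharing a sign have *identical* residual rows. Four-class
integrated accuracy is therefore capped at 1/2 (against chance 1/4), and the
per-run guesses are pairwise dependent, which widens the z distribution
(SD ≈ 1.57 under the null instead of 1). Neither effect biases the mean —
Monte-Carlo calibration over thousands of null subjects puts mean z within a
few hundredths of 0, and the group t-test (being scale-free) keeps its
nominal size — but integrated accuracies should be read against the 0.5
ceiling, not against 1.

## Representational geometry

* **Noise covariance / prewhitening.** Pooled covariance of
  within-condition across-run residuals, shrunk toward its diagonal
  (intensity configurable, `'auto'` analytic by default), whitener = inverse
  principal square root via eigendecomposition with a relative eigenvalue
  floor of 1e−10; zero residual variances are floored with a warning.
* **Crossnobis RDM.** `d_ab = mean over run pairs m≠n of
  (x_a^m − x_b^m)' Σ⁻¹ (x_a^n − x_b^n) / P` over the 8 sequence×phase
  conditions. The whitener is *cross-validated per run pair* (estimated from
  the remaining runs only): a whitener estimated from all runs correlates
  with the pattern noise and biases distances upward by many standard
  errors, whereas the leave-pair-out construction is exactly unbiased
  (verified: |mean| < 3 MC SEs of 0 over 500 null simulations). With fewer
  than 4 runs the code falls back to a pooled whitener and warns. Distances
  may legitimately be negative.
* **Classical MDS.** Torgerson route: row-center the run-averaged whitened
  condition means, eigendecompose the Gram matrix, coordinates =
  eigenvectors × sqrt(eigenvalues). Negative eigenvalues are clipped with a
  warning; numerically-null components get exactly zero coordinates.
* **Cross-phase statistic.** Mean prep↔production Euclidean distance per
  sequence on components 2–3, divided by the grand mean of the 6
  within-preparation plus 6 within-production pairwise distances *in the
  same subspace* (numerator and denominator share the subspace so the ratio
  is scale-invariant; the statistic is invariant to uniform pattern
  rescaling and to translations).
* **Baselines.** The statistic is positively biased by noise even without a
  representational change, so it is tested one-sided against the mean of a
  simulated *no-switch* baseline with matched P, K and per-phase SNR
  (production signal scaled by the prep→production SNR ratio), Bonferroni
  factor 7 by default. The baseline summarizes the statistic over
  independent simulated subjects; the group test consumes only its mean.
  A *switch* reference distribution is simulated the same way.

One geometric subtlety: a finite phase offset is generically not orthogonal
to the random signal subspace, so PC1 does not absorb it exactly and a small
deterministic fraction leaks into components 2–3 (≈0.07 normalized at
offset 5 and P = 60, independent of noise level). The matched no-switch
baseline contains the same leakage, so the inference is unaffected; the
noiseless limit of the statistic is exactly zero only at offset 0, which is
how the limiting case is tested.

## Searchlights

Members of a searchlight are the in-mask voxels sorted by physical (mm)
distance from the center — ties broken lexicographically on the coordinate
offset — truncated at a 160-voxel cap and a 6 mm maximum radius, whichever
binds first. At 2 mm isotropic resolution the radius cap binds: an interior
searchlight holds exactly 123 voxels (the lattice points with
dx²+dy²+dz² ≤ 9), so the 160-voxel target is unreachable under the radius
constraint; both parameters are exposed in the configuration. Distances use
the voxel size, never voxel counts. The analysis statistic is assigned to
the center voxel; failures are recorded as missing, not fatal. Group maps
are voxelwise one-sample t-tests with 26-connected suprathreshold clusters
(default cut 3.48 = t(23) one-tailed 0.001 quantile); cluster-level
family-wise-error p values are deliberately not computed.

## Simulation studies and problem sizes

`seqmvpa.experiments` holds the validation studies; the same functions power
`tests/test_acceptance.py` and `scripts/acceptance.py`. Sizes were chosen
once so the full battery runs in minutes on one CPU:

* **Null calibration** — 1,000 groups of 12 subjects, 40-voxel ROIs, no
  signal: one-sided rejection 5% ± 2% at α = 0.05 and |mean z| ≤ 0.1 for all
  three decoders. (The null and transfer properties do not depend on voxel
  count, hence the 40-voxel ROIs.)
* **Feature specificity** — signal in exactly one component at SNR 0.5
  (component variance 1, `var_r = 0`, `var_e = 2`), 200 groups of 24
  subjects: matched-decoder power ≥ 0.90; off-target decoders within the
  null band (|mean z| ≤ 0.1, rejection ≤ 0.12).
* **Crossnobis null** — 500 subjects with identical condition patterns:
  |mean distance| < 3 MC SEs.
* **Switch recovery** — the full study geometry (160 voxels, 6 runs, 24
  subjects) at prep SNR 0.5 / production SNR 1.0, 200 group repetitions per
  regime, tested one-sided at α = 0.05/7 against a 200-subject simulated
  no-switch baseline: the switch regime rejects in the majority of
  repetitions, the no-switch regime does not.
* **Searchlight localization** — 10×10×10 mask at 2 mm with a 4×4×4 signal
  cube and 4 mm searchlights (33 voxels interior; smaller radius keeps the
  50-simulation study fast without changing the property under test): the
  center of mass of the top half of the order-decoding z map falls inside
  the signal cube in ≥ 90% of simulations.

## What the simulations do and do not show

The generator reproduces the *statistical skeleton* of the task: factorial
condition structure, run effects, phase offsets, component-specific signals,
ROI-matched SNR. It does not model hemodynamics, spatially correlated or
temporally autocorrelated noise, subject motion, anatomical variability, or
inter-subject alignment. Passing tests therefore certify the estimators and
their calibration under the stated model — unbiasedness, specificity, type-I
control, power ordering — not the empirical magnitudes any real region would
produce.

## Known limitations

* The integrated decoder's 0.5 accuracy ceiling (above) is a property of
  the 2×2 interaction projection, not of the implementation.
* The within-phase normalizing denominator pools both phases ("grand
  mean"); per-phase normalization would differ when phase SNRs differ
  strongly.
* Cluster inference reports extents only; no random-field or permutation
  correction.
* With fewer than 4 runs the crossnobis whitener cannot be cross-validated
  and distances regain a positive bias (warned at run time).
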