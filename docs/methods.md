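# Methods

## Model and procedure

The analysis relates two session-indexed blocks: **X** (sessions ×
edges), each row the vectorized upper triangle of a session's FC matrix
(zero-lag Pearson correlation between regional time series; for *k*
nodes, *p = k(k−1)/2* edges in a frozen row-major `i < j` order), and
**Y** (sessions × mood scales).  Both blocks are standardized
column-wise (mean 0, sd 1 with the n−1 denominator; zero-variance
columns are a hard error, never silently dropped).  The cross-block
correlation matrix `R = XzᵀYz/(n−1)` is decomposed by SVD,
`R = U S Vᵀ`.  Each latent variable (LV) is a triple (u, v, σ): paired
edge and scale weight patterns whose projected session scores `Xz u`
and `Yz v` maximize cross-block covariance, with effect size
η_i = σ_i²/Σ_j σ_j².  Scale loadings are Pearson correlations of each
*raw* mood scale with the network scores.  All LVs are computed and
reported; dividing by (n−1) makes R's entries bona-fide correlations
and changes no singular vector or effect size.

SVD signs are arbitrary, so each (u, v) pair is flipped jointly so
that the summed v weight over an anchor set of scales — by default the
general positive-affect scale — is nonnegative.  This fixes the
orientation "positive weights ↔ positive mood" reproducibly.  Without
scale names, the largest-magnitude v entry is made positive.

Item-level mood schedules are scored as the *mean* (not sum) of each
scale's items, with the item → scale map supplied by the user; ratings
are validated against the declared range (0–5 by default).

### Resampling inference

Every p-value uses the (count + 1)/(n_resamples + 1) convention: valid
at finite sample size and never exactly zero, so an overwhelming effect
is reported at the floor 1/(n + 1).

- **Permutation test.** Rows of X are permuted against Y; the i-th
  observed singular value is compared with the i-th null singular value
  per replicate.  No Procrustes alignment of null samples is applied —
  the simplest faithful reading of the procedure; a max-statistic
  variant can be built from the returned null matrix.
- **Bootstrap.** Sessions are resampled jointly in X and Y with
  replacement; replicate singular vectors are sign-aligned to the
  original by a per-LV dot-product flip (reflection is the dominant
  instability for a dominant LV; full Procrustes rotation is out of
  scope).  The bootstrap ratio divides the *original-sample* weight by
  the bootstrap sd (a bootstrap-mean numerator is available via
  `numerator="boot_mean"`).  Degenerate resamples (a single unique
  session, or a zero-variance column) are discarded and counted, with a
  warning if more than 1% are lost.  Loading intervals are percentile
  2.5/97.5.
- **Split-half.** Sessions are split into halves of ⌈n/2⌉ and ⌊n/2⌋;
  each half's cross-correlation matrix is projected onto the
  full-sample singular vectors (U_h = R_h V S⁻¹, V_h = R_hᵀ U S⁻¹;
  LVs with numerically zero singular values are excluded), and the
  per-LV correlation between the two halves' projections is averaged
  over splits with percentile CIs.
- **Cross-validation.** Test sets of ⌈test_fraction · n⌉ sessions
  (19 at 25% of 73) are held out; standardization parameters and the
  decomposition come exclusively from the training rows, so corrupting
  test rows cannot change the fitted model (tested).  Significance by
  permuting rows of X and repeating the whole procedure.

Within permutation and bootstrap replicates the blocks are
re-standardized (a flag disables this); for row permutations this is a
mathematical no-op, for bootstrap resamples it is not.

### Known caveat: split-half null bias

Projecting both halves onto *full-sample* singular vectors couples the
halves through U, S, V.  Under a no-signal null this inflates the
split-half correlation of the low-dimensional pattern: with q = 13
scales and p ≫ n edges, the null mean v-pattern correlation is large
(≈ 0.86 at p = 1770, measured), while the u-pattern correlation is
essentially unbiased once p ≫ n (≈ 0.01–0.03; it reaches ≈ 0.26 only
when p is as small as 45).  High scale-pattern stability numbers from
this procedure should therefore not be read as evidence of signal on
their own; the calibrated null tests in this package assert only the
edge-pattern side, and the generous v-side numbers are expected even
for noise.

### Network statistics

All community statistics take a fixed node → community partition; no
community detection is performed.  Within/between-community densities
and system segregation S = (Z_w − Z_b)/Z_w use raw signed FC weights.
Modularity zeroes negative weights (it is defined on positive-valued
connection weights) and uses the configuration-model expectation
p_ij = s_i s_j / 2m, with the conventional 1/2m normalization so that Q
is comparable across sessions of different total connectivity; the
unnormalized sum Σ[w − ss/2m]δ is available via `normalized=False`.

Two label-permuting nulls are provided.  `label_permutation_null`
permutes node labels independently per replicate for any
partition-valued statistic (e.g. sign-restricted block means of a
bootstrap-ratio matrix) and reports z-scores and two-sided p-values;
entries with zero null sd are flagged undefined rather than zeroed.
`session_consistent_label_null` permutes labels once per replicate and
applies the *same* permutation to every session, recomputing all four
per-session measures and their Spearman correlations with the behavior
scores — the null hypothesis that unspecific density fluctuations, not
module assignments, drive the correlations.  The behavior score for
these correlations is the first LV's mood (y-side) score.

In the seed-fingerprint analysis the seed node is excluded from every
community average and its own label is never permuted; null
correlations from all communities and replicates are pooled into one
distribution for z and p.  "Positive mood" there can be either the raw
positive-affect scale or an LV score — both are plain per-session
vectors to the function; examples use whichever the caller supplies.

Top-contributing nodes use ⌈fraction · k⌉ (32 of 630 at 5%) with ties
broken by node index for determinism.

### Covariates

Fasting contrasts use the pooled-variance (Student) two-sample t with
df = n₁ + n₂ − 2 — the form consistent with df = 71 for a 39 vs 34
split.  Within-group score correlations are compared with the standard
Fisher z, z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).  Lifestyle
variables are screened with one simple linear regression per
(covariate, score type) pair, and Benjamini–Hochberg FDR correction is
applied across the whole family; constant covariates are excluded with
a warning.

## Synthetic data generators

Two generators provide ground truth at different levels, decoupling
unit tests of the decomposition from integration tests of the FC
pipeline.

**Edge-level.** Plants a rank-1 cross-covariance directly:
X = d·t u*ᵀ + E, Y = d·t v*ᵀ + F with per-session latent t_s ~ N(0,1)
i.i.d. (an optional AR(1) session-score mode exists, default off, since
session-to-session autocorrelation is a recognized threat to resampling
estimates) and standard-normal noise.  Defaults mirror the emulated
study design: 73 sessions, 13 scales (PANAS-X names), 518 time points;
60 nodes for desk-scale work.  The default u* is dense Gaussian; the
default v* is a bipolar valence contrast (+1 positive scales, −1
negative, 0 for valence-ambiguous surprise, normalized).  The contrast
has equal nonzero magnitudes on purpose: column standardization scales
a signal column by d·v_j/√(1 + d²v_j²), so unequal-magnitude patterns
are nonlinearly compressed at strong signal and no estimator can
recover them perfectly; the equal-magnitude contrast is invariant to
that compression (and is the more realistic mood structure).  A sparse
u* (via `u_support_fraction`) supports on/off-support reliability
contrasts.

**Time-series level.** Per session, a stationary vector AR(1)
x_t = φ x_{t−1} + √(1−φ²) L z_t whose spatial correlation target has
`within_coupling` inside communities and
`between_coupling + latent_gain · t_s` across communities — the planted
encoding of "integration tracks positive mood"; the latent modulates
*between*-community coupling only.  The lag-1 autocorrelation equals φ
exactly in expectation, and the sample FC converges to the target as T
grows (tested at T = 5000 within ±0.05).  Defaults: within 0.35,
between 0.10, gain 0.10, φ = 0.4 — magnitudes typical of within/between
resting-state network correlations and of band-passed BOLD temporal
autocorrelation.  Coupling magnitudes ≥ 1 (including the modulated
value) are rejected; because a strongly negative common between-block
correlation is mathematically infeasible as an exact target on large
networks, negative eigenvalues of the ideal target are clipped at 1e-8
and the matrix renormalized to unit diagonal, so extreme latent draws
saturate the modulation instead of aborting a simulation.

The covariate generator produces a strictly alternating fasting
indicator (37/36 at n = 73; real acquisition schedules produce slightly
uneven splits such as 39 vs 34 through missed sessions, which is not
modeled) and lifestyle columns (alcohol, gut health, stress, time outdoors,
weather, sleep staging) drawn independently of the latent — the null
ground truth for the regression screen.

**What the generators do not emulate:** hemodynamics, motion or
physiological artifacts, frame censoring, spatial autocorrelation of
parcels, heavy-tailed or ordinal mood distributions, and (by default)
session-to-session autocorrelation.  Passing tests therefore show the
statistical machinery is correct and calibrated under the stated
model, not that real fMRI preprocessing choices are handled.

## Numerical choices

- Edge order: row-major upper triangle, 0-based, `i < j` — a frozen,
  serialized contract.
- Degenerate inputs raise with the offending column/node named:
  constant time series, zero-variance block columns, all-zero singular
  values, partitions not covering the node set, communities containing
  only the seed (flagged NaN, not zero).
- Singular values below 1e-10 (relative) are excluded from split-half
  projections (S⁻¹ would blow up).
- All stage seeds derive from one master seed via
  `numpy.random.SeedSequence` spawning; identical (inputs, config,
  seed) reproduce outputs byte for byte.
- Test-set size uses the ceiling; top-fraction node counts use the
  ceiling; split halves of odd n are ⌈n/2⌉ / ⌊n/2⌋.

## Problem sizes in the test suite

The shipped tests run the full statistical battery at reduced but
honest scales chosen to keep the suite fast while preserving the
regimes that matter (sessions ≪ edges for the PLS tests; hundreds of
resamples for calibration): permutation-test calibration uses 200 null
datasets × 500 permutations at 45 edges; label-null z calibration uses
500 datasets × 200 permutations at 20 nodes; pattern recovery uses 60
nodes (1770 edges) at n = 100; the integration→mood power check uses
50 replicates of 73 sessions × 40 nodes × 300 time points with 200
permutations each.  `scripts/acceptance.py` reruns the pipeline at the
emulated design scale (73 sessions; 60-node edge-level and 40-node
time-series datasets) with 500–2000 resamples per procedure.

## Limitations

- Only sessions present in both blocks are analyzed; no imputation.
- No regression-mode PLS (SIMPLS), canonical correlation, or sparse
  variants; no partial-correlation or tangent-space FC; no analytic
  significance approximations; no spatial/geometric null models.
- The split-half stability of the low-dimensional (scale) pattern is
  optimistically biased under the null (see above); interpret it
  jointly with the permutation and cross-validation results.
- Bootstrap CIs here are fixed-effects statements about one subject's
  sessions; with temporally autocorrelated sessions they can be too
  narrow.
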