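# Methods

## The factorial response model

The unit of analysis is a feature (protein or transcript) with replicate
log2 fold changes under three test conditions of a 2×2 binary stimulus
design: stimulus A alone, stimulus B alone, and both concurrently (AB).
Fold changes are taken relative to the unstimulated baseline, so the
baseline itself never appears as a sample and its fold change is
identically zero.

The model is parameterized as cell means: one coefficient per test
condition, no intercept. This is numerically the saturated main-effects +
interaction model of the 2×2 design refit to condition means, and it is the
parameterization the downstream classification needs — each of the three
"effect size estimates" is a condition mean fold change whose sign is the
direction of regulation and whose t test asks "does this condition change
this feature". A dummy-coded factorial fit would instead make the third
coefficient the interaction contrast, which is not the quantity the class
rules threshold.

For condition means β_c with replicate counts n_c (n = Σ n_c):

- pooled residual variance s² = SS_within / (n − 3), se_c = s/√n_c;
- coefficient t_c = β_c / se_c with n − 3 df, two-sided p;
- overall F = [Σ_c n_c β_c² / 3] / s² with (3, n − 3) df, testing all
  three means jointly zero (a no-intercept joint test, consistent with the
  3 numerator df of the design).

Overall p-values are Benjamini–Hochberg adjusted across all features (the
only family correction applied); responders are features with q ≤ 0.05.
Coefficient p-values are used raw at p < 0.05, as is conventional for the
second, conditional stage of this two-stage procedure.

Conventions at the boundaries: the responder gate is inclusive (q ≤
threshold), coefficient significance strict (p < α). Zero residual
variance (possible for noiseless synthetic input) cannot produce a t
statistic; by convention the coefficient p is 0 where β ≠ 0 and 1 where
β = 0, and the feature is flagged. Unbalanced replicate counts (e.g. the
5/3/4/3 chemostat design supported by `fold_changes_from_baseline`) are
handled by the same formulas; df_resid stays n − 3.

## Interaction classes

Coding each condition's response as significant-up / significant-down /
not-significant gives 27 states. The rules are applied in a fixed order
(NER before dominance resolves their only overlap; the all-significant
same-direction state belongs to NER):

1. not a responder → NON_RESPONDER;
2. all three significant, same direction → NER (2 patterns);
3. A and AB significant and same direction, B non-significant or opposed →
   A_DOMINANT (4); mirror for B_DOMINANT (4);
4. AB non-significant but A or B significant → SUPPRESSION (8);
5. AB significant, matched in direction by neither single stimulus →
   DISCORDANT (8);
6. otherwise UNCLASSIFIED.

UNCLASSIFIED exists because the joint F can be significant when no single
coefficient is; such responders carry the all-non-significant state. They
are counted and surfaced as a warning rather than forced into a class.

## Environmental epistasis

Additivity is the null: the combined response equals the sum of the single
responses. The statistic is

    t = (β_A + β_B − β_AB) / √(se_A² + se_B² + se_AB²)

with the feature model's residual df (a Welch–Satterthwaite df over the
three components is available behind `epistasis_welch=True`; with a pooled
variance the two coincide for balanced designs). Epistasis is called at
p ≤ 0.05, evaluated for every feature — responder or not — so the
epistatic/non-epistatic split partitions the whole feature set. Under the
balanced 3-replicate design the statistic is exactly t-distributed with
n − 3 df under additivity, which is what the 10,000-feature null
calibration in the acceptance script verifies (rejection rate 0.05 ± 0.01).
Only the additive definition of epistasis is implemented; multiplicative,
minimum and log definitions are out of scope.

## Synthetic-data generator

The generator is the package's study condition, not a tuning knob. True
condition means take values in {0, +effect_size, −effect_size} only: each
feature is assigned a class (largest-remainder apportionment of the
requested mix), a pattern drawn uniformly from the class's admissible
sign/significance patterns, and means equal to pattern × effect_size.
Replicate values add independent Gaussian noise. Defaults — effect 1.0
log2 units, replicate sd 0.2, 3 replicates per condition — describe a
well-powered isobaric-labeling proteomics design in which a two-fold change
is about five replicate standard deviations; they give per-class recall and
precision above 0.9 without being noiseless. The epistatic flag is computed
from the means (μ_AB ≠ μ_A + μ_B), never sampled. Suppression features
have μ_AB = 0 exactly; discordant features have single-stimulus means 0 or
opposite in sign to μ_AB.

The additive null model draws μ_A, μ_B ~ Uniform(−1, 1) and sets
μ_AB = μ_A + μ_B exactly; it is the calibration bed for the epistasis test.

What the generator does not emulate: reporter-ion ratio compression,
missing values, feature-dependent variance, and correlated replicates. A
classification accuracy of 0.98 on this generator therefore demonstrates
that the statistical machinery is correct under its own assumptions, not
that real proteomes are classified with that accuracy.

Growth curves are exponential: OD(t) = od0·2^((t − lag)/τ) after a lag,
optionally capped at a stationary plateau, with log-normal noise on OD;
3-minute sampling mirrors a plate reader.

## Coexpression network

The pipeline order is fixed and logged: PQN → glog → standardize →
estimate → threshold.

- **PQN** computes each sample's dilution factor as the median quotient
  against the feature-wise median reference. On signed fold-change data the
  quotient is unstable near zero references, so features with |reference| ≤
  1e-8 are excluded from the median; PQN can also be skipped entirely
  (`apply_pqn=False`), which is the sensible setting for data that are
  already ratios to a common baseline.
- **glog**: g(x) = ln((x + √(x² + λ))/2), natural log, λ = 1.0 by default;
  defined for negative values, → ln(x) for large x. For x < 0 the
  algebraically equivalent form λ/(√(x²+λ) − x) avoids cancellation.
- **Standardization**: per feature, mean 0 and sd 1 across samples
  (ddof = 1); zero-variance features are an error, not silently dropped.

The sparse partial-correlation estimator minimizes

    1/2 Σ_i w_i ‖x_i − Σ_{j≠i} ρ_ij √(d_j/d_i) x_j‖² + λ Σ_{i<j} |ρ_ij|

over the symmetric matrix ρ by cyclic coordinate descent (soft-threshold
updates over pairs, convergence at max |Δρ| < 1e-6, warning on
non-convergence). d_i are residual precisions, re-estimated for 3 outer
iterations with weights w_i = d_i (down-weighting noisy variables). The
default penalty is λ = √n · Φ⁻¹(1 − α/(2p²)) with α = 0.1, the
√n-scaled normal-quantile rule canonical for this estimator family. Two
limits anchor the implementation: λ → ∞ empties the matrix, and λ = 0
reproduces the dense sample partial correlation (the latter requires the
weight iteration to converge to the precision diagonal, so the dense-limit
test passes `n_outer=25`; with the default 3 outer iterations the penalized
estimates of interest are unaffected).

Edges join pairs whose |partial correlation| strictly exceeds the mean
absolute off-diagonal value of the estimated matrix (zeros included in the
mean). Absolute values prevent sign-dependent edge loss; a signed variant
and a fixed threshold are config switches. Isolated nodes stay in the node
table and are reported separately from "nodes with at least one neighbor".

Degree validation fits a discrete power law P(k) ∝ k^(−α) for k ≥ x_min
(default 1) by maximum likelihood with the Hurwitz-zeta normalization,
optimized numerically; the log-log frequency-regression estimate is
reported only as a diagnostic because it is known to be biased (it
underestimates α noticeably — both numbers are printed so the discrepancy
is visible). Hubs are the ceil(hub_fraction × n) top-degree nodes (ties by
node id, fraction 0.01 by default); their stability is the mean pairwise
Jaccard index between hub sets recomputed across the tuning grid (1.0 by
convention for a single network), and their significance a two-sided
Wilcoxon rank-sum test of hub vs non-hub degrees. Both the Jaccard and
rank-sum constructions are interpretations of loosely specified
conventions in the field and are labeled as such. On small synthetic
networks (~80 nodes) a 1% hub fraction selects a single node, making the
Jaccard score a coin flip; the acceptance script therefore uses 5% there.

Edge tallies form two partitions of the edge set — (both endpoints
epistatic, neither, mixed) and (same interaction class, different) — each
summing to |E|; the identities are asserted on every run.

## Growth kinetics

Doubling time is 1/slope of log2(OD) on time. The log phase is found by a
sliding full-length window (default 90 min, ≥ 10 points): among windows
with R² ≥ 0.98 the steepest is taken. Lag and plateau windows fail the R²
floor or have smaller slopes; windows shorter than the nominal length
(curve tails) are skipped as unstable, and a curve shorter than the window
is fit whole. A flat, noiseless window has R² defined as 1 (zero residual,
zero total variance), so constant curves resolve to a non-growing flag
(infinite doubling time) rather than an error. Window length, point
minimum and R² floor are configurable; the selection scheme itself is a
package convention, since "regression through the log phase" underdetermines
the window.

Stimulus effects are differences of mean doubling time vs control, with
difference-of-means SE √(sd_c²/n_c + sd_0²/n_0); the condition's replicate
SD is reported alongside. The additivity test compares the observed
concurrent effect to the sum of single effects (SE = root sum of squares)
with a Welch t-test — Satterthwaite df over the component effects using
n_i − 1 per component — and Bonferroni-corrects by the experiment's
comparison count (default 11, matching a 7 + 3 + 1 comparison design).
The correlation between observed and expected effects through the shared
control mean is ignored (independence approximation). Pooled-variance
rather than Welch testing is not offered for growth effects because the
replicate counts and variances per condition are typically unequal.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at the
sizes stated in each check: 500 features for classification recovery,
10,000 for the epistasis null calibration, chain graphs of 10 variables ×
500 samples for support recovery, 5,000 degree draws for power-law
recovery, 80 features for the end-to-end network run. These sizes were
chosen to make stochastic assertions stable at the stated tolerances.

## Known limitations

- The classification is rule-based on marginal significance; it inherits
  the multiplicity behavior of raw coefficient p-values at the second
  stage.
- PQN on signed data is a convention, not a derivation; prefer skipping it
  when inputs are already baseline-referenced log ratios.
- The partial-correlation estimator's default penalty is a theory-driven
  rule, not cross-validated; network-level statistics (node counts, hub
  sets) are sensitive to it, which is exactly why the tuning-grid Jaccard
  is reported.
- With few samples (e.g. 9) the network stage estimates p ≫ n partial
  correlations; results should be read as exploratory structure, not
  inferred conditional independence.
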