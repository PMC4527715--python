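# envepi

Environmental interaction and epistasis analysis of factorial
stimulus-response omics data.

When a cell is exposed to two environmental stimuli at once — say high
temperature and a non-fermentable carbon source — the response of each
protein or transcript to the combined condition need not be the sum of its
responses to the single stimuli. By analogy with gene interaction, the two
stimuli can *interact*: one can be dominant over the other, a response can
be suppressed by the second stimulus, or the combined condition can produce
a change that neither stimulus causes alone. When the combined response
deviates from additivity the feature is said to be affected by
**environmental epistasis**.

`envepi` implements this framework as a tested pipeline for feature ×
sample matrices of log2 fold changes measured under a 2×2 factorial design
(stimulus A, stimulus B, both concurrently, against a common baseline):

- **Per-feature factorial model.** Each feature's replicate fold changes
  are fit with a cell-means regression (one coefficient per test
  condition, no intercept): β_A, β_B, β_AB are condition mean fold changes
  with pooled-variance standard errors s/√n_c, coefficient t tests on
  n − 3 df, and an overall 3-df F test of all means jointly zero. Overall
  p-values are Benjamini–Hochberg adjusted across features; a feature is a
  *responder* when q ≤ 0.05.
- **Interaction classes.** Responders are classified from the significance
  (p < 0.05) and sign of the three estimates: non-specific environmental
  response (NER, all same direction), A-dominant, B-dominant, suppression
  (combined response absent while a single response is present), and
  discordant (combined response matched by neither stimulus). Over the 27
  possible sign/significance states the classes comprise 2/4/4/8/8
  theoretical patterns.
- **Epistasis test.** Per feature, t = (β_A + β_B − β_AB) /
  √(se_A² + se_B² + se_AB²) on the model's residual df; p ≤ 0.05 flags
  epistasis.
- **Coexpression network.** Probabilistic quotient normalization →
  generalized log transform → per-feature standardization → sparse
  partial-correlation estimation (joint symmetric lasso regression with
  residual-precision weights, cyclic coordinate descent) → edges where
  |partial correlation| exceeds the matrix's mean absolute off-diagonal
  value. Degree distributions are checked against a discrete power law
  (maximum likelihood), hubs are the top fraction by degree with a
  tuning-grid Jaccard stability score and a rank-sum significance test,
  and edges are tallied within/between epistasis flags and interaction
  classes.
- **Growth kinetics.** Doubling times from log-linear regression over the
  steepest high-R² window of log2(OD) vs time; stimulus effects as changes
  in doubling time vs control; additivity of concurrent stimuli tested
  with a Bonferroni-corrected Welch t-test.
- **Synthetic data.** A generator with known per-feature ground truth
  (class, pattern, true means) emulating the replicate structure of an
  iTRAQ-style experiment, an exactly additive null model for calibration,
  and exponential growth curves — so every stage runs and is testable
  without external data.

## Worked example

```sh
envepi simulate --n-features 500 --seed 7 --out sim/
envepi interactions --matrix sim/fold_changes.tsv --out results/
```

The second command prints (output from this exact invocation):

```
Stimulus-response factorial model
================================================
features: 500   samples: 9
stimuli: HT, G (concurrent HTG)
responder gate: q <= 0.05 (BH on overall ANOVA p)
coefficient significance: p < 0.05

differentially expressed: HT 320, G 313, HTG 337

interaction classes:
  HT-dominant                                83
  G-dominant                                 83
  non-specific environmental response        86
  discordant                                 85
  suppression                                81
  non-responder                              82

environmental epistasis (p <= 0.05): 315 affected, 185 not affected
```

The simulated truth allocates the 500 features evenly across the six
classes (83–84 each); the fitted classification recovers them with ~98%
accuracy, so each reported class count sits within a few features of its
true size. The DE lines count features that respond (q ≤ 0.05 overall and
coefficient p < 0.05) in each condition; the epistasis line splits all 500
features by the additivity test. The same run writes `feature_models.tsv`
(estimates, SEs, p, q), `interaction_classes.tsv`, `epistasis.tsv` and
`summary_counts.tsv` to `results/`.

The library mirrors the CLI with statsmodels-style objects:

```python
from envepi import GeneratorConfig, generate_truth_table, \
    simulate_fold_changes, StimulusResponseModel

cfg = GeneratorConfig(n_features=500, seed=7)
matrix = simulate_fold_changes(generate_truth_table(cfg), cfg)
results = StimulusResponseModel(matrix).fit()
print(results.summary())
results.epistasis_frame.head()
```

`envepi network` adds the coexpression stage; `envepi growth` estimates
doubling times and the additivity test from long-format curve TSVs.

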