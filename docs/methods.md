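# Methods

## Null models

The package predicts the combined response of two simultaneous stressors —
always warming (`S_A`) plus one other stressor (`S_B`) — from their
independent responses relative to a shared control `C`:

* **additive**: `X_p = S_A + S_B − C`. For response metrics that cannot be
  negative (abundance, biomass, diversity, survival, decomposition) a
  negative prediction is replaced by zero and flagged `clamped`. The
  non-negative set is a package constant; growth/size and condition are
  treated as sign-free. Clamping applies to the additive model only: the
  multiplicative prediction cannot go negative when all inputs are positive,
  and for mixed-sign data we deliberately leave it unclamped rather than
  invent a rule.
* **multiplicative**: `X_p = S_A·S_B / C`, undefined when `C = 0`. We flag
  the record for this model rather than patching the denominator with a
  constant, which would silently distort effect sizes; the record still
  participates in the other two models.
* **dominance**: `X_p = S_A` iff `|S_A−C| > |S_B−C|`, else `S_B`. The
  strict inequality means exact ties fall to the `S_B` branch; a relative
  tie tolerance (default 1e-9) additionally labels near-ties
  (`dominant_stressor="tie"`) without changing the value, so the
  classification layer can see that the choice of arm was arbitrary.

All three predictions of one record share a single uncertainty: the SD
pooling the two single-stressor arms with `(n−1)` weights, and a prediction
sample size `n_p = min(n_A, n_B)`.

## Effect sizes

Hedges' *d* compares the observed combined arm with each prediction (see
README for the formulas). Numerical conventions:

* A zero predicted effect (`X_p = C`) does not trigger sign inversion; the
  rule fires only for predictions strictly below control.
* A zero pooled SD (both arms variance-free) yields an *undefined* effect
  flag, not an infinite d; any finite substitute would be arbitrary. Such
  records are excluded from the meta-analysis and reported in the run log.
* The inversion rule is keyed on each model's own predicted effect, so one
  record can have inverted and non-inverted effects across models.
* Outlier flagging (`|d| > 30`, strict) is per (record, model) pair.
  Outliers are dropped from the meta-analysis but retained in frequency
  counts and best-model selection, which are descriptive tallies.

## Classification

* **Range position**: the observed mean against the closed interval between
  the lowest and highest *defined* predictions.
* **Best model**: smallest `|d|`. Because all models share `(s_p, n_p)`,
  ranking by `|d|` and by raw `|X_o − X_p|` give identical winners; when all
  three d are undefined because the pooled SD is zero (noise-free data) the
  implementation therefore falls back to the raw deviation. The top two
  scores tying within a tolerance (default 1e-6 on `|d|`) yields
  `undefined` — this captures records where predictions coincide exactly
  (e.g. a stressor with no independent effect) without absorbing real
  differences.
* **Asymmetry**: `degree = |pctA − pctB|` with percent effects relative to
  control. The asymmetric flag uses the difference of *absolute* percent
  effects (`||pctA| − |pctB|| > 50` percentage points), so a strong negative
  effect prevails over a weak positive one; the threshold is configurable
  because a relative (ratio) reading is also defensible. Undefined when
  `C = 0`.
* Grouped frequency tables drop levels with fewer than 8 classified
  responses (configurable).

## Multilevel meta-analysis

Effect sizes are pooled with the three-level model
`d_i = x_i'β + u_study(i) + u_id(i) + e_i`, `e_i ~ N(0, v_i)` with known
`v_i = V_d`, random intercepts for study (non-independence of responses from
one study) and for observation ID nested in study (residual heterogeneity).
Fixed effects use no-intercept dummy coding, one mean per moderator level,
so each coefficient and its Wald CI is directly the level's pooled effect;
QM is the Wald chi-square that all level means are zero (df = number of
levels), QE the classical 1/v-weighted residual heterogeneity statistic
(df = k − p), both against chi-square references.

Variance components are estimated by REML: the profiled negative restricted
log-likelihood is minimised over `(τ²_study, τ²_id)` with L-BFGS-B under
non-negativity bounds, three starting points (balanced and each component
near zero), and block-wise Cholesky factorisation per study for speed.
`k ≤ p` fixes both components at zero (saturated fit). A fit with
`tau2=(0, 0)` reproduces the closed-form inverse-variance weighted means,
and with one effect per study and `τ²_id = 0` the model reduces to a
standard random-effects meta-analysis; the test suite cross-checks both
reductions (against the closed form and statsmodels' DerSimonian–Laird
pooling) and the full fit against R metafor's `rma.mv`, which agrees to
about 1e-4 at optimizer tolerance.

The accuracy–asymmetry relationship is a Gamma GLM with log link,
`log E[|d|] = b0 + b1·degree`, fitted by statsmodels IRLS separately per
prevailing-stressor subset. A constant `1e-9` is added to the responses of
the temperature-prevailing subset; the pipeline switches the constant on for
any subset that contains exact zeros of `|d|` (which synthetic data can
produce when an arm collapses to zero), recording `epsilon_applied` in the
artifact. An exactly constant response is handled analytically
(`b0 = log y`, `b1 = 0`) since IRLS cannot start from zero deviance.

## Synthetic data generator

The generator emulates a compiled database of 4-arm factorial summaries
with study-level clustering; it does **not** emulate publication bias,
unequal stressor-type frequencies, correlated responses within an
experiment, non-normal replicate distributions, or reporting error. Passing
recovery tests therefore demonstrates correctness of the pipeline's
arithmetic and estimators under the stated generative model, not robustness
to every feature of literature-compiled data.

Defaults, chosen once as field-realistic: 30 studies of 1–4 responses,
3–6 replicates per arm; control means log-normal (median 20, σ_log 0.5);
within-arm CV 10%; stressor effects −20% (warming) and −50% (second
stressor) of control — harmful stressors, the prevalent case in warming
experiments; between-study SD 10 percentage points on the percent-effect
scale (so asymmetry targets remain interpretable across control means); a
metric mix of 65% non-negative and 35% sign-free metrics. Within-arm
replicates are normal, truncated at zero for non-negative metrics, and arm
summaries are the sample mean and SD; a CV above 0.5 with non-negative
metrics is rejected as infeasible, because the truncation then removes a
non-negligible share of the distribution and biases the summaries.

`asymmetry_target` sets the second stressor's percent effect to the
warming effect minus the target, making the configured degree of asymmetry
exact on noiseless data. The `reversal` regime sets the combined effect to
the negative of the summed single effects (`X = C − (S_A−C) − (S_B−C)`),
guaranteed outside the three-model range whenever both single effects share
a sign. Seeding derives one substream per (study, response) by counter, so
record sets are reproducible and stable under reordering.

Two geometric facts shape the recovery behaviour and are visible in tests:
discrimination of the dominance regime from the additive one improves as
the prevailing (negative) effect grows, because the combined arm's mean and
hence its CV-scaled noise shrink while the additive–dominance gap (the
weaker effect) is unchanged; and as the prevailing percent effect
approaches −100% the multiplicative and dominance predictions converge
(both approach zero), so best-model selection legitimately returns
`undefined` more often at extreme asymmetry.

## Problem sizes

Tests and the acceptance script use 25–60 study databases (about 100–180
responses — the scale of the motivating compiled database), 200 replicate
meta-datasets for estimator recovery, and 10⁴ random draws for the
arithmetic oracles; the full suite runs in about a minute.

## Known limitations

* The REML surface can be flat when study and ID components are weakly
  separated (few studies, one response each); estimates then trade off
  between `τ²_study` and `τ²_id` although their sum — and the fixed
  effects — remain stable.
* Wald CIs (z, not t) match the default of standard meta-analytic software
  but are anti-conservative for very few studies.
* Mortality data must be converted to survival upstream; the loader treats
  this as an input convention and does not detect it.
* The multiplicative model is left undefined for `C = 0` records; datasets
  with many zero controls will carry many flagged records.
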