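# multistress

Predicting and classifying the joint effect of climate warming and a second
environmental stressor from fully factorial experiments.

Ecologists routinely measure a biological response (abundance, biomass,
growth, survival, ...) under four treatments: an unstressed control `C`,
warming alone `S_A`, a second stressor alone `S_B` (nutrients, contamination,
acidification, habitat alteration, ...), and both stressors combined `X_o`.
`multistress` asks: which *null model* of stressor combination best predicts
the combined response, and how far do observed responses deviate from each
prediction?

## The models and statistics

Three null predictions of the combined response:

| model          | prediction `X_p`                                | assumption |
|----------------|-------------------------------------------------|------------|
| additive       | `S_A + S_B − C`                                 | effects add on the raw scale |
| multiplicative | `S_A · S_B / C`                                 | proportional effects multiply |
| dominance      | `S_A` if `|S_A−C| > |S_B−C|` else `S_B`         | the stronger stressor masks the weaker |

Negative additive predictions are replaced with zero for metrics that cannot
be negative (there is no negative abundance). Deviation of observation from
prediction is measured by the bias-corrected standardised mean difference
(Hedges' *d*):

```
d   = J (X_o − X_p) / s,           J = 1 − 3 / (4(n_o + n_p − 2) − 1)
s   = sqrt( ((n_o−1) s_o² + (n_p−1) s_p²) / (n_o + n_p − 2) )
V_d = (n_o + n_p)/(n_o n_p) + d² / (2 (n_o + n_p))
```

where the prediction's SD pools the two single-stressor arms and
`n_p = min(n_A, n_B)`. Signs are inverted when the predicted effect is
negative relative to control, so negative *d* always means *observed effect
smaller than predicted* (antagonistic) and positive means larger. Effects
with `|d| > 30` are treated as outliers.

Per-record classification reports whether `X_o` falls within / below / above
the range spanned by the three predictions, the best model (smallest `|d|`),
and the *degree of asymmetry* between the single-stressor effects,
`|((S_A−C)/C − (S_B−C)/C) × 100|`, with a pair called asymmetric when one
percent effect exceeds the other by more than 50 points.

Mean deviations are pooled by a three-level random-effects meta-analysis
(`d_i = x_i'β + u_study + u_id + e_i`, REML; residual-heterogeneity QE and
moderator QM tests), matching an `rma.mv`-style model with observation IDs
nested in studies. The accuracy–asymmetry relationship is a Gamma GLM with
log link of `|d|` on asymmetry degree, fitted separately for
temperature-prevailing and other-prevailing subsets.

## Worked example

```python
from multistress import (SyntheticConfig, generate_database,
                         classify_database, frequency_table,
                         effects_frame, fit_multilevel_meta)

db, truth = generate_database(SyntheticConfig(seed=42, n_studies=40,
                                              responses_per_study=(2, 4),
                                              true_regime="dominance"))
cls = classify_database(db)
print(frequency_table(cls.assign(all="all"), "all", min_n=1))

eff = effects_frame(db)
usable = eff[eff["defined"] & ~eff["outlier"] & (eff["model"] == "additive")]
print(fit_multilevel_meta(usable, moderator_col="organisation_level").summary())
```

prints (117 responses generated under a dominance regime with harmful
stressors, −20% warming and −50% second-stressor effects):

```
  n  pct_within  pct_below  pct_above  pct_best_additive  pct_best_multiplicative  pct_best_dominance
117        49.6        1.7       48.7                1.7                      6.8                91.5

Multilevel random-effects meta-analysis (REML)
k = 117 effects, 40 studies, 3 level mean(s)
tau2_study = 2.3039   tau2_id = 0.1902
QE(114) = 358.663, p = 4.279e-27
QM(3) = 153.405, p = 4.855e-33
converged: True (26 optimizer iterations)

            mean_d     se   k  ci_low  ci_high interaction_class
community  -3.2742 0.4098  51 -4.0774  -2.4709      antagonistic
individual -3.2268 0.5096  30 -4.2256  -2.2279      antagonistic
population -3.4475 0.4900  36 -4.4080  -2.4871      antagonistic
```

The classifier recovers the generating dominance regime for 91.5% of
records, and the pooled Hedges' *d* against the additive prediction is
strongly negative at every organisational level: observed combined impacts
are smaller than additive expectations — antagonism, as expected when the
stronger stressor masks the weaker one.

The same pipeline runs from the shell on any CSV matching the shipped
schema (`multistress.database.schema()`):

```
multistress simulate --seed 42 --n-studies 40 --out db.csv
multistress run-all db.csv --outdir run/
```

writing predictions, classifications, effect sizes, per-grouping frequency
tables, meta-analysis fits and asymmetry GLM fits under `run/`.

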