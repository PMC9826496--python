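"""Synthetic factorial two-stressor databases with known ground truth.

The generator emulates the statistical structure of a compiled experimental
database: studies contribute one or more responses, each response is a
4-arm factorial summary (control, warming alone, second stressor alone,
combined), and the true combined response follows a configurable interaction
regime — additive, multiplicative, dominance, or reversal (a combined effect
opposite in direction to the single-stressor effects, hence outside the
range of all three null models).

Stressor effects are specified as signed percent changes of the control
mean; between-study heterogeneity is injected on that percent-effect scale,
so the configured asymmetry degree is exactly the percent-effect difference
the classification stage computes.  Within-arm variation is normal with a
configurable coefficient of variation, truncated at zero for metrics that
cannot be negative; arm summaries are the sample mean and SD of the
simulated replicates.  The defaults describe harmful stressors (negative
percent effects), the prevalent case in warming experiments.

Seeding uses per-(study, response) counter-derived substreams, so the
generated records are stable under reordering and fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .database import (
    NON_NEGATIVE_METRICS,
    ExperimentRecord,
    ResponseDatabase,
    TreatmentSummary,
)

REGIMES = ("additive", "multiplicative", "dominance", "reversal")

_DEFAULT_METRIC_PROBS = (
    ("abundance", 0.35),
    ("biomass", 0.20),
    ("survival", 0.10),
    ("growth_size", 0.25),
    ("condition", 0.10),
)
_STRESSOR_TYPES = (
    "nutrients",
    "contamination",
    "acidification",
    "habitat_alteration",
    "food_quantity",
    "salinity",
)
_ORG_LEVELS = ("individual", "population", "community")
_ORGANISMS = ("invertebrate", "fish", "algae", "zooplankton", "microbe")


class ConfigError(ValueError):
    """The synthetic-data configuration is invalid or infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic database.

    Percent effects are signed changes relative to the control mean; the
    defaults (-20% warming, -50% second stressor) describe two harmful
    stressors with the second one prevailing.  ``asymmetry_target``, when
    set, overrides ``effect_b_pct`` so that the percent-effect difference
    |pct_temp - pct_b| equals the target exactly (the second stressor made
    more negative than temperature by the target).
    """

    n_studies: int = 30
    responses_per_study: tuple[int, int] = (1, 4)
    replicates_per_arm: tuple[int, int] = (3, 6)
    control_mean_median: float = 20.0
    control_mean_sigma_log: float = 0.5
    cv: float = 0.10
    true_regime: str = "dominance"
    effect_temp_pct: float = -20.0
    effect_b_pct: float = -50.0
    between_study_sd_pct: float = 10.0
    asymmetry_target: Optional[float] = None
    metric_probs: tuple = _DEFAULT_METRIC_PROBS
    seed: int = 0

    def __post_init__(self):
        if self.true_regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.true_regime!r}; use {REGIMES}")
        if self.n_studies < 1:
            raise ConfigError("n_studies must be >= 1")
        lo, hi = self.responses_per_study
        if not (1 <= lo <= hi):
            raise ConfigError("responses_per_study range invalid")
        rlo, rhi = self.replicates_per_arm
        if not (2 <= rlo <= rhi):
            raise ConfigError("replicates_per_arm must be >= 2")
        if self.cv < 0 or self.between_study_sd_pct < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        probs = [p for _, p in self.metric_probs]
        if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0):
            raise ConfigError("metric probabilities must be >= 0 and sum to 1")
        has_nonneg = any(
            m in NON_NEGATIVE_METRICS and p > 0 for m, p in self.metric_probs
        )
        # With sd = cv * mean, the mass a zero-truncation removes is
        # Phi(-1/cv); beyond cv = 0.5 the truncation visibly distorts the
        # arm summaries, so such configs are rejected as infeasible.
        if has_nonneg and self.cv > 0.5:
            raise ConfigError(
                f"cv = {self.cv} too large for zero-truncated non-negative "
                "metrics (require cv <= 0.5)"
            )

    @property
    def pct_b_base(self) -> float:
        if self.asymmetry_target is not None:
            return self.effect_temp_pct - self.asymmetry_target
        return self.effect_b_pct


def _combined_population_mean(
    regime: str, c0: float, sa: float, sb: float, non_negative: bool
) -> float:
    if regime == "additive":
        x = sa + sb - c0
    elif regime == "multiplicative":
        x = sa * sb / c0
    elif regime == "dominance":
        x = sa if abs(sa - c0) > abs(sb - c0) else sb
    else:  # reversal: combined effect opposite in sign to the summed singles
        x = c0 - ((sa - c0) + (sb - c0))
    if non_negative and x < 0:
        x = 0.0
    return x


def _sample_arm(
    rng: np.random.Generator,
    pop_mean: float,
    cv: float,
    n: int,
    non_negative: bool,
) -> TreatmentSummary:
    sd_pop = cv * abs(pop_mean)
    if sd_pop == 0:
        return TreatmentSummary(pop_mean, 0.0, n)
    if non_negative and pop_mean >= 0:
        a = (0.0 - pop_mean) / sd_pop
        x = sps.truncnorm.rvs(a, np.inf, loc=pop_mean, scale=sd_pop, size=n,
                              random_state=rng)
    else:
        x = rng.normal(pop_mean, sd_pop, size=n)
    return TreatmentSummary(float(np.mean(x)), float(np.std(x, ddof=1)), n)


def generate_database(cfg: SyntheticConfig) -> tuple[ResponseDatabase, pd.DataFrame]:
    """Generate a database and its truth table.

    Returns ``(db, truth)`` where ``truth`` holds, per response, the latent
    percent effects, population arm means, regime and population asymmetry
    degree.  Deterministic under ``cfg.seed``.
    """
    metrics = [m for m, _ in cfg.metric_probs]
    probs = [p for _, p in cfg.metric_probs]
    records: list[ExperimentRecord] = []
    truth_rows = []
    for s in range(cfg.n_studies):
        rng_study = np.random.default_rng([cfg.seed, s, 0])
        pct_a = cfg.effect_temp_pct + rng_study.normal(0, cfg.between_study_sd_pct)
        pct_b = cfg.pct_b_base + rng_study.normal(0, cfg.between_study_sd_pct)
        stressor_b = _STRESSOR_TYPES[int(rng_study.integers(len(_STRESSOR_TYPES)))]
        org_level = _ORG_LEVELS[int(rng_study.integers(len(_ORG_LEVELS)))]
        organism = _ORGANISMS[int(rng_study.integers(len(_ORGANISMS)))]
        lo, hi = cfg.responses_per_study
        n_resp = int(rng_study.integers(lo, hi + 1))
        for r in range(n_resp):
            rng = np.random.default_rng([cfg.seed, s, r + 1])
            metric = str(rng.choice(metrics, p=probs))
            non_neg = metric in NON_NEGATIVE_METRICS
            c0 = float(
                rng.lognormal(math.log(cfg.control_mean_median),
                              cfg.control_mean_sigma_log)
            )
            sa = c0 * (1.0 + pct_a / 100.0)
            sb = c0 * (1.0 + pct_b / 100.0)
            if non_neg:
                sa, sb = max(sa, 0.0), max(sb, 0.0)
            x_comb = _combined_population_mean(cfg.true_regime, c0, sa, sb, non_neg)
            rlo, rhi = cfg.replicates_per_arm
            arms = {}
            for key, mu in (("control", c0), ("temp_alone", sa),
                            ("stressorB_alone", sb), ("combined", x_comb)):
                n = int(rng.integers(rlo, rhi + 1))
                arms[key] = _sample_arm(rng, mu, cfg.cv, n, non_neg)
            study_id = f"S{s + 1:03d}"
            response_id = f"R{r + 1}"
            records.append(
                ExperimentRecord(
                    study_id=study_id,
                    response_id=response_id,
                    stressor_b_type=stressor_b,
                    organisation_level=org_level,
                    organism_group=organism,
                    response_metric=metric,
                    **arms,
                )
            )
            truth_rows.append(
                {
                    "study_id": study_id,
                    "response_id": response_id,
                    "true_regime": cfg.true_regime,
                    "response_metric": metric,
                    "pct_effect_temp": pct_a,
                    "pct_effect_b": pct_b,
                    "pop_control": c0,
                    "pop_temp_alone": sa,
                    "pop_stressorB_alone": sb,
                    "pop_combined": x_comb,
                    "pop_asymmetry_degree": abs(pct_a - pct_b),
                }
            )
    db = ResponseDatabase(records, provenance=f"synthetic seed={cfg.seed}")
    return db, pd.DataFrame(truth_rows)


def truth_recovery_report(
    truth: pd.DataFrame, classifications: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Confusion matrix of true regime vs selected best model.

    Returns ``(confusion, accuracy)``: the cross-tabulated counts, and the
    per-regime fraction of records whose best model names the generating
    regime (defined for the three regimes that are null models; the
    'reversal' regime has no matching model and reports NaN).
    """
    merged = truth.merge(
        classifications[["study_id", "response_id", "best_model"]],
        on=["study_id", "response_id"],
        validate="one_to_one",
    )
    confusion = pd.crosstab(merged["true_regime"], merged["best_model"])
    acc = {}
    for regime, sub in merged.groupby("true_regime"):
        if regime in ("additive", "multiplicative", "dominance"):
            acc[regime] = float((sub["best_model"] == regime).mean())
        else:
            acc[regime] = math.nan
    return confusion, pd.Series(acc, name="recovery_fraction")
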