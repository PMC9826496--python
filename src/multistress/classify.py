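"""Per-record interaction classification and frequency summaries.

Each record is classified by (i) whether its observed combined response falls
within the closed interval spanned by the three null predictions, below it,
or above it; (ii) which null model predicts it best (smallest |Hedges' d|,
with near-ties declared 'undefined'); and (iii) the degree of asymmetry
between the two single-stressor effects,

    degree = | (S_A - C)/C * 100  -  (S_B - C)/C * 100 |,

with a pair called asymmetric when one stressor's independent effect exceeds
the other's by more than 50 percentage points (on absolute percent effects);
the larger-|effect| arm is the prevailing stressor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .database import ExperimentRecord, ResponseDatabase
from .effects import EffectSize, compute_effects
from .nullmodels import MODELS, NullPredictionSet, predict_all

DEFAULT_ASYMMETRY_THRESHOLD = 50.0
DEFAULT_BEST_MODEL_TIE_TOL = 1e-6


@dataclass(frozen=True)
class AsymmetryResult:
    """Percent effects of the two stressors and their imbalance."""

    pct_effect_temp: float
    pct_effect_b: float
    degree: float
    prevailing: str  # 'temperature' | 'stressor_b' | 'none'
    asymmetric: bool
    defined: bool = True
    undefined_reason: Optional[str] = None


@dataclass(frozen=True)
class ClassificationResult:
    """Full per-record classification."""

    range_position: str  # 'within' | 'below' | 'above' | 'unclassifiable'
    best_model: str  # model name | 'undefined' | 'unclassifiable'
    asymmetry: AsymmetryResult
    deviations: dict  # model -> |d| (or raw |x_o - x_p| fallback)


def classify_range(observed: float, predictions: NullPredictionSet) -> str:
    """Position of the observed mean relative to the null-prediction range.

    The range is the closed interval between the lowest and highest defined
    predictions; undefined models are excluded.  Returns 'unclassifiable'
    when no prediction is defined.
    """
    xs = [p.x_p for p in predictions.defined().values()]
    if not xs:
        return "unclassifiable"
    lo, hi = min(xs), max(xs)
    if observed < lo:
        return "below"
    if observed > hi:
        return "above"
    return "within"


def select_best_model(
    effects: dict[str, EffectSize],
    tie_tol: float = DEFAULT_BEST_MODEL_TIE_TOL,
    predictions: NullPredictionSet | None = None,
    observed: float | None = None,
) -> tuple[str, dict]:
    """Model with the smallest |d|; 'undefined' when the top two tie.

    When every d is undefined because the pooled SD is zero (noise-free
    data), the ranking falls back to the raw deviation |x_o - x_p|, which
    orders models identically since all three share one (s_p, n_p).
    Outlier-flagged effects remain eligible: best-model selection feeds the
    frequency summaries, from which outliers are not excluded.

    Returns ``(best_model, deviations)``.
    """
    scores = {m: abs(e.d) for m, e in effects.items() if e.defined}
    if not scores and predictions is not None and observed is not None:
        zero_sd = any(
            e.undefined_reason == "zero pooled SD" for e in effects.values()
        )
        if zero_sd:
            scores = {
                m: abs(observed - p.x_p)
                for m, p in predictions.defined().items()
            }
    if not scores:
        return "unclassifiable", {}
    ranked = sorted(scores.items(), key=lambda kv: kv[1])
    if len(ranked) > 1 and ranked[1][1] - ranked[0][1] <= tie_tol:
        return "undefined", scores
    return ranked[0][0], scores


def degree_of_asymmetry(
    c: float,
    sa: float,
    sb: float,
    threshold: float = DEFAULT_ASYMMETRY_THRESHOLD,
) -> AsymmetryResult:
    """Imbalance between the two stressors' percent effects relative to control.

    ``degree`` is the absolute difference of the signed percent effects.  The
    asymmetry flag fires when the absolute percent effects differ by more
    than ``threshold`` percentage points; the prevailing stressor is the arm
    with the larger absolute percent effect (so a strong negative effect can
    prevail over a weak positive one).
    """
    if c == 0:
        return AsymmetryResult(
            math.nan, math.nan, math.nan, "none", False,
            defined=False, undefined_reason="control mean is zero",
        )
    pct_a = (sa - c) / c * 100.0
    pct_b = (sb - c) / c * 100.0
    degree = abs(pct_a - pct_b)
    asymmetric = abs(abs(pct_a) - abs(pct_b)) > threshold
    if asymmetric:
        prevailing = "temperature" if abs(pct_a) > abs(pct_b) else "stressor_b"
    else:
        prevailing = "none"
    return AsymmetryResult(pct_a, pct_b, degree, prevailing, asymmetric)


def classify_record(
    record: ExperimentRecord,
    predictions: NullPredictionSet | None = None,
    effects: dict[str, EffectSize] | None = None,
    tie_tol: float = DEFAULT_BEST_MODEL_TIE_TOL,
    asymmetry_threshold: float = DEFAULT_ASYMMETRY_THRESHOLD,
) -> ClassificationResult:
    """Classify one record (range position, best model, asymmetry)."""
    if predictions is None:
        predictions = predict_all(record)
    if effects is None:
        effects = compute_effects(record, predictions)
    observed = record.combined.mean
    best, scores = select_best_model(
        effects, tie_tol, predictions=predictions, observed=observed
    )
    return ClassificationResult(
        range_position=classify_range(observed, predictions),
        best_model=best,
        asymmetry=degree_of_asymmetry(
            record.control.mean,
            record.temp_alone.mean,
            record.stressorB_alone.mean,
            asymmetry_threshold,
        ),
        deviations=scores,
    )


def asymmetry_category(record: ExperimentRecord, asym: AsymmetryResult) -> str:
    """Grouping label: 'symmetric', 'temperature', or the prevailing B type."""
    if not asym.defined or not asym.asymmetric:
        return "symmetric"
    if asym.prevailing == "temperature":
        return "temperature"
    return record.stressor_b_type


def classify_database(
    db: ResponseDatabase,
    tie_tol: float = DEFAULT_BEST_MODEL_TIE_TOL,
    asymmetry_threshold: float = DEFAULT_ASYMMETRY_THRESHOLD,
    pred_tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """One classification row per record."""
    rows = []
    for rec in db:
        preds = predict_all(rec, pred_tie_tol)
        effs = compute_effects(rec, preds)
        cr = classify_record(rec, preds, effs, tie_tol, asymmetry_threshold)
        rows.append(
            {
                "study_id": rec.study_id,
                "response_id": rec.response_id,
                "stressor_b_type": rec.stressor_b_type,
                "organisation_level": rec.organisation_level,
                "organism_group": rec.organism_group,
                "response_metric": rec.response_metric,
                "range_position": cr.range_position,
                "best_model": cr.best_model,
                "pct_effect_temp": cr.asymmetry.pct_effect_temp,
                "pct_effect_b": cr.asymmetry.pct_effect_b,
                "asymmetry_degree": cr.asymmetry.degree,
                "prevailing": cr.asymmetry.prevailing,
                "asymmetric": cr.asymmetry.asymmetric,
                "asymmetry_category": asymmetry_category(rec, cr.asymmetry),
                "dominant_stressor": preds.dominance.dominant_stressor,
            }
        )
    return pd.DataFrame(rows)


def frequency_table(
    classifications: pd.DataFrame, grouping: str, min_n: int = 8
) -> pd.DataFrame:
    """Per-level percentages of range positions and best models.

    Levels with fewer than ``min_n`` classified records are excluded.
    Percentages are computed over the classified records in each level and
    sum to 100 within each family (range positions; best models).
    """
    if grouping not in classifications.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    rows = []
    for level, sub in classifications.groupby(grouping, sort=True):
        n = len(sub)
        if n < min_n:
            continue
        row = {"grouping": grouping, "level": level, "n": n}
        for pos in ("within", "below", "above"):
            row[f"pct_{pos}"] = (sub["range_position"] == pos).sum() / n * 100.0
        for model in (*MODELS, "undefined"):
            row[f"pct_best_{model}"] = (sub["best_model"] == model).sum() / n * 100.0
        rows.append(row)
    return pd.DataFrame(rows)
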