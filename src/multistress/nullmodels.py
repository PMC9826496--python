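"""Null-model predictions of the combined two-stressor response.

Three contrasting null models predict the combined response X_p from the
single-stressor responses S_A (temperature), S_B and the control C, assuming
no interaction:

* additive       X_p = S_A + S_B - C          (effects add on the raw scale)
* multiplicative X_p = S_A * S_B / C          (proportional effects multiply)
* dominance      X_p = S_A if |S_A-C| > |S_B-C| else S_B
                                              (the stronger stressor masks
                                               the weaker one)

For response metrics that cannot be negative (abundance, biomass, diversity,
survival, decomposition) a negative additive prediction is replaced with
zero.  All three predictions for one record share a single pooled standard
deviation s_p (pooling the two single-stressor arms) and a prediction sample
size n_p = min of the two single-stressor replicate counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .database import (
    NON_NEGATIVE_METRICS,
    ExperimentRecord,
    ResponseDatabase,
    TreatmentSummary,
)

MODELS = ("additive", "multiplicative", "dominance")

DEFAULT_TIE_TOL = 1e-9


class UndefinedPredictionError(ValueError):
    """A null model is undefined for the given inputs (e.g. C = 0)."""


class DegenerateVarianceError(ValueError):
    """Pooling is undefined because n_a + n_b <= 2."""


@dataclass(frozen=True)
class NullPrediction:
    """One model's predicted combined response with pooled uncertainty."""

    model: str
    x_p: float
    s_p: float
    n_p: int
    clamped: bool = False
    dominant_stressor: Optional[str] = None
    defined: bool = True
    undefined_reason: Optional[str] = None


@dataclass(frozen=True)
class NullPredictionSet:
    """The three null predictions for one record."""

    record: ExperimentRecord
    additive: NullPrediction
    multiplicative: NullPrediction
    dominance: NullPrediction

    def __getitem__(self, model: str) -> NullPrediction:
        if model not in MODELS:
            raise KeyError(model)
        return getattr(self, model)

    def defined(self) -> dict[str, NullPrediction]:
        return {m: self[m] for m in MODELS if self[m].defined}


def predict_additive(
    c: float, sa: float, sb: float, metric: str | None = None
) -> tuple[float, bool]:
    """Additive prediction ``sa + sb - c``; clamped at zero for non-negative metrics.

    Returns ``(x_p, clamped)``.
    """
    for v in (c, sa, sb):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    x = sa + sb - c
    if metric in NON_NEGATIVE_METRICS and x < 0:
        return 0.0, True
    return x, False


def predict_multiplicative(c: float, sa: float, sb: float) -> float:
    """Multiplicative prediction ``sa * sb / c``; undefined when c = 0."""
    for v in (c, sa, sb):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    if c == 0:
        raise UndefinedPredictionError("multiplicative prediction undefined for c = 0")
    return sa * sb / c


def predict_dominance(
    c: float, sa: float, sb: float, tie_tol: float = DEFAULT_TIE_TOL
) -> tuple[float, str]:
    """Dominance prediction: the single-stressor arm deviating more from control.

    The value follows the strict rule (``sa`` iff ``|sa-c| > |sb-c|``, else
    ``sb``); ``tie_tol`` is a relative tolerance that only labels near-ties,
    returning ``dominant_stressor='tie'`` while keeping the strict value.

    Returns ``(x_p, dominant_stressor)`` with dominant_stressor in
    {'temperature', 'stressor_b', 'tie'}.
    """
    for v in (c, sa, sb):
        if not math.isfinite(v):
            raise ValueError("inputs must be finite")
    da, db_ = abs(sa - c), abs(sb - c)
    value = sa if da > db_ else sb
    scale = max(da, db_)
    if abs(da - db_) <= tie_tol * scale or da == db_:
        return value, "tie"
    return value, ("temperature" if da > db_ else "stressor_b")


def pooled_prediction_uncertainty(
    arm_a: TreatmentSummary, arm_b: TreatmentSummary
) -> tuple[float, int]:
    """Pooled SD and sample size of the predicted response.

    s_p pools the two single-stressor arm SDs with (n-1) weights; n_p is the
    minimum of the two single-stressor replicate counts.
    """
    na, nb = arm_a.n, arm_b.n
    if na + nb <= 2:
        raise DegenerateVarianceError(
            f"pooling undefined for n_a + n_b = {na + nb} <= 2"
        )
    s_p = math.sqrt(
        ((na - 1) * arm_a.sd**2 + (nb - 1) * arm_b.sd**2) / (na + nb - 2)
    )
    return s_p, min(na, nb)


def predict_all(
    record: ExperimentRecord, tie_tol: float = DEFAULT_TIE_TOL
) -> NullPredictionSet:
    """Compute all three null predictions for one record.

    Per-model undefined cases (multiplicative with a zero control) are
    returned as flagged predictions rather than raised, so one undefined
    model never drops a record from the others.
    """
    c = record.control.mean
    sa = record.temp_alone.mean
    sb = record.stressorB_alone.mean
    s_p, n_p = pooled_prediction_uncertainty(record.temp_alone, record.stressorB_alone)

    x_add, clamped = predict_additive(c, sa, sb, record.response_metric)
    additive = NullPrediction("additive", x_add, s_p, n_p, clamped=clamped)

    try:
        x_mult = predict_multiplicative(c, sa, sb)
        multiplicative = NullPrediction("multiplicative", x_mult, s_p, n_p)
    except UndefinedPredictionError as exc:
        multiplicative = NullPrediction(
            "multiplicative", math.nan, s_p, n_p, defined=False,
            undefined_reason=str(exc),
        )

    x_dom, dominant = predict_dominance(c, sa, sb, tie_tol)
    dominance = NullPrediction(
        "dominance", x_dom, s_p, n_p, dominant_stressor=dominant
    )
    return NullPredictionSet(record, additive, multiplicative, dominance)


def predictions_frame(
    db: ResponseDatabase, tie_tol: float = DEFAULT_TIE_TOL
) -> pd.DataFrame:
    """Database table augmented with the three predictions per record."""
    base = db.to_frame()
    extra = []
    for rec in db:
        ps = predict_all(rec, tie_tol)
        extra.append(
            {
                "pred_additive": ps.additive.x_p,
                "pred_multiplicative": ps.multiplicative.x_p,
                "pred_dominance": ps.dominance.x_p,
                "pred_sd": ps.additive.s_p,
                "pred_n": ps.additive.n_p,
                "clamped": ps.additive.clamped,
                "dominant_stressor": ps.dominance.dominant_stressor,
            }
        )
    return pd.concat([base, pd.DataFrame(extra)], axis=1)
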