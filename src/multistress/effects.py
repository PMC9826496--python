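"""Hedges' d effect sizes between observed and null-predicted combined responses.

The standardised mean difference

    d = J * (X_o - X_p) / s

compares the observed combined response X_o with each null prediction X_p,
where s pools the observed-arm SD with the prediction SD and J corrects for
small-sample bias,

    J   = 1 - 3 / (4 (n_o + n_p - 2) - 1)
    s   = sqrt( ((n_o-1) s_o^2 + (n_p-1) s_p^2) / (n_o + n_p - 2) )
    V_d = (n_o + n_p) / (n_o n_p) + d^2 / (2 (n_o + n_p)).

When a model's predicted effect is negative relative to the control the sign
of d is inverted, so that a negative d uniformly means "observed effect
smaller in magnitude than predicted" (antagonistic) and a positive d means
larger, irrespective of the direction of the underlying response.  Effects
with |d| > 30 are flagged as outliers and excluded from the quantitative
meta-analysis (but retained in frequency counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .database import ExperimentRecord, ResponseDatabase
from .nullmodels import MODELS, NullPredictionSet, predict_all

DEFAULT_OUTLIER_THRESHOLD = 30.0


class DegenerateSampleError(ValueError):
    """Hedges machinery undefined because n_o + n_p <= 2."""


@dataclass(frozen=True)
class EffectSize:
    """Hedges' d for one (record, null model) pair."""

    model: str
    d: float
    v_d: float
    j: float
    s_pooled: float
    inverted: bool = False
    outlier: bool = False
    defined: bool = True
    undefined_reason: Optional[str] = None


def small_sample_correction(n_o: int, n_p: int) -> float:
    """Small-sample bias correction factor J; strictly increasing to 1."""
    if n_o + n_p <= 2:
        raise DegenerateSampleError(f"J undefined for n_o + n_p = {n_o + n_p} <= 2")
    return 1.0 - 3.0 / (4.0 * (n_o + n_p - 2) - 1.0)


def pooled_sd(n_o: int, s_o: float, n_p: int, s_p: float) -> float:
    """Pooled standard deviation of observed and predicted responses."""
    if n_o + n_p <= 2:
        raise DegenerateSampleError(f"pooling undefined for n_o + n_p <= 2")
    if s_o < 0 or s_p < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.sqrt(((n_o - 1) * s_o**2 + (n_p - 1) * s_p**2) / (n_o + n_p - 2))


def hedges_d(
    x_o: float,
    x_p: float,
    n_o: int,
    s_o: float,
    n_p: int,
    s_p: float,
    j: float | None = None,
) -> tuple[float, float]:
    """Hedges' d and its sampling variance V_d.

    Passing ``j=1.0`` yields the uncorrected Cohen's d.

    Raises
    ------
    ZeroDivisionError
        If the pooled SD is zero (both arms variance-free); callers flag the
        effect as undefined instead of substituting a finite value.
    """
    s = pooled_sd(n_o, s_o, n_p, s_p)
    if s == 0:
        raise ZeroDivisionError("pooled SD is zero; d undefined")
    if j is None:
        j = small_sample_correction(n_o, n_p)
    d = j * (x_o - x_p) / s
    v_d = (n_o + n_p) / (n_o * n_p) + d**2 / (2 * (n_o + n_p))
    return d, v_d


def apply_direction_inversion(d: float, x_p: float, c: float) -> tuple[float, bool]:
    """Invert d's sign when the predicted effect is negative relative to control.

    A predicted effect of exactly zero (x_p == c) is treated as not negative
    and left unchanged.  Returns ``(d, inverted)``.
    """
    if x_p < c:
        return -d, True
    return d, False


def compute_effects(
    record: ExperimentRecord,
    predictions: NullPredictionSet | None = None,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> dict[str, EffectSize]:
    """Hedges' d of observed vs each null prediction for one record.

    The inversion rule is keyed on each model's own predicted effect sign.
    Undefined models (zero control for multiplicative, zero pooled SD) yield
    flagged EffectSize entries with ``defined=False``.
    """
    if predictions is None:
        predictions = predict_all(record)
    obs = record.combined
    c = record.control.mean
    out: dict[str, EffectSize] = {}
    for model in MODELS:
        pred = predictions[model]
        if not pred.defined:
            out[model] = EffectSize(
                model, math.nan, math.nan, math.nan, math.nan,
                defined=False, undefined_reason=pred.undefined_reason,
            )
            continue
        j = small_sample_correction(obs.n, pred.n_p)
        s = pooled_sd(obs.n, obs.sd, pred.n_p, pred.s_p)
        if s == 0:
            out[model] = EffectSize(
                model, math.nan, math.nan, j, 0.0,
                defined=False, undefined_reason="zero pooled SD",
            )
            continue
        d, v_d = hedges_d(obs.mean, pred.x_p, obs.n, obs.sd, pred.n_p, pred.s_p, j=j)
        d, inverted = apply_direction_inversion(d, pred.x_p, c)
        out[model] = EffectSize(
            model, d, v_d, j, s,
            inverted=inverted, outlier=abs(d) > outlier_threshold,
        )
    return out


def flag_outliers(
    effects: Iterable[EffectSize], threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> list[EffectSize]:
    """Re-flag a collection of effects at a given |d| cutoff.

    The flag is exclusive of the boundary: |d| must exceed the threshold.
    """
    return [
        replace(e, outlier=e.defined and abs(e.d) > threshold) for e in effects
    ]


def effects_frame(
    db: ResponseDatabase,
    tie_tol: float = 1e-9,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> pd.DataFrame:
    """Long-format effect-size table: one row per (record, model).

    Columns: study_id, response_id, model, d, v_d, j, s_pooled, inverted,
    outlier, undefined_reason, plus the record's categorical metadata.
    """
    rows = []
    for rec in db:
        preds = predict_all(rec, tie_tol)
        effs = compute_effects(rec, preds, outlier_threshold)
        for model in MODELS:
            e = effs[model]
            rows.append(
                {
                    "study_id": rec.study_id,
                    "response_id": rec.response_id,
                    "stressor_b_type": rec.stressor_b_type,
                    "organisation_level": rec.organisation_level,
                    "organism_group": rec.organism_group,
                    "response_metric": rec.response_metric,
                    "model": model,
                    "d": e.d,
                    "v_d": e.v_d,
                    "j": e.j,
                    "s_pooled": e.s_pooled,
                    "inverted": e.inverted,
                    "outlier": e.outlier,
                    "defined": e.defined,
                    "undefined_reason": e.undefined_reason,
                }
            )
    return pd.DataFrame(rows)
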