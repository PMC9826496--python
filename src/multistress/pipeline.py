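"""End-to-end analysis orchestration: predict, classify, effect sizes,
meta-analysis, asymmetry regression, and artifact output."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import effects as _effects
from . import meta as _meta
from . import nullmodels as _null
from .database import ResponseDatabase, read_database

DEFAULT_GROUPINGS = ("stressor_b_type", "organisation_level", "asymmetry_category")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and paths governing one full analysis run."""

    input_path: str = ""
    output_dir: str = "multistress_run"
    pred_tie_tol: float = 1e-9
    best_model_tie_tol: float = 1e-6
    asymmetry_threshold: float = 50.0
    outlier_threshold: float = 30.0
    min_group_size: int = 8
    epsilon: float = 1e-9
    groupings: tuple = DEFAULT_GROUPINGS
    seed: int = 0

    def __post_init__(self):
        for name in ("asymmetry_threshold", "outlier_threshold", "min_group_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "groupings" in data:
            data["groupings"] = tuple(data["groupings"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groupings"] = list(d["groupings"])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending detail."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")


def _meta_table(effects: pd.DataFrame, moderator_col, cfg) -> Optional[dict]:
    """Fit one multilevel meta-analysis, returning its JSON-able summary."""
    usable = effects[effects["defined"] & ~effects["outlier"]].copy()
    dropped_small = 0
    if moderator_col is not None:
        counts = usable[moderator_col].value_counts()
        keep = counts[counts >= cfg.min_group_size].index
        dropped_small = int(len(usable) - usable[moderator_col].isin(keep).sum())
        usable = usable[usable[moderator_col].isin(keep)]
    if len(usable) == 0:
        return None
    try:
        res = _meta.fit_multilevel_meta(usable, moderator_col)
    except (_meta.UnderdeterminedError, _meta.ConvergenceError) as exc:
        return {"error": str(exc), "k": int(len(usable))}
    out = res.to_dict()
    out["dropped_small_groups"] = dropped_small
    out["level_table"] = json.loads(res.level_table().to_json(orient="index"))
    return out


def run_full_analysis(
    cfg: RunConfig, db: ResponseDatabase | None = None
) -> dict[str, Path]:
    """Run the complete analysis and write all artifacts.

    Artifacts (under ``cfg.output_dir``): predictions.csv, effects.csv,
    classification.csv, frequency_<grouping>.csv per grouping plus an
    all-responses row, meta_fits.json (per model x grouping), asymmetry_glm.json
    (per model x prevailing subset), and run_log.json with the config echo
    and record-exclusion accounting.

    Returns a mapping of artifact names to paths.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if db is None:
        try:
            db = read_database(cfg.input_path)
        except Exception as exc:
            raise StageError("read_database", str(exc)) from exc
    n_input = len(db)

    try:
        preds = _null.predictions_frame(db, cfg.pred_tie_tol)
    except Exception as exc:
        raise StageError("predict", str(exc)) from exc
    artifacts["predictions"] = outdir / "predictions.csv"
    preds.to_csv(artifacts["predictions"], index=False)

    try:
        eff = _effects.effects_frame(db, cfg.pred_tie_tol, cfg.outlier_threshold)
    except Exception as exc:
        raise StageError("effects", str(exc)) from exc
    artifacts["effects"] = outdir / "effects.csv"
    eff.to_csv(artifacts["effects"], index=False)

    try:
        cls = _classify.classify_database(
            db, cfg.best_model_tie_tol, cfg.asymmetry_threshold, cfg.pred_tie_tol
        )
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    artifacts["classification"] = outdir / "classification.csv"
    cls.to_csv(artifacts["classification"], index=False)

    # Frequency tables: per grouping, plus a single all-responses table.
    all_tab = cls.assign(_all="all_responses")
    freq_all = _classify.frequency_table(all_tab, "_all", min_n=1)
    artifacts["frequency_all"] = outdir / "frequency_all.csv"
    freq_all.to_csv(artifacts["frequency_all"], index=False)
    for grouping in cfg.groupings:
        tab = _classify.frequency_table(cls, grouping, cfg.min_group_size)
        key = f"frequency_{grouping}"
        artifacts[key] = outdir / f"{key}.csv"
        tab.to_csv(artifacts[key], index=False)

    # Meta-analysis: merge the classification's asymmetry category onto the
    # effect table so it is available as a moderator.
    eff_m = eff.merge(
        cls[["study_id", "response_id", "asymmetry_category", "prevailing",
             "asymmetry_degree", "asymmetric"]],
        on=["study_id", "response_id"],
    )
    meta_fits: dict = {}
    for model in _null.MODELS:
        sub = eff_m[eff_m["model"] == model]
        meta_fits[model] = {"overall": _meta_table(sub, None, cfg)}
        for grouping in cfg.groupings:
            meta_fits[model][grouping] = _meta_table(sub, grouping, cfg)
    artifacts["meta_fits"] = outdir / "meta_fits.json"
    artifacts["meta_fits"].write_text(json.dumps(meta_fits, indent=2, default=str))

    # Asymmetry-accuracy Gamma GLMs, per model and prevailing subset.
    glm_fits: dict = {}
    asym = eff_m[eff_m["defined"] & ~eff_m["outlier"] & eff_m["asymmetric"]]
    for model in _null.MODELS:
        glm_fits[model] = {}
        for subset, label in (("temperature", "temperature"), ("other", "stressor_b")):
            rows = asym[(asym["model"] == model) & (asym["prevailing"] == label)]
            if len(rows) < 3:
                glm_fits[model][subset] = {"error": "fewer than 3 observations",
                                           "n": int(len(rows))}
                continue
            y = rows["d"].abs().to_numpy()
            x = rows["asymmetry_degree"].to_numpy()
            try:
                epsilon_all = bool((y == 0).any())  # zeros force the constant
                res = _meta.fit_gamma_glm(
                    y, x, subset=subset, epsilon=cfg.epsilon,
                    epsilon_all=epsilon_all,
                )
                out = res.to_dict()
                out["epsilon_applied"] = epsilon_all or subset == "temperature"
                glm_fits[model][subset] = out
            except (ValueError, _meta.ConvergenceError) as exc:
                glm_fits[model][subset] = {"error": str(exc), "n": int(len(rows))}
    artifacts["asymmetry_glm"] = outdir / "asymmetry_glm.json"
    artifacts["asymmetry_glm"].write_text(json.dumps(glm_fits, indent=2))

    # Exclusion accounting: every record lands in exactly one bin.
    n_unclassifiable = int((cls["best_model"] == "unclassifiable").sum())
    accounting = {
        "n_input": n_input,
        "n_classified": n_input - n_unclassifiable,
        "n_unclassifiable": n_unclassifiable,
        "n_undefined_effects": {
            m: int((~eff[eff["model"] == m]["defined"]).sum()) for m in _null.MODELS
        },
        "n_outlier_effects": {
            m: int(eff[eff["model"] == m]["outlier"].sum()) for m in _null.MODELS
        },
    }
    log = {"config": cfg.to_dict(), "accounting": accounting}
    artifacts["run_log"] = outdir / "run_log.json"
    artifacts["run_log"].write_text(json.dumps(log, indent=2))
    return artifacts
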