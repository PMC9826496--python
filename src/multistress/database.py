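"""Data model, CSV I/O and validation for factorial two-stressor experiment summaries.

A database row describes one biological response measured under a fully
factorial design: an unstressed control, warming alone, a second stressor
alone, and both stressors combined.  Each treatment arm is summarised by its
mean, standard deviation and replicate count; categorical metadata identify
the source study, the second stressor, the level of biological organisation
and the response metric.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

STRESSOR_B_TYPES = frozenset(
    {
        "acidification",
        "contamination",
        "food_quantity",
        "habitat_alteration",
        "invasion",
        "light",
        "nutrients",
        "salinity",
        "oxygen",
    }
)
ORGANISATION_LEVELS = frozenset({"individual", "population", "community"})
RESPONSE_METRICS = frozenset(
    {
        "abundance",
        "biomass",
        "condition",
        "diversity",
        "growth_size",
        "survival",
        "decomposition",
    }
)

#: Metrics that cannot take negative values (no such thing as negative
#: abundance); the additive null prediction is clamped at zero for these.
NON_NEGATIVE_METRICS = frozenset(
    {"abundance", "biomass", "diversity", "survival", "decomposition"}
)

#: Categorical record fields usable as grouping variables.
CATEGORICAL_FIELDS = (
    "study_id",
    "response_id",
    "stressor_b_type",
    "organisation_level",
    "organism_group",
    "response_metric",
)

#: Fixed wide-format column schema of the database CSV.
COLUMNS = list(CATEGORICAL_FIELDS) + [
    f"{arm}_{stat}"
    for arm in ("ctrl", "ta", "tb", "tab")
    for stat in ("mean", "sd", "n")
]

_ARM_ATTR = {
    "ctrl": "control",
    "ta": "temp_alone",
    "tb": "stressorB_alone",
    "tab": "combined",
}


class SchemaError(ValueError):
    """The CSV header does not match the documented column schema."""


class DatabaseValidationError(ValueError):
    """One or more rows violate a field invariant.

    Attributes
    ----------
    errors : list of (row, field, message)
        Row numbers are 0-based positions in the data (header excluded).
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}, field '{f}': {m}" for r, f, m in self.errors)
        super().__init__(f"{len(self.errors)} invalid value(s): {lines}")


@dataclass(frozen=True)
class TreatmentSummary:
    """Summary statistics of one treatment arm."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if not math.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValueError("sd must be finite and >= 0")
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be an integer >= 1")
        object.__setattr__(self, "mean", float(self.mean))
        object.__setattr__(self, "sd", float(self.sd))
        object.__setattr__(self, "n", int(self.n))


@dataclass(frozen=True)
class ExperimentRecord:
    """One factorial response: four treatment summaries plus metadata.

    Stressor A is always temperature (warming); ``stressor_b_type`` names the
    second stressor applied alongside it.
    """

    study_id: str
    response_id: str
    stressor_b_type: str
    organisation_level: str
    organism_group: str
    response_metric: str
    control: TreatmentSummary
    temp_alone: TreatmentSummary
    stressorB_alone: TreatmentSummary
    combined: TreatmentSummary

    def __post_init__(self):
        if self.stressor_b_type not in STRESSOR_B_TYPES:
            raise ValueError(
                f"unknown stressor_b_type {self.stressor_b_type!r}; "
                f"permitted: {sorted(STRESSOR_B_TYPES)}"
            )
        if self.organisation_level not in ORGANISATION_LEVELS:
            raise ValueError(
                f"unknown organisation_level {self.organisation_level!r}; "
                f"permitted: {sorted(ORGANISATION_LEVELS)}"
            )
        if self.response_metric not in RESPONSE_METRICS:
            raise ValueError(
                f"unknown response_metric {self.response_metric!r}; "
                f"permitted: {sorted(RESPONSE_METRICS)}"
            )

    @property
    def is_non_negative_metric(self) -> bool:
        return self.response_metric in NON_NEGATIVE_METRICS


@dataclass
class ResponseDatabase:
    """Ordered collection of :class:`ExperimentRecord` with provenance note."""

    records: list[ExperimentRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        keys = [(r.study_id, r.response_id) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (study_id, response_id) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExperimentRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Return the database as a wide-format DataFrame (schema columns)."""
        rows = []
        for rec in self.records:
            row = {f: getattr(rec, f) for f in CATEGORICAL_FIELDS}
            for col_arm, attr in _ARM_ATTR.items():
                ts = getattr(rec, attr)
                row[f"{col_arm}_mean"] = ts.mean
                row[f"{col_arm}_sd"] = ts.sd
                row[f"{col_arm}_n"] = ts.n
            rows.append(row)
        return pd.DataFrame(rows, columns=COLUMNS)


def _record_from_row(row: pd.Series, i: int, errors: list) -> ExperimentRecord | None:
    arms = {}
    ok = True
    for col_arm, attr in _ARM_ATTR.items():
        vals = {}
        for stat in ("mean", "sd", "n"):
            col = f"{col_arm}_{stat}"
            raw = row[col]
            try:
                vals[stat] = int(raw) if stat == "n" else float(raw)
                if pd.isna(raw) or (stat != "n" and not math.isfinite(vals[stat])):
                    raise ValueError("missing or non-finite")
            except (TypeError, ValueError):
                errors.append((i, col, f"non-numeric or missing value {raw!r}"))
                ok = False
                continue
        if not ok:
            continue
        try:
            arms[attr] = TreatmentSummary(**vals)
        except ValueError as exc:
            errors.append((i, col_arm, str(exc)))
            ok = False
    if not ok:
        return None
    try:
        return ExperimentRecord(
            **{f: str(row[f]) for f in CATEGORICAL_FIELDS}, **arms
        )
    except ValueError as exc:
        errors.append((i, "categorical", str(exc)))
        return None


def read_database(path: str | Path, provenance: str | None = None) -> ResponseDatabase:
    """Read a response database from a CSV file.

    Parameters
    ----------
    path
        CSV file following the documented wide schema (see ``schema()``).
    provenance
        Optional free-text source note; defaults to the file path.

    Raises
    ------
    SchemaError
        If any required column is missing.
    DatabaseValidationError
        If any row fails validation; the error lists every (row, field).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    errors: list[tuple[int, str, str]] = []
    records = []
    for i, (_, row) in enumerate(df.iterrows()):
        rec = _record_from_row(row, i, errors)
        if rec is not None:
            records.append(rec)
    if errors:
        raise DatabaseValidationError(errors)
    return ResponseDatabase(records, provenance or str(path))


def write_database(db: ResponseDatabase, path: str | Path) -> None:
    """Write the database to CSV in the documented column order.

    Numeric fields are written with full float precision (repr round-trip).
    """
    db.to_frame().to_csv(path, index=False, float_format=None)


def filter_min_group_size(
    db: ResponseDatabase, grouping: str, min_n: int = 8
) -> ResponseDatabase:
    """Drop records whose level of ``grouping`` has fewer than ``min_n`` members.

    Groupings with fewer than eight responses are excluded from all grouped
    analyses; the default mirrors that rule.  Record order is preserved.
    """
    if grouping not in CATEGORICAL_FIELDS:
        raise ValueError(
            f"unknown grouping field {grouping!r}; permitted: {CATEGORICAL_FIELDS}"
        )
    counts: dict[str, int] = {}
    for rec in db:
        counts[getattr(rec, grouping)] = counts.get(getattr(rec, grouping), 0) + 1
    kept = [rec for rec in db if counts[getattr(rec, grouping)] >= min_n]
    return ResponseDatabase(kept, db.provenance)


def schema() -> dict:
    """Return the machine-readable JSON schema shipped with the package."""
    with resources.files("multistress").joinpath("schema.json").open() as fh:
        return json.load(fh)
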