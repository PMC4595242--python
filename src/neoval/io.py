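"""CSV/JSON input-output with strict schema validation.

All tables are comma-separated UTF-8 with a mandatory header row; booleans
are written ``true``/``false``.  Validation errors name the offending row
(1-based, excluding the header) and value.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd

from .causes import ASSIGNABLE, Cause
from .hierarchy import CaseRecord

PathLike = Union[str, Path]

CASE_COLUMNS = [
    "case_id",
    "age_at_death_days",
    "gestation_weeks",
    "sex",
    "birth_weight_g",
    "source",
]
ELIGIBILITY_COLUMNS = [f"elig_{c.value}" for c in ASSIGNABLE]
REVIEW_COLUMNS = ["case_id", "reviewer_id", "round", "cause"]
DIAGNOSIS_COLUMNS = ["case_id", "final_cause"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


class SchemaError(ValueError):
    """An input file failed schema validation."""


def _require_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _parse_bool(value: Any, row: int, column: str, path: PathLike) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE or text == "nan":
        return False
    raise SchemaError(f"{path}: row {row}, column {column}: bad boolean {value!r}")


def _check_unique_ids(df: pd.DataFrame, path: PathLike) -> None:
    dup = df["case_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise SchemaError(
            f"{path}: row {row}: duplicate case_id {df.loc[dup.idxmax(), 'case_id']!r}"
        )


def read_cases(path: PathLike) -> list[CaseRecord]:
    """Read case records (one row per deceased neonate) from CSV."""
    df = pd.read_csv(path, dtype={"case_id": str})
    _require_columns(df, CASE_COLUMNS, path)
    elig_cols = [c for c in df.columns if c.startswith("elig_")]
    for col in elig_cols:
        code = col[len("elig_") :]
        try:
            cause = Cause.parse(code)
        except ValueError:
            raise SchemaError(f"{path}: unknown cause in column {col!r}") from None
        if cause not in ASSIGNABLE:
            raise SchemaError(f"{path}: column {col!r} flags a non-assignable cause")
    _check_unique_ids(df, path)

    records: list[CaseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        gest = d["gestation_weeks"]
        gest = None if pd.isna(gest) else float(gest)
        bw = d["birth_weight_g"]
        bw = None if pd.isna(bw) else float(bw)
        eligibility = {
            Cause.parse(col[len("elig_") :]): _parse_bool(d[col], i, col, path)
            for col in elig_cols
        }
        try:
            records.append(
                CaseRecord(
                    case_id=str(d["case_id"]),
                    age_at_death_days=int(d["age_at_death_days"]),
                    gestation_weeks=gest,
                    sex=str(d["sex"]),
                    birth_weight_g=bw,
                    eligibility=eligibility,
                    source=str(d["source"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {i}: {exc}") from None
    return records


def write_cases(records_or_df, path: PathLike) -> None:
    """Write case records (list of CaseRecord or an equivalent DataFrame)."""
    if isinstance(records_or_df, pd.DataFrame):
        df = records_or_df.copy()
    else:
        rows = []
        for rec in records_or_df:
            row = {
                "case_id": rec.case_id,
                "age_at_death_days": rec.age_at_death_days,
                "gestation_weeks": rec.gestation_weeks,
                "sex": rec.sex,
                "birth_weight_g": rec.birth_weight_g,
                "source": rec.source,
            }
            row.update(
                {f"elig_{c.value}": rec.eligibility.get(c, False) for c in ASSIGNABLE}
            )
            rows.append(row)
        df = pd.DataFrame(rows, columns=CASE_COLUMNS + ELIGIBILITY_COLUMNS)
    for col in [c for c in df.columns if c.startswith("elig_")]:
        df[col] = df[col].map(lambda v: "true" if bool(v) else "false")
    df.to_csv(path, index=False)


def _validated_cause_column(df: pd.DataFrame, column: str, path: PathLike) -> None:
    for i, value in enumerate(df[column], start=1):
        try:
            Cause.parse(value)
        except ValueError:
            raise SchemaError(
                f"{path}: row {i}, column {column}: unknown cause {value!r}"
            ) from None


def read_reviews(path: PathLike) -> pd.DataFrame:
    """Read a long-format reviewer-assignment table from CSV."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, REVIEW_COLUMNS, path)
    bad = ~df["round"].isin(["primary", "arbiter"])
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise SchemaError(
            f"{path}: row {row}: bad round {df.loc[bad.idxmax(), 'round']!r} "
            "(expected primary or arbiter)"
        )
    _validated_cause_column(df, "cause", path)
    return df[REVIEW_COLUMNS]


def read_diagnoses(path: PathLike) -> pd.DataFrame:
    """Read an adjudicated-diagnosis table (case_id, final_cause[, resolution])."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, DIAGNOSIS_COLUMNS, path)
    _check_unique_ids(df, path)
    _validated_cause_column(df, "final_cause", path)
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_sim_config(path: PathLike, *, seed: Optional[int] = None):
    """Read a simulation config from YAML (or JSON, a YAML subset)."""
    import yaml

    from .simulate import ConfigError, config_from_dict

    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"{path}: not valid YAML/JSON: {exc}") from None
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    try:
        return config_from_dict(data, seed=seed)
    except ConfigError as exc:
        raise SchemaError(f"{path}: {exc}") from None


# --- report JSON -----------------------------------------------------------

#: Minimal JSON-schema-style description of the validation report.
REPORT_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": ["n_cases", "overall_agreement_pct", "csmf", "accuracy"],
    "properties": {
        "n_cases": {"type": "integer"},
        "overall_agreement_pct": {"type": "number"},
        "adjudication": {
            "type": "object",
            "properties": {
                "hospital": {"type": "object"},
                "verbal_autopsy": {"type": "object"},
            },
        },
        "csmf": {
            "type": "object",
            "required": ["reference", "va"],
            "properties": {
                "reference": {"type": "array"},
                "va": {"type": "array"},
            },
        },
        "accuracy": {"type": "array"},
    },
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA, where: str = "report") -> None:
    """Validate a report object against the (small) schema subset used here.

    Supports ``type`` (object/array/number/integer/string/boolean),
    ``required`` and per-property sub-schemas; raises ``SchemaError`` with the
    offending JSON path.
    """
    kind = schema.get("type")
    checks = {
        "object": dict,
        "array": list,
        "string": str,
        "boolean": bool,
        "integer": int,
        "number": (int, float),
    }
    if kind is not None:
        expected = checks[kind]
        ok = isinstance(report, expected)
        if kind in ("integer", "number") and isinstance(report, bool):
            ok = False
        if not ok:
            raise SchemaError(f"{where}: expected {kind}, got {type(report).__name__}")
    if kind == "object":
        for key in schema.get("required", []):
            if key not in report:
                raise SchemaError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{where}.{key}")


def write_report(report: dict, path: PathLike) -> None:
    validate_report(report)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def read_report(path: PathLike) -> dict:
    with open(path, encoding="utf-8") as fh:
        report = json.load(fh)
    validate_report(report)
    return report
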