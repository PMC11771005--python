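"""CSV readers/writers, typed record construction, and report rendering.

Interchange format: one row per patient, a mandatory header, column names
exactly matching the domain-type field names, booleans encoded 0/1 and
enumerations as lowercase tokens. ``time_to_complete_lc_min`` (unscored
pass-through) and ``bmi_intraop`` (a duplicate BMI column that must agree
with ``bmi``) are the only optional columns.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_THRESHOLDS, ScoreThresholds
from .scoring import binarize_intraop, binarize_preop, score_modified, score_preop, score_sugrue
from .types import (
    ADHESION_LEVELS,
    INJURY_LEVELS,
    INTRAOP_FIELDS,
    LIGATURE_LEVELS,
    PREOP_FIELDS,
    SCAR_LEVELS,
    SEX_LEVELS,
    IntraopFindings,
    PreopProfile,
    ValidationError,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "records_from_frame",
    "score_frame",
    "render_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"

_BOOL_COLUMNS = (
    "admission_history_acute_cholecystitis",
    "palpable_gb",
    "impacted_stone_imaging",
    "distended_or_contracted",
    "ungraspable_with_forceps",
    "stone_impacted_hartmann_ge_1cm",
    "adhesions_prev_surgery_limiting_access",
    "bile_or_pus_outside_gb",
    "bile_stone_spillage",
    "conversion_to_open",
)
_LEVEL_COLUMNS = {
    "sex": SEX_LEVELS,
    "abdominal_scar": SCAR_LEVELS,
    "adhesion_grade": ADHESION_LEVELS,
    "injury": INJURY_LEVELS,
    "ligature": LIGATURE_LEVELS,
}
_OPTIONAL_COLUMNS = ("time_to_complete_lc_min", "bmi_intraop")

_SCHEMAS = {
    "preop": PREOP_FIELDS,
    "intraop": INTRAOP_FIELDS,
    "both": PREOP_FIELDS + tuple(f for f in INTRAOP_FIELDS if f != "bmi"),
}


def _schema_columns(schema: str) -> tuple[str, ...]:
    try:
        return _SCHEMAS[schema]
    except KeyError:
        raise ValidationError(
            f"schema must be one of {tuple(_SCHEMAS)}, got {schema!r}"
        ) from None


def read_cohort(
    path: str | Path, schema: str = "both"
) -> pd.DataFrame:
    """Read and validate a patient cohort CSV.

    Returns a typed data frame (booleans as bool, numerics as float/int).
    The first invalid cell aborts the read with an error naming its
    1-based data row and column. When both ``bmi`` and ``bmi_intraop``
    are present, every row must agree.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=object, keep_default_na=False)
    expected = _schema_columns(schema)
    required = [c for c in expected if c != "time_to_complete_lc_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in expected and c not in _OPTIONAL_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    if df.empty:
        raise ValidationError(f"{path} contains a header but no rows")

    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        values = df[col].astype(str).str.strip()
        if col in _BOOL_COLUMNS:
            bad = ~values.isin(["0", "1"])
            _raise_first(bad, col, values, "booleans must be 0 or 1")
            out[col] = values == "1"
        elif col in _LEVEL_COLUMNS:
            levels = _LEVEL_COLUMNS[col]
            bad = ~values.isin(levels)
            _raise_first(bad, col, values, f"allowed levels are {levels}")
            out[col] = values.to_numpy(dtype=object)
        elif col == "age":
            num = pd.to_numeric(values, errors="coerce")
            bad = num.isna() | (num <= 0) | (num != num.round())
            _raise_first(bad, col, values, "age must be a positive integer")
            out[col] = num.astype(int)
        elif col in ("bmi", "bmi_intraop"):
            num = pd.to_numeric(values, errors="coerce")
            bad = num.isna() | (num <= 0)
            _raise_first(bad, col, values, "BMI must be a positive number")
            out[col] = num.astype(float)
        else:  # time columns; optional one may be blank
            blank = values == ""
            if col == "time_to_complete_lc_min":
                values = values.mask(blank, "nan")
            num = pd.to_numeric(values, errors="coerce")
            bad = (num.isna() & ~blank) | (num < 0)
            _raise_first(bad, col, values, "times must be non-negative minutes")
            out[col] = num.astype(float)

    if "bmi" in out.columns and "bmi_intraop" in out.columns:
        mismatch = ~np.isclose(out["bmi"], out["bmi_intraop"], atol=1e-9)
        if mismatch.any():
            row = int(np.argmax(mismatch)) + 1
            raise ValidationError(
                f"row {row}: preoperative bmi {out['bmi'].iloc[row - 1]} and "
                f"bmi_intraop {out['bmi_intraop'].iloc[row - 1]} disagree"
            )
        out = out.drop(columns=["bmi_intraop"])
    return out


def _raise_first(bad: pd.Series, col: str, values: pd.Series, rule: str) -> None:
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValidationError(
            f"row {i + 1}, column {col}: invalid value {values.iloc[i]!r} ({rule})"
        )


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort frame as interchange CSV (booleans as 0/1)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def records_from_frame(
    df: pd.DataFrame, schema: str = "both"
) -> list[tuple[PreopProfile | None, IntraopFindings | None]]:
    """Typed record pairs from a validated cohort frame.

    Row-level invariant violations are aggregated and reported together
    with their 1-based row numbers.
    """
    records: list[tuple[PreopProfile | None, IntraopFindings | None]] = []
    errors: list[str] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            preop = intra = None
            if schema in ("preop", "both"):
                preop = PreopProfile(**{f: row[f] for f in PREOP_FIELDS})
            if schema in ("intraop", "both"):
                kwargs = {f: row.get(f) for f in INTRAOP_FIELDS}
                t = kwargs.get("time_to_complete_lc_min")
                if t is None or (isinstance(t, float) and np.isnan(t)):
                    kwargs["time_to_complete_lc_min"] = None
                intra = IntraopFindings(**kwargs)
            records.append((preop, intra))
        except (ValidationError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("invalid records:\n" + "\n".join(errors))
    return records


def score_frame(
    df: pd.DataFrame,
    stage: str,
    system: str = "standard",
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Score every row of a cohort frame.

    ``stage`` is "preop" or "intraop"; for intraop, ``system`` picks the
    standard or the modified grade. Returns total, per-item breakdown
    (as "item=points;..." text), band and binary class per row.
    """
    if stage == "preop":
        results = [
            score_preop(p, thresholds)
            for p, _ in records_from_frame(df, schema="preop" if "adhesion_grade" not in df.columns else "both")
        ]
        binaries = [binarize_preop(r, thresholds.preop_difficult_min) for r in results]
    elif stage == "intraop":
        scorer = {"standard": score_sugrue, "modified": score_modified}.get(system)
        if scorer is None:
            raise ValidationError(f"system must be standard/modified, got {system!r}")
        results = [
            scorer(f, thresholds)
            for _, f in records_from_frame(df, schema="intraop" if "sex" not in df.columns else "both")
        ]
        binaries = [binarize_intraop(r, system) for r in results]
    else:
        raise ValidationError(f"stage must be preop/intraop, got {stage!r}")
    return pd.DataFrame(
        {
            "total": [r.total for r in results],
            "breakdown": [
                ";".join(f"{k}={v}" for k, v in r.breakdown) for r in results
            ],
            "band": [r.band for r in results],
            "binary": binaries,
        },
        index=df.index,
    )


def _round3(x) -> float | None:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), 3)


def render_report(metrics=None, roc=None, association=None) -> tuple[str, dict]:
    """Render a validation/association report as text plus a JSON-ready dict.

    At least one section must be provided. Numbers are rounded to 3
    decimals; field order is stable; the JSON schema carries a version tag.
    """
    if metrics is None and roc is None and association is None:
        raise ValidationError("nothing to report: all sections are empty")
    doc: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    lines: list[str] = []

    if metrics is not None:
        sec = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"):
            value = getattr(metrics, name)
            lo, hi = metrics.ci.get(name, (float("nan"), float("nan")))
            sec[name] = {
                "value": _round3(value),
                "ci95": [_round3(lo), _round3(hi)],
                "undefined": name in metrics.undefined,
            }
        doc["diagnostic_metrics"] = sec
        lines.append("Diagnostic metrics (value [95% CI])")
        for name, entry in sec.items():
            if entry["undefined"]:
                lines.append(f"  {name:<12} undefined (zero denominator)")
            else:
                lo, hi = entry["ci95"]
                lines.append(
                    f"  {name:<12} {entry['value']:.3f} [{lo:.3f}, {hi:.3f}]"
                )

    if roc is not None:
        from .validation import auc_band

        band = auc_band(roc.auc)
        doc["roc"] = {
            "auc": _round3(roc.auc),
            "auc_interpretation": band,
            "thresholds": [None if np.isinf(t) else t for t in roc.thresholds],
            "points": [[_round3(f), _round3(t)] for f, t in roc.points],
        }
        lines.append(f"ROC: AUC = {roc.auc:.3f} ({band})")

    if association is not None:
        tab = association.table.reset_index()
        doc["association"] = {
            "n_obs": association.n_obs,
            "converged": association.converged,
            "penalized": association.penalized,
            "factors": [
                {
                    "variable": str(r["variable"]),
                    "bivariate_p": _round3(r["bivariate_p"]),
                    "included": bool(r["included"]),
                    "aor": _round3(r["aor"]),
                    "ci95": [_round3(r["ci_low"]), _round3(r["ci_high"])],
                    "p_value": _round3(r["p_value"]),
                    "separation": bool(r["separation"]),
                }
                for r in tab.to_dict("records")
            ],
        }
        lines.append(f"Association (n={association.n_obs}):")
        for f in doc["association"]["factors"]:
            if not f["included"]:
                lines.append(f"  {f['variable']:<24} screened out")
                continue
            aor = f["aor"]
            lo, hi = f["ci95"]
            flag = "  [separation]" if f["separation"] else ""
            if aor is None:
                lines.append(f"  {f['variable']:<24} fit unavailable{flag}")
            elif lo is None:
                lines.append(f"  {f['variable']:<24} AOR {aor:<8.3g} (penalized){flag}")
            else:
                lines.append(
                    f"  {f['variable']:<24} AOR {aor:<8.3g} [{lo:.3g}, {hi:.3g}] "
                    f"p={f['p_value']:.3f}{flag}"
                )

    return "\n".join(lines), doc


def write_report_json(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
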