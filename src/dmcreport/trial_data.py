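"""Trial data model: subject-level safety tables, readers, and validation.

The pipeline operates on five subject-level tables shaped like the CDISC
ADaM analysis datasets a sponsor would hand to a DMC report producer:

* ``subjects``  (ADSL-like)  — one row per randomized subject,
* ``adverse_events`` (ADAE-like) — one row per reported adverse event,
* ``labs``      (ADLB-like)  — one row per laboratory measurement,
* ``exposure``  (ADEX-like)  — one row per dosing interval,
* ``conmeds`` / ``medhistory`` — optional, used only for patient profiles.

All temporal fields are *study days* under the CDISC convention: day 1 is
the day of first dose, there is no day 0, and days before first dose are
negative.  Readers accept either precomputed ``*_day`` columns or ISO-8601
date columns (converted against a per-subject first-dose date); precomputed
day columns win when both are present.

Tables are plain :class:`pandas.DataFrame` objects with canonical column
names; :class:`TrialData` bundles them with the arm declaration and the
data-cutoff day for the current DMC look.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMAS",
    "ALIASES",
    "TrialData",
    "ValidationIssue",
    "SchemaError",
    "IntegrityError",
    "read_table",
    "write_table",
    "assemble_trial",
    "validate_trial",
]


class SchemaError(ValueError):
    """A table's columns do not map onto the expected schema."""


class IntegrityError(ValueError):
    """A table violates a structural invariant (duplicates, bad ranges...)."""


# Canonical schema per table kind: column -> (dtype kind, required)
# dtype kinds: "str", "int", "float", "bool", "opt_int" (nullable Int64),
# "opt_float".
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "subjects": {
        "subject_id": ("str", True),
        "arm": ("str", True),
        "age": ("float", True),
        "sex": ("str", True),
        "race": ("str", False),
        "country": ("str", False),
        "first_dose_day": ("opt_int", False),
        "last_dose_day": ("opt_int", False),
        "randomized_flag": ("bool", False),
        "discontinued_flag": ("bool", False),
    },
    "adverse_events": {
        "subject_id": ("str", True),
        "preferred_term": ("str", True),
        "system_organ_class": ("str", True),
        "onset_day": ("int", True),
        "resolution_day": ("opt_int", False),
        "ctc_grade": ("int", True),
        "serious_flag": ("bool", True),
        "related_flag": ("bool", False),
        "discontinuation_flag": ("bool", False),
        "aesi_flag": ("bool", False),
    },
    "labs": {
        "subject_id": ("str", True),
        "param_code": ("str", True),
        "param_name": ("str", False),
        "visit_index": ("int", True),
        "visit_name": ("str", False),
        "day": ("int", True),
        "value": ("float", True),
        "unit": ("str", False),
        "lln": ("opt_float", False),
        "uln": ("opt_float", False),
        "baseline_flag": ("bool", False),
    },
    "exposure": {
        "subject_id": ("str", True),
        "start_day": ("int", True),
        "end_day": ("int", True),
        "dose_label": ("str", False),
    },
    "conmeds": {
        "subject_id": ("str", True),
        "term": ("str", True),
        "start_day": ("int", True),
        "end_day": ("opt_int", False),
        "ongoing_flag": ("bool", False),
    },
    "medhistory": {
        "subject_id": ("str", True),
        "term": ("str", True),
        "start_day": ("int", True),
        "end_day": ("opt_int", False),
        "ongoing_flag": ("bool", False),
    },
}

# Documented ADaM-style header aliases, matched case-insensitively.
ALIASES: dict[str, dict[str, str]] = {
    "subjects": {
        "usubjid": "subject_id",
        "subjid": "subject_id",
        "arm": "arm",
        "trt01p": "arm",
        "trt01a": "arm",
        "age": "age",
        "sex": "sex",
        "race": "race",
        "country": "country",
        "trtsdy": "first_dose_day",
        "trtedy": "last_dose_day",
        "randfl": "randomized_flag",
        "dcsreas_fl": "discontinued_flag",
        "dcutdy": "last_dose_day",
    },
    "adverse_events": {
        "usubjid": "subject_id",
        "aedecod": "preferred_term",
        "aebodsys": "system_organ_class",
        "astdy": "onset_day",
        "aendy": "resolution_day",
        "aetoxgr": "ctc_grade",
        "aeser": "serious_flag",
        "aerel": "related_flag",
        "aeacn_disc": "discontinuation_flag",
        "aesifl": "aesi_flag",
    },
    "labs": {
        "usubjid": "subject_id",
        "paramcd": "param_code",
        "param": "param_name",
        "avisitn": "visit_index",
        "avisit": "visit_name",
        "ady": "day",
        "aval": "value",
        "avalu": "unit",
        "anrlo": "lln",
        "anrhi": "uln",
        "ablfl": "baseline_flag",
    },
    "exposure": {
        "usubjid": "subject_id",
        "exstdy": "start_day",
        "exendy": "end_day",
        "extrt": "dose_label",
    },
    "conmeds": {
        "usubjid": "subject_id",
        "cmdecod": "term",
        "cmstdy": "start_day",
        "cmendy": "end_day",
        "cmongo": "ongoing_flag",
    },
    "medhistory": {
        "usubjid": "subject_id",
        "mhdecod": "term",
        "mhstdy": "start_day",
        "mhendy": "end_day",
        "mhongo": "ongoing_flag",
    },
}

# Date-column aliases, converted to study days when the *_day column is
# absent: day = date - first_dose_date + 1 on/after first dose, else
# date - first_dose_date (no day 0).
DATE_ALIASES: dict[str, dict[str, str]] = {
    "adverse_events": {"astdt": "onset_day", "aendt": "resolution_day"},
    "labs": {"adt": "day"},
    "exposure": {"exstdt": "start_day", "exendt": "end_day"},
    "conmeds": {"cmstdt": "start_day", "cmendt": "end_day"},
    "medhistory": {"mhstdt": "start_day", "mhendt": "end_day"},
    "subjects": {"trtsdt": "first_dose_day", "trtedt": "last_dose_day"},
}

_TRUTHY = {"y", "yes", "true", "t", "1", "1.0"}
_FALSY = {"n", "no", "false", "f", "0", "0.0", "", "nan", "none"}


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    table: str
    row: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" row {self.row}" if self.row is not None else ""
        return f"[{self.severity}] {self.table}{loc}: {self.message}"


@dataclass
class TrialData:
    """The five safety tables plus arm declaration and data cutoff.

    ``arms`` is the ordered list of arm labels; the *last* entry is the
    reference (control) arm, matching the display convention of putting
    the control arm below/after the treatment arms.
    """

    subjects: pd.DataFrame
    adverse_events: pd.DataFrame
    labs: pd.DataFrame
    exposure: pd.DataFrame
    conmeds: pd.DataFrame = field(default_factory=pd.DataFrame)
    medhistory: pd.DataFrame = field(default_factory=pd.DataFrame)
    arms: Sequence[str] = ()
    reference_arm: str | None = None
    cutoff_day: int | None = None

    def __post_init__(self) -> None:
        self.arms = list(self.arms)
        if self.reference_arm is None and self.arms:
            self.reference_arm = self.arms[-1]

    def arm_subjects(self, arm: str, dosed_only: bool = True) -> pd.DataFrame:
        if arm not in self.arms:
            raise ValueError(f"unknown arm {arm!r}; declared arms: {self.arms}")
        sub = self.subjects[self.subjects["arm"] == arm]
        if dosed_only:
            sub = sub[sub["first_dose_day"].notna()]
        return sub

    def copy(self) -> "TrialData":
        return replace(
            self,
            subjects=self.subjects.copy(),
            adverse_events=self.adverse_events.copy(),
            labs=self.labs.copy(),
            exposure=self.exposure.copy(),
            conmeds=self.conmeds.copy(),
            medhistory=self.medhistory.copy(),
            arms=list(self.arms),
        )


def _empty_table(table_kind: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_pandas_dtype(k))
                         for c, (k, _) in SCHEMAS[table_kind].items()})


def _pandas_dtype(kind: str) -> str:
    return {
        "str": "object",
        "int": "int64",
        "float": "float64",
        "bool": "bool",
        "opt_int": "Int64",
        "opt_float": "float64",
    }[kind]


def _coerce_bool(series: pd.Series, table: str, col: str) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
            continue
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out.append(True)
        elif s in _FALSY:
            out.append(False)
        else:
            raise SchemaError(
                f"{table} row {i}: cannot interpret {v!r} as boolean in column {col!r}"
            )
    return pd.Series(out, index=series.index, dtype="bool")


def _coerce_column(series: pd.Series, kind: str, table: str, col: str) -> pd.Series:
    if kind == "str":
        return series.astype("object").where(series.notna(), None).map(
            lambda v: None if v is None else str(v)
        )
    if kind == "bool":
        return _coerce_bool(series.fillna(False), table, col)
    try:
        if kind == "int":
            num = pd.to_numeric(series)
            if num.isna().any():
                bad = int(num.index[num.isna()][0])
                raise SchemaError(
                    f"{table} row {bad}: missing value in required integer column {col!r}"
                )
            return num.astype("int64")
        if kind == "opt_int":
            return pd.to_numeric(series).round().astype("Int64")
        if kind == "float":
            num = pd.to_numeric(series)
            if num.isna().any():
                bad = int(num.index[num.isna()][0])
                raise SchemaError(
                    f"{table} row {bad}: missing value in required numeric column {col!r}"
                )
            return num.astype("float64")
        if kind == "opt_float":
            return pd.to_numeric(series).astype("float64")
    except SchemaError:
        raise
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{table}: column {col!r} is not numeric: {exc}") from exc
    raise AssertionError(kind)


def _study_day(dates: pd.Series, first_dose: pd.Series) -> pd.Series:
    """CDISC study day: no day 0; day 1 is the first-dose date itself."""
    d = pd.to_datetime(dates, errors="coerce")
    f = pd.to_datetime(first_dose, errors="coerce")
    delta = (d - f).dt.days
    return (delta + (delta >= 0).astype(int)).astype("Int64")


def normalize_columns(
    df: pd.DataFrame,
    table_kind: str,
    first_dose_dates: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Map headers (case-insensitive, with ADaM aliases) onto the canonical
    schema, coerce dtypes, and convert date columns to study days."""
    if table_kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    schema = SCHEMAS[table_kind]
    aliases = ALIASES[table_kind]
    date_aliases = DATE_ALIASES.get(table_kind, {})

    rename: dict[str, str] = {}
    date_cols: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in schema:
            rename[col] = key
        elif key in aliases:
            rename[col] = aliases[key]
        elif key in date_aliases:
            date_cols[col] = date_aliases[key]
    out = df.rename(columns=rename)

    # Date conversion only for targets not already supplied as day columns.
    for src, target in date_cols.items():
        if target in out.columns and out[target].notna().any():
            continue  # precomputed *_day wins
        if table_kind == "subjects" and target == "first_dose_day":
            first = out[src]
        elif first_dose_dates is not None:
            fdd = pd.Series(first_dose_dates)
            first = out["subject_id"].map(fdd) if "subject_id" in out else None
        else:
            first = None
        if first is None:
            raise SchemaError(
                f"{table_kind}: date column {src!r} requires first-dose dates "
                f"to convert to study days"
            )
        out[target] = _study_day(out[src], first)

    missing = [c for c, (_, req) in schema.items() if req and c not in out.columns]
    if missing:
        raise SchemaError(
            f"{table_kind}: missing required column(s) {', '.join(repr(m) for m in missing)}"
        )

    result = pd.DataFrame(index=out.index)
    for col, (kind, _req) in schema.items():
        if col in out.columns:
            result[col] = _coerce_column(out[col], kind, table_kind, col)
        elif kind == "bool":
            result[col] = pd.Series(False, index=out.index, dtype="bool")
        elif kind == "opt_int":
            result[col] = pd.Series(pd.NA, index=out.index, dtype="Int64")
        elif kind == "opt_float":
            result[col] = pd.Series(np.nan, index=out.index, dtype="float64")
        else:
            result[col] = pd.Series([None] * len(out), index=out.index, dtype="object")
    return result.reset_index(drop=True)


def _per_table_issues(df: pd.DataFrame, table_kind: str) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []

    def err(row, msg):
        issues.append(ValidationIssue("error", table_kind, row, msg))

    if table_kind == "subjects":
        dup = df["subject_id"][df["subject_id"].duplicated()]
        for i, sid in dup.items():
            err(int(i), f"duplicate subject_id {sid!r}")
        both = df["first_dose_day"].notna() & df["last_dose_day"].notna()
        bad = both & (df["last_dose_day"] < df["first_dose_day"])
        for i in df.index[bad]:
            err(int(i), f"subject {df.at[i, 'subject_id']!r}: "
                        f"last_dose_day < first_dose_day")
        neg = df["age"] < 0
        for i in df.index[neg.fillna(False)]:
            err(int(i), f"subject {df.at[i, 'subject_id']!r}: negative age")
    elif table_kind == "adverse_events":
        bad_grade = ~df["ctc_grade"].isin([1, 2, 3, 4, 5])
        for i in df.index[bad_grade]:
            err(int(i), f"ctc_grade {df.at[i, 'ctc_grade']} outside 1..5")
        both = df["resolution_day"].notna()
        bad = both & (df["resolution_day"] < df["onset_day"])
        for i in df.index[bad]:
            err(int(i), "resolution_day before onset_day")
    elif table_kind == "labs":
        both = df["lln"].notna() & df["uln"].notna()
        bad = both & (df["lln"] >= df["uln"])
        for i in df.index[bad]:
            err(int(i), f"lln {df.at[i, 'lln']} not below uln {df.at[i, 'uln']}")
        base = df[df["baseline_flag"]]
        dup = base.duplicated(subset=["subject_id", "param_code"], keep=False)
        seen = set()
        for i in base.index[dup]:
            key = (base.at[i, "subject_id"], base.at[i, "param_code"])
            if key not in seen:
                seen.add(key)
                err(int(i), f"multiple baseline-flagged records for subject "
                            f"{key[0]!r}, param {key[1]!r}")
    elif table_kind == "exposure":
        bad = df["end_day"] < df["start_day"]
        for i in df.index[bad]:
            err(int(i), "end_day before start_day")
        for sid, grp in df.groupby("subject_id"):
            iv = grp.sort_values("start_day")[["start_day", "end_day"]].to_numpy()
            for k in range(1, len(iv)):
                if iv[k, 0] <= iv[k - 1, 1]:
                    err(None, f"subject {sid!r}: overlapping exposure intervals")
                    break
    return issues


def read_table(
    path: str | Path,
    table_kind: str,
    dialect: str = "csv",
    first_dose_dates: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Read one trial table from CSV or SAS transport (XPT v5).

    Headers are matched case-insensitively against the canonical schema and
    the documented ADaM aliases (``USUBJID`` -> ``subject_id`` and so on).
    Raises :class:`SchemaError` for unmappable/missing columns and
    :class:`IntegrityError` when the parsed table violates a per-table
    invariant (duplicate subject ids, ``lln >= uln``, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        raw = pd.read_csv(path)
    elif dialect == "xpt":
        raw = pd.read_sas(path, format="xport")
        for col in raw.columns:  # xport strings arrive as bytes
            if raw[col].dtype == object:
                raw[col] = raw[col].map(
                    lambda v: v.decode("utf-8").strip() if isinstance(v, bytes) else v
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = normalize_columns(raw, table_kind, first_dose_dates=first_dose_dates)
    issues = _per_table_issues(df, table_kind)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise IntegrityError("; ".join(str(e) for e in errors))
    return df


def write_table(df: pd.DataFrame, path: str | Path, table_kind: str) -> None:
    """Write a canonical table as CSV (the round-trip dialect)."""
    cols = [c for c in SCHEMAS[table_kind] if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def assemble_trial(
    subjects: pd.DataFrame,
    adverse_events: pd.DataFrame | None = None,
    labs: pd.DataFrame | None = None,
    exposure: pd.DataFrame | None = None,
    conmeds: pd.DataFrame | None = None,
    medhistory: pd.DataFrame | None = None,
    *,
    arms: Sequence[str],
    reference_arm: str | None = None,
    cutoff_day: int | None = None,
) -> TrialData:
    """Bundle validated tables into a :class:`TrialData`, enforcing
    referential integrity and applying the data cutoff.

    Records starting after ``cutoff_day`` are dropped (with a logged count
    per table); intervals running past the cutoff are truncated to it.
    """
    adverse_events = _empty_table("adverse_events") if adverse_events is None or adverse_events.empty else adverse_events.copy()
    labs = _empty_table("labs") if labs is None or labs.empty else labs.copy()
    exposure = _empty_table("exposure") if exposure is None or exposure.empty else exposure.copy()
    conmeds = _empty_table("conmeds") if conmeds is None or conmeds.empty else conmeds.copy()
    medhistory = _empty_table("medhistory") if medhistory is None or medhistory.empty else medhistory.copy()
    subjects = subjects.copy()

    known = set(subjects["subject_id"])
    for name, tbl in [("adverse_events", adverse_events), ("labs", labs),
                      ("exposure", exposure), ("conmeds", conmeds),
                      ("medhistory", medhistory)]:
        if tbl.empty:
            continue
        unknown = sorted(set(tbl["subject_id"]) - known)
        if unknown:
            raise IntegrityError(
                f"{name} references unknown subject id(s): {', '.join(map(repr, unknown))}"
            )
    bad_arms = sorted(set(subjects["arm"]) - set(arms))
    if bad_arms:
        raise IntegrityError(f"subjects carry undeclared arm(s): {bad_arms}")

    if cutoff_day is not None:
        def cut(tbl: pd.DataFrame, start_col: str, end_cols: Iterable[str], name: str) -> pd.DataFrame:
            keep = tbl[start_col] <= cutoff_day
            n_drop = int((~keep).sum())
            if n_drop:
                logger.info("cutoff day %s: dropped %d record(s) from %s",
                            cutoff_day, n_drop, name)
            tbl = tbl[keep].reset_index(drop=True)
            for c in end_cols:
                over = tbl[c].notna() & (tbl[c] > cutoff_day)
                tbl.loc[over, c] = cutoff_day
            return tbl

        adverse_events = cut(adverse_events, "onset_day", ["resolution_day"], "adverse_events")
        labs = cut(labs, "day", [], "labs")
        exposure = cut(exposure, "start_day", ["end_day"], "exposure")
        conmeds = cut(conmeds, "start_day", ["end_day"], "conmeds")
        medhistory = cut(medhistory, "start_day", ["end_day"], "medhistory")
        over = subjects["last_dose_day"].notna() & (subjects["last_dose_day"] > cutoff_day)
        subjects.loc[over, "last_dose_day"] = cutoff_day

    return TrialData(
        subjects=subjects.reset_index(drop=True),
        adverse_events=adverse_events.reset_index(drop=True),
        labs=labs.reset_index(drop=True),
        exposure=exposure.reset_index(drop=True),
        conmeds=conmeds.reset_index(drop=True),
        medhistory=medhistory.reset_index(drop=True),
        arms=list(arms),
        reference_arm=reference_arm,
        cutoff_day=cutoff_day,
    )


def validate_trial(trial: TrialData) -> list[ValidationIssue]:
    """Return every invariant violation; never raises.

    An empty list means the trial is internally consistent: per-table
    invariants hold, all cross-table subject references resolve, and no
    record lies beyond the data cutoff.
    """
    issues: list[ValidationIssue] = []
    issues += _per_table_issues(trial.subjects, "subjects")
    issues += _per_table_issues(trial.adverse_events, "adverse_events")
    issues += _per_table_issues(trial.labs, "labs")
    issues += _per_table_issues(trial.exposure, "exposure")

    known = set(trial.subjects["subject_id"])
    for name in ("adverse_events", "labs", "exposure", "conmeds", "medhistory"):
        tbl: pd.DataFrame = getattr(trial, name)
        if tbl.empty:
            continue
        for i in tbl.index[~tbl["subject_id"].isin(known)]:
            issues.append(ValidationIssue(
                "error", name, int(i),
                f"unknown subject_id {tbl.at[i, 'subject_id']!r}"))

    if not trial.arms:
        issues.append(ValidationIssue("error", "trial", None, "no arms declared"))
    else:
        undeclared = sorted(set(trial.subjects["arm"].dropna()) - set(trial.arms))
        for arm in undeclared:
            issues.append(ValidationIssue("error", "subjects", None,
                                          f"arm {arm!r} not declared"))
    if trial.cutoff_day is not None:
        for name, col in [("adverse_events", "onset_day"), ("labs", "day"),
                          ("exposure", "start_day")]:
            tbl = getattr(trial, name)
            if tbl.empty:
                continue
            for i in tbl.index[tbl[col] > trial.cutoff_day]:
                issues.append(ValidationIssue(
                    "error", name, int(i), f"{col} beyond cutoff_day"))
    return issues
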