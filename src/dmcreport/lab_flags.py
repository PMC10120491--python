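"""Laboratory derivations: normal-range flags, CTC grading, per-visit
distribution summaries, abnormal prevalence, shift pairs, and
outlier-trajectory selection.

Every rule here treats the limits of normal as *per measurement* — the
subject's own LLN/ULN travel with each lab record, because reference
ranges routinely differ by age, sex or laboratory.  Abnormality uses a
strict inequality (a value exactly at the limit is normal); grading
thresholds are likewise strict.  Both conventions are configurable at the
call sites that matter.

CTC grading rules are configuration data, not clinical authority: the
severity scale is the standard oncology CTC/CTCAE idea (grades 1-4 on a
laboratory axis), but the shipped thresholds are illustrative defaults
for the synthetic fixture parameters and must be replaced with
protocol-approved ones for real use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialData

__all__ = [
    "GradingRule",
    "BoxStats",
    "ShiftPair",
    "flag_abnormal",
    "flag_abnormal_frame",
    "ctc_grade",
    "ctc_grade_frame",
    "visit_box_stats",
    "abnormal_prevalence",
    "select_outlier_subjects",
    "shift_pairs",
    "shift_table",
    "default_grading_rules",
]


@dataclass
class GradingRule:
    """Four strictly monotone grade thresholds for one lab parameter.

    ``mode='multiple'`` thresholds are multiples of the subject's ULN
    (direction ``high``) or LLN (direction ``low``); ``mode='absolute'``
    thresholds are raw values in the parameter's unit.
    """

    param_code: str
    direction: str  # "high" | "low"
    thresholds: tuple[float, float, float, float]
    mode: str = "multiple"

    def __post_init__(self) -> None:
        if self.direction not in ("high", "low"):
            raise ValueError(f"direction must be high/low, got {self.direction!r}")
        if self.mode not in ("multiple", "absolute"):
            raise ValueError(f"mode must be multiple/absolute, got {self.mode!r}")
        t = self.thresholds
        if len(t) != 4:
            raise ValueError("exactly four grade thresholds required")
        inc = all(t[i] < t[i + 1] for i in range(3))
        dec = all(t[i] > t[i + 1] for i in range(3))
        if self.direction == "high" and not inc:
            raise ValueError("high-direction thresholds must be strictly increasing")
        if self.direction == "low" and not dec:
            raise ValueError("low-direction thresholds must be strictly decreasing")


@dataclass
class BoxStats:
    """Tukey box-whisker summary for one arm at one visit."""

    param_code: str
    visit_index: int
    arm: str
    n: int
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    whisker_lo: float | None = None
    whisker_hi: float | None = None
    outlier_values: list[float] = field(default_factory=list)


@dataclass
class ShiftPair:
    subject_id: str
    param_code: str
    baseline_value: float
    post_value: float
    baseline_abnormal: str  # low | normal | high | unknown
    post_abnormal: str


def flag_abnormal(
    value: float, lln: float | None, uln: float | None, strict: bool = True
) -> str:
    """Classify one measurement as low / normal / high / unknown.

    Strict convention: a value exactly at a limit is normal.  A missing
    limit makes the flag ``unknown`` only when the decision actually
    depends on it (a value below a present LLN is ``low`` no matter
    whether ULN is known).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    lln = None if lln is None or (isinstance(lln, float) and np.isnan(lln)) else lln
    uln = None if uln is None or (isinstance(uln, float) and np.isnan(uln)) else uln
    if lln is not None and ((value < lln) if strict else (value <= lln)):
        return "low"
    if uln is not None and ((value > uln) if strict else (value >= uln)):
        return "high"
    if lln is not None and uln is not None:
        return "normal"
    return "unknown"


def flag_abnormal_frame(labs: pd.DataFrame, strict: bool = True) -> pd.Series:
    """Vectorised :func:`flag_abnormal` over a lab table."""
    return pd.Series(
        [flag_abnormal(v, l, u, strict)
         for v, l, u in zip(labs["value"], labs["lln"], labs["uln"])],
        index=labs.index, dtype="object")


def ctc_grade(
    value: float, lln: float | None, uln: float | None, rule: GradingRule
) -> int | None:
    """Highest toxicity grade (0-4) whose threshold the value exceeds.

    Returns None (undetermined) when the limit the rule scales by is
    missing.  Monotone non-decreasing in value for direction ``high``,
    non-increasing for ``low``.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if rule.mode == "multiple":
        ref = uln if rule.direction == "high" else lln
        if ref is None or (isinstance(ref, float) and np.isnan(ref)):
            return None
        bounds = [t * ref for t in rule.thresholds]
    else:
        bounds = list(rule.thresholds)
    grade = 0
    for g, b in enumerate(bounds, start=1):
        passed = value > b if rule.direction == "high" else value < b
        if passed:
            grade = g
    return grade


def ctc_grade_frame(labs: pd.DataFrame, rule: GradingRule) -> pd.Series:
    sub = labs[labs["param_code"] == rule.param_code]
    return pd.Series(
        [ctc_grade(v, l, u, rule)
         for v, l, u in zip(sub["value"], sub["lln"], sub["uln"])],
        index=sub.index, dtype="object")


def default_grading_rules() -> dict[str, GradingRule]:
    """Illustrative grading thresholds for the synthetic fixture parameters
    (NOT clinical authority — replace with protocol-approved rules)."""
    return {
        "CK": GradingRule("CK", "high", (1.0, 2.5, 5.0, 10.0)),
        "CHOL": GradingRule("CHOL", "high", (1.0, 1.5, 2.0, 5.0)),
    }


def _box_from_values(values: np.ndarray) -> dict:
    """Tukey statistics: linear-interpolation quartiles, whiskers at the
    last data point within 1.5*IQR beyond the box, points beyond listed
    as outliers."""
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    whisker_lo = float(inside.min()) if inside.size else float(q1)
    whisker_hi = float(inside.max()) if inside.size else float(q3)
    outliers = sorted(float(v) for v in values[(values < lo_fence) | (values > hi_fence)])
    return dict(median=float(med), q1=float(q1), q3=float(q3),
                whisker_lo=whisker_lo, whisker_hi=whisker_hi,
                outlier_values=outliers)


def visit_box_stats(
    trial: TrialData, param_code: str, log_scale: bool = False
) -> list[BoxStats]:
    """Per arm x scheduled visit box-whisker statistics for one parameter.

    Quantiles use linear interpolation between order statistics.  Visits
    with no evaluable value still yield a record with n=0 (so the per-visit
    n annotation row stays complete as drop-out shrinks the sample).
    The statistics are order statistics, so a log-scaled display simply
    transforms the axis; ``log_scale`` is carried through to the figure
    layer unchanged.
    """
    labs = trial.labs[trial.labs["param_code"] == param_code]
    if labs.empty:
        raise ValueError(f"parameter {param_code!r} not present")
    visits = sorted(labs["visit_index"].unique())
    arm_of = trial.subjects.set_index("subject_id")["arm"]
    out: list[BoxStats] = []
    for arm in trial.arms:
        in_arm = labs["subject_id"].map(arm_of) == arm
        for vi in visits:
            vals = labs.loc[in_arm & (labs["visit_index"] == vi), "value"]
            vals = vals.dropna().to_numpy(dtype=float)
            if vals.size == 0:
                out.append(BoxStats(param_code, int(vi), arm, 0))
            else:
                out.append(BoxStats(param_code, int(vi), arm, int(vals.size),
                                    **_box_from_values(vals)))
    return out


def abnormal_prevalence(
    trial: TrialData, param_code: str, side: str = "either", strict: bool = True
) -> pd.DataFrame:
    """Per arm x visit abnormality prevalence.

    Denominators count subjects with a non-missing, *flaggable* value at
    that visit (a measurement whose relevant limit is missing is neither
    numerator nor denominator).  ``side`` selects which abnormality counts:
    ``low``, ``high``, or ``either`` (low + high, each measurement counted
    once).
    """
    if side not in ("low", "high", "either"):
        raise ValueError(f"side must be low/high/either, got {side!r}")
    labs = trial.labs[trial.labs["param_code"] == param_code].copy()
    if labs.empty:
        raise ValueError(f"parameter {param_code!r} not present")
    labs["flag"] = flag_abnormal_frame(labs, strict=strict)
    arm_of = trial.subjects.set_index("subject_id")["arm"]
    labs["arm"] = labs["subject_id"].map(arm_of)
    rows = []
    abnormal_set = {"low", "high"} if side == "either" else {side}
    for arm in trial.arms:
        for vi in sorted(labs["visit_index"].unique()):
            sub = labs[(labs["arm"] == arm) & (labs["visit_index"] == vi)]
            evaluable = sub[sub["flag"] != "unknown"]
            n = int(evaluable["subject_id"].nunique())
            hit = evaluable[evaluable["flag"].isin(abnormal_set)]
            n_abn = int(hit["subject_id"].nunique())
            rows.append(dict(arm=arm, visit_index=int(vi), n=n,
                             n_abnormal=n_abn,
                             percent=100.0 * n_abn / n if n else np.nan))
    return pd.DataFrame(rows)


def select_outlier_subjects(
    trial: TrialData,
    param_code: str,
    multiplier: float = 3.0,
    grade_rule: GradingRule | None = None,
    min_grade: int | None = None,
) -> dict[str, list[str]]:
    """Subjects whose trajectory warrants individual display, with reasons.

    Selected iff any *post-baseline* measurement strictly exceeds
    ``multiplier`` times the subject's own ULN, or (when a grading rule is
    supplied) reaches CTC grade >= ``min_grade``.  Returns
    ``{subject_id: [reason, ...]}``.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    labs = trial.labs[trial.labs["param_code"] == param_code]
    reasons: dict[str, list[str]] = {}
    for _, row in labs.iterrows():
        if row["baseline_flag"]:
            continue
        sid = row["subject_id"]
        uln = row["uln"]
        if pd.notna(uln) and row["value"] > multiplier * uln:
            reasons.setdefault(sid, []).append(
                f"{param_code} {row['value']:g} > {multiplier:g}x ULN "
                f"({uln:g}) at day {row['day']}")
        if grade_rule is not None and min_grade is not None:
            g = ctc_grade(row["value"], row["lln"], row["uln"], grade_rule)
            if g is not None and g >= min_grade:
                reasons.setdefault(sid, []).append(
                    f"{param_code} CTC grade {g} at day {row['day']}")
    return reasons


def shift_pairs(
    trial: TrialData,
    param_code: str,
    post_rule: str = "worst_case",
    direction: str = "high",
    strict: bool = True,
) -> list[ShiftPair]:
    """One baseline/post-baseline value pair per eligible subject.

    Eligible subjects have a baseline value (the baseline-flagged record,
    else the last value on/before first dose day) and at least one
    post-baseline value.  ``post_rule='worst_case'`` takes the maximum
    post-baseline value for direction-high parameters (minimum for low);
    ``'last_value'`` takes the latest.  Abnormality classes come from the
    measurement's own limits of normal.
    """
    if post_rule not in ("worst_case", "last_value"):
        raise ValueError(f"post_rule must be worst_case/last_value, got {post_rule!r}")
    labs = trial.labs[trial.labs["param_code"] == param_code]
    if labs.empty:
        raise ValueError(f"parameter {param_code!r} not present")
    first_dose = trial.subjects.set_index("subject_id")["first_dose_day"]
    out: list[ShiftPair] = []
    for sid, grp in labs.groupby("subject_id", sort=True):
        base_rec = grp[grp["baseline_flag"]]
        if base_rec.empty:
            fd = first_dose.get(sid)
            if pd.isna(fd):
                continue  # never dosed: no baseline
            pre = grp[(grp["day"] <= fd) & grp["value"].notna()]
            if pre.empty:
                continue
            base_rec = pre.sort_values("day").tail(1)
        else:
            base_rec = base_rec.head(1)
        base = base_rec.iloc[0]
        post = grp[~grp["baseline_flag"] & (grp["day"] > int(base["day"])) &
                   grp["value"].notna()]
        if post.empty:
            continue
        if post_rule == "worst_case":
            idx = post["value"].idxmax() if direction == "high" else post["value"].idxmin()
        else:
            idx = post.sort_values("day").index[-1]
        prec = post.loc[idx]
        out.append(ShiftPair(
            subject_id=str(sid), param_code=param_code,
            baseline_value=float(base["value"]), post_value=float(prec["value"]),
            baseline_abnormal=flag_abnormal(base["value"], base["lln"],
                                            base["uln"], strict),
            post_abnormal=flag_abnormal(prec["value"], prec["lln"],
                                        prec["uln"], strict),
        ))
    return out


def shift_table(pairs: Iterable[ShiftPair]) -> pd.DataFrame:
    """Classic 3x3 (plus unknown) shift cross-tabulation from the same
    pairs that feed the scatter display, so figure and table agree by
    construction."""
    cats = ["low", "normal", "high", "unknown"]
    tab = pd.DataFrame(0, index=cats, columns=cats)
    for p in pairs:
        tab.loc[p.baseline_abnormal, p.post_abnormal] += 1
    tab.index.name = "baseline"
    tab.columns.name = "post"
    return tab
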