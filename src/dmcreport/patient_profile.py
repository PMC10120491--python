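"""One-page clinical summaries for subjects of special interest.

A profile collects, for one subject, everything a DMC clinician needs to
judge the clinical relevance of an adverse event or abnormal laboratory
value: demographics, medical history, concomitant medication, the dosing
interval, all adverse events with grade and seriousness, the laboratory
parameters that ever went abnormal for this subject (baseline, worst and
last value with worst CTC grade), and a key-event timeline merging the
exposure interval, AE intervals, conmed intervals and flagged lab values.

Subjects are selected for profiling when they have a serious adverse
event, an adverse event of CTC grade >= 3, or a laboratory value of CTC
grade >= 3 — each selected id carries the list of reasons that triggered
it.  History and conmed lists truncate to the most recent entries (with an
explicit "+k more" marker) so the rendered profile stays on one page.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .lab_flags import GradingRule, ctc_grade, flag_abnormal
from .trial_data import TrialData

__all__ = [
    "TimelineEvent",
    "LabSummary",
    "PatientProfile",
    "select_profile_subjects",
    "build_profile",
]

MAX_LIST_ENTRIES = 15  # one-page truncation for history/conmed blocks


@dataclass
class TimelineEvent:
    day: int
    track: str  # exposure | ae | conmed | lab
    label: str
    end_day: int | None = None
    ongoing: bool = False
    severity: int | None = None


@dataclass
class LabSummary:
    param_code: str
    baseline_value: float | None
    worst_value: float
    worst_day: int
    worst_grade: int | None
    last_value: float
    last_day: int


@dataclass
class PatientProfile:
    subject_id: str
    demographics: dict
    medhistory: list[str]
    medhistory_more: int
    conmeds: list[dict]
    conmeds_more: int
    exposure: list[dict]
    adverse_events: list[dict]
    labs: list[LabSummary]
    timeline: list[TimelineEvent] = field(default_factory=list)


def select_profile_subjects(
    trial: TrialData,
    grading_rules: dict[str, GradingRule] | None = None,
    min_grade: int = 3,
) -> dict[str, list[str]]:
    """Subjects needing a detailed clinical profile, with reasons.

    Union of: subjects with at least one serious adverse event; with an
    adverse event of CTC grade >= ``min_grade``; with a laboratory value
    of CTC grade >= ``min_grade`` under the supplied grading rules.
    """
    reasons: dict[str, list[str]] = {}
    ae = trial.adverse_events
    if not ae.empty:
        for _, row in ae[ae["serious_flag"]].iterrows():
            reasons.setdefault(row["subject_id"], []).append(
                f"serious AE: {row['preferred_term']}")
        for _, row in ae[ae["ctc_grade"] >= min_grade].iterrows():
            reasons.setdefault(row["subject_id"], []).append(
                f"grade {row['ctc_grade']} AE: {row['preferred_term']}")
    if grading_rules:
        labs = trial.labs
        for code, rule in grading_rules.items():
            sub = labs[labs["param_code"] == code]
            for _, row in sub.iterrows():
                g = ctc_grade(row["value"], row["lln"], row["uln"], rule)
                if g is not None and g >= min_grade:
                    reasons.setdefault(row["subject_id"], []).append(
                        f"grade {g} lab value: {code} {row['value']:g} "
                        f"at day {row['day']}")
    return dict(sorted(reasons.items()))


def _truncate(items: list, limit: int = MAX_LIST_ENTRIES) -> tuple[list, int]:
    if len(items) <= limit:
        return items, 0
    return items[-limit:], len(items) - limit


def build_profile(
    trial: TrialData,
    subject_id: str,
    grading_rules: dict[str, GradingRule] | None = None,
) -> PatientProfile:
    """Assemble the one-page profile for one subject.

    The lab block is relevance-filtered to parameters with at least one
    abnormal value for this subject.  The timeline contains the exposure
    interval, every adverse event as an interval (running to the data
    cutoff with an ongoing marker when unresolved), conmed intervals, and
    each abnormal lab value as a point event; events are ordered by day
    then track then label, deterministically.
    """
    subj = trial.subjects[trial.subjects["subject_id"] == subject_id]
    if subj.empty:
        raise ValueError(f"unknown subject {subject_id!r}")
    s = subj.iloc[0]
    demographics = {
        "subject_id": subject_id, "arm": s["arm"], "age": s["age"],
        "sex": s["sex"], "race": s.get("race"), "country": s.get("country"),
    }
    cutoff = trial.cutoff_day

    mh = trial.medhistory[trial.medhistory["subject_id"] == subject_id] \
        if not trial.medhistory.empty else pd.DataFrame()
    history = ([] if mh.empty else
               mh.sort_values("start_day")["term"].astype(str).tolist())
    history, mh_more = _truncate(history)

    cm = trial.conmeds[trial.conmeds["subject_id"] == subject_id] \
        if not trial.conmeds.empty else pd.DataFrame()
    conmed_list = []
    if not cm.empty:
        for _, row in cm.sort_values("start_day").iterrows():
            conmed_list.append(dict(term=str(row["term"]),
                                    start_day=int(row["start_day"]),
                                    end_day=(None if pd.isna(row["end_day"])
                                             else int(row["end_day"])),
                                    ongoing=bool(row.get("ongoing_flag", False))))
    conmed_list, cm_more = _truncate(conmed_list)

    expo = trial.exposure[trial.exposure["subject_id"] == subject_id]
    exposure = [dict(start_day=int(r["start_day"]), end_day=int(r["end_day"]),
                     dose_label=str(r["dose_label"]))
                for _, r in expo.sort_values("start_day").iterrows()]

    ae = trial.adverse_events[trial.adverse_events["subject_id"] == subject_id]
    ae_list = []
    for _, row in ae.sort_values(["onset_day", "preferred_term"]).iterrows():
        ae_list.append(dict(
            preferred_term=str(row["preferred_term"]),
            onset_day=int(row["onset_day"]),
            resolution_day=(None if pd.isna(row["resolution_day"])
                            else int(row["resolution_day"])),
            ctc_grade=int(row["ctc_grade"]),
            serious=bool(row["serious_flag"]),
            related=bool(row["related_flag"]),
        ))

    labs = trial.labs[trial.labs["subject_id"] == subject_id]
    lab_summaries: list[LabSummary] = []
    flagged_points: list[tuple[int, str, float]] = []
    if not labs.empty:
        for code, grp in labs.groupby("param_code", sort=True):
            grp = grp.sort_values("day")
            flags = [flag_abnormal(v, l, u) for v, l, u in
                     zip(grp["value"], grp["lln"], grp["uln"])]
            if not any(f in ("low", "high") for f in flags):
                continue  # relevance filter: only parameters that went abnormal
            rule = (grading_rules or {}).get(code)
            grades = [ctc_grade(v, l, u, rule) if rule else None
                      for v, l, u in zip(grp["value"], grp["lln"], grp["uln"])]
            base = grp[grp["baseline_flag"]]
            direction = rule.direction if rule else "high"
            vals = grp["value"].to_numpy(float)
            worst_pos = int(vals.argmax() if direction == "high" else vals.argmin())
            lab_summaries.append(LabSummary(
                param_code=str(code),
                baseline_value=(None if base.empty else float(base.iloc[0]["value"])),
                worst_value=float(vals[worst_pos]),
                worst_day=int(grp.iloc[worst_pos]["day"]),
                worst_grade=max((g for g in grades if g is not None), default=None),
                last_value=float(grp.iloc[-1]["value"]),
                last_day=int(grp.iloc[-1]["day"]),
            ))
            for (_, row), f in zip(grp.iterrows(), flags):
                if f in ("low", "high"):
                    flagged_points.append((int(row["day"]), str(code),
                                           float(row["value"])))

    timeline: list[TimelineEvent] = []
    for e in exposure:
        timeline.append(TimelineEvent(e["start_day"], "exposure",
                                      e["dose_label"], end_day=e["end_day"]))
    for a in ae_list:
        ongoing = a["resolution_day"] is None
        timeline.append(TimelineEvent(
            a["onset_day"], "ae", a["preferred_term"],
            end_day=(cutoff if ongoing else a["resolution_day"]),
            ongoing=ongoing, severity=a["ctc_grade"]))
    for c in conmed_list:
        end = c["end_day"]
        timeline.append(TimelineEvent(c["start_day"], "conmed", c["term"],
                                      end_day=(cutoff if end is None else end),
                                      ongoing=end is None))
    for day, code, value in flagged_points:
        timeline.append(TimelineEvent(day, "lab", f"{code}={value:g}"))
    timeline.sort(key=lambda e: (e.day, e.track, e.label))

    return PatientProfile(
        subject_id=subject_id, demographics=demographics,
        medhistory=history, medhistory_more=mh_more,
        conmeds=conmed_list, conmeds_more=cm_more,
        exposure=exposure, adverse_events=ae_list,
        labs=lab_summaries, timeline=timeline,
    )
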