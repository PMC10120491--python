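"""Adverse-event statistics: incidence, exposure adjustment, and the
volcano quantities (effect estimate, exact p-value, FDR adjustment).

Counting conventions
--------------------
Incidence is *subject-level*: a subject contributes at most once per
preferred term to ``n_subjects_with_event`` no matter how many episodes
they report, while ``n_events`` counts episodes.  The denominator
``n_at_risk`` is the safety population of the arm — every subject who
received at least one dose.  Person-time runs from first to last dose day
inclusive (divided by 365.25), optionally truncated at the first event of
the term when an exposure-adjusted view wants time-at-risk semantics.

Treatment emergence: an event is included if its onset falls on or after
the first dose day and no later than the last dose day plus a follow-up
lag (default 30 days).

The per-term p-value is a two-sided Fisher exact test on the subject-level
2x2 table, computed by direct hypergeometric enumeration with the
minimum-likelihood two-sided rule.  With many terms tested at once these
p-values are descriptive screening quantities, not confirmatory tests;
the Benjamini-Hochberg adjustment is offered for the same screening
purpose, applied once across all terms of one arm-pair comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, fsum, lgamma, log
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialData

__all__ = [
    "IncidenceRecord",
    "VolcanoRecord",
    "treatment_emergent",
    "person_years_by_arm",
    "ae_incidence",
    "order_terms",
    "fisher_two_sided",
    "bh_adjust",
    "rate_ratio",
    "volcano_stats",
]

DAYS_PER_YEAR = 365.25
DEFAULT_TE_LAG_DAYS = 30


@dataclass
class IncidenceRecord:
    preferred_term: str
    system_organ_class: str
    arm: str
    n_subjects_with_event: int
    n_at_risk: int
    percent: float
    n_events: int
    person_years: float
    rate_per_100py: float | None


@dataclass
class VolcanoRecord:
    preferred_term: str
    estimate_kind: str  # "risk_difference" | "rate_ratio"
    estimate: float
    p_value: float
    fdr_p: float
    n_event_a: int
    n_event_b: int
    n_a: int
    n_b: int
    labeled: bool = False


def treatment_emergent(
    trial: TrialData, lag_days: int = DEFAULT_TE_LAG_DAYS
) -> pd.DataFrame:
    """Adverse events with onset within [first dose, last dose + lag]."""
    ae = trial.adverse_events
    if ae.empty:
        return ae
    subj = trial.subjects.set_index("subject_id")
    first = ae["subject_id"].map(subj["first_dose_day"])
    last = ae["subject_id"].map(subj["last_dose_day"])
    keep = first.notna() & (ae["onset_day"] >= first) & \
        (last.notna() & (ae["onset_day"] <= last + lag_days))
    return ae[keep.fillna(False)].reset_index(drop=True)


def person_years_by_arm(
    trial: TrialData,
    truncate_at_first_event_of: str | None = None,
    lag_days: int = DEFAULT_TE_LAG_DAYS,
) -> dict[str, float]:
    """Total exposure time per arm, in years.

    Per subject: first to last dose day inclusive.  If a preferred term is
    given, affected subjects' time is truncated at their first event of
    that term (time-at-risk semantics for exposure-adjusted rates).
    """
    subj = trial.subjects[trial.subjects["first_dose_day"].notna()]
    days = (subj["last_dose_day"] - subj["first_dose_day"] + 1).astype(float)
    days = pd.Series(days.to_numpy(), index=subj["subject_id"].to_numpy())
    if truncate_at_first_event_of is not None:
        ae = treatment_emergent(trial, lag_days)
        hits = ae[ae["preferred_term"] == truncate_at_first_event_of]
        first_onset = hits.groupby("subject_id")["onset_day"].min()
        fd = subj.set_index("subject_id")["first_dose_day"]
        for sid, onset in first_onset.items():
            if sid in days.index:
                days.loc[sid] = min(days.loc[sid],
                                    float(onset - fd.loc[sid] + 1))
    arm = subj.set_index("subject_id")["arm"]
    out: dict[str, float] = {a: 0.0 for a in trial.arms}
    totals = days.groupby(arm).sum() / DAYS_PER_YEAR
    out.update({str(a): float(v) for a, v in totals.items()})
    return out


def ae_incidence(
    trial: TrialData,
    filters: Callable[[pd.DataFrame], pd.Series] | None = None,
    group_by: str = "preferred_term",
    lag_days: int = DEFAULT_TE_LAG_DAYS,
    truncate_person_time: bool = False,
) -> list[IncidenceRecord]:
    """Subject-level incidence per term x arm, with exposure-adjusted rates.

    ``filters`` is a predicate on the AE table (e.g. seriousness, grade or
    AESI subsets) returning a boolean mask.  Terms with zero events in all
    arms are omitted.
    """
    if group_by not in ("preferred_term", "system_organ_class"):
        raise ValueError(f"unsupported group_by {group_by!r}")
    ae = treatment_emergent(trial, lag_days)
    if filters is not None and not ae.empty:
        ae = ae[np.asarray(filters(ae), dtype=bool)]
    subj = trial.subjects[trial.subjects["first_dose_day"].notna()]
    n_at_risk = subj.groupby("arm")["subject_id"].nunique().to_dict()
    arm_of = subj.set_index("subject_id")["arm"]
    soc_of = {}
    if not ae.empty:
        soc_of = ae.groupby(group_by)["system_organ_class"].first().to_dict()

    records: list[IncidenceRecord] = []
    terms = sorted(ae[group_by].unique()) if not ae.empty else []
    base_py = person_years_by_arm(trial, None, lag_days)
    for term in terms:
        sub = ae[ae[group_by] == term]
        py = (person_years_by_arm(trial, term, lag_days)
              if truncate_person_time and group_by == "preferred_term"
              else base_py)
        for arm in trial.arms:
            in_arm = sub["subject_id"].map(arm_of) == arm
            n_subj = int(sub.loc[in_arm, "subject_id"].nunique())
            n_events = int(in_arm.sum())
            n_risk = int(n_at_risk.get(arm, 0))
            pct = 100.0 * n_subj / n_risk if n_risk else 0.0
            pyears = float(py.get(arm, 0.0))
            rate = 100.0 * n_subj / pyears if pyears > 0 else None
            records.append(IncidenceRecord(
                preferred_term=term,
                system_organ_class=str(soc_of.get(term, term)),
                arm=arm, n_subjects_with_event=n_subj, n_at_risk=n_risk,
                percent=pct, n_events=n_events, person_years=pyears,
                rate_per_100py=rate,
            ))
    return records


def order_terms(
    records: Sequence[IncidenceRecord],
    by_arm: str,
    descending: bool = True,
    exposure_adjusted: bool = False,
) -> list[str]:
    """Deterministic term ordering for the AE dot plot.

    Sorts by the chosen arm's incidence (percent, or rate per 100
    person-years for the exposure-adjusted view), ties broken by the other
    arms' incidence, then alphabetically.
    """
    arms_seen = {r.arm for r in records}
    if by_arm not in arms_seen:
        raise ValueError(f"arm {by_arm!r} not present in records")

    def metric(r: IncidenceRecord) -> float:
        if exposure_adjusted:
            return r.rate_per_100py if r.rate_per_100py is not None else 0.0
        return r.percent

    by_term: dict[str, dict[str, float]] = {}
    for r in records:
        by_term.setdefault(r.preferred_term, {})[r.arm] = metric(r)
    other_arms = sorted(arms_seen - {by_arm})

    def key(term: str):
        vals = by_term[term]
        primary = vals.get(by_arm, 0.0)
        others = tuple(vals.get(a, 0.0) for a in other_arms)
        sign = -1.0 if descending else 1.0
        return (sign * primary, tuple(sign * o for o in others), term)

    return sorted(by_term, key=key)


def _log_hyper_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = a) for X ~ Hypergeometric with margins (r1, r2 | c1, .)."""
    n = r1 + r2

    def lchoose(nn: int, kk: int) -> float:
        return lgamma(nn + 1) - lgamma(kk + 1) - lgamma(nn - kk + 1)

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_two_sided(n11: int, n12: int, n21: int, n22: int) -> float | None:
    """Two-sided Fisher exact p-value by direct hypergeometric enumeration.

    Conditional on both margins, sums the probability of every table whose
    point probability does not exceed the observed one (minimum-likelihood
    rule, with a 1e-7 relative tolerance against ties lost to rounding).
    Returns None for the all-zero table, where the test is undefined.
    """
    if min(n11, n12, n21, n22) < 0:
        raise ValueError("cell counts must be non-negative")
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    if r1 + r2 == 0:
        return None
    lo, hi = max(0, c1 - r2), min(c1, r1)
    if lo == hi:  # degenerate margin: only one table possible
        return 1.0
    log_obs = _log_hyper_pmf(n11, r1, r2, c1)
    cutoff = log_obs + log(1 + 1e-7)
    masses = [exp(_log_hyper_pmf(a, r1, r2, c1)) for a in range(lo, hi + 1)
              if _log_hyper_pmf(a, r1, r2, c1) <= cutoff]
    # fsum is exactly rounded, so the p-value is invariant to the
    # enumeration order (arm-swap symmetry holds bit-for-bit)
    return float(min(fsum(sorted(masses)), 1.0))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values.

    With order statistics p(1) <= ... <= p(m), the adjusted value at rank i
    is min(1, min_{j >= i} m * p(j) / j), mapped back to input positions.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def rate_ratio(
    n_a: int, py_a: float, n_b: int, py_b: float, continuity: float = 0.5
) -> float:
    """Exposure-adjusted incidence rate ratio with a zero-cell continuity
    correction: ((n_a + c)/py_a) / ((n_b + c)/py_b), c applied to both
    numerators only when either count is zero.  Swapping the arms inverts
    the ratio exactly.
    """
    if py_a <= 0 or py_b <= 0:
        raise ValueError("person-years must be positive")
    if continuity < 0:
        raise ValueError("continuity must be non-negative")
    c = continuity if (n_a == 0 or n_b == 0) else 0.0
    return ((n_a + c) / py_a) / ((n_b + c) / py_b)


def volcano_stats(
    trial: TrialData,
    arm_a: str,
    arm_b: str,
    estimate_kind: str = "risk_difference",
    label_rule: dict | None = None,
    lag_days: int = DEFAULT_TE_LAG_DAYS,
    continuity: float = 0.5,
) -> list[VolcanoRecord]:
    """Per-preferred-term volcano statistics for one arm-pair comparison.

    One record per term with at least one affected subject in either arm.
    ``estimate`` is the risk difference in percentage points
    (100*(pA - pB)) or the exposure-adjusted incidence rate ratio; the
    p-value is the two-sided Fisher exact test on the subject-level 2x2
    table; ``fdr_p`` is Benjamini-Hochberg across all included terms
    jointly.  ``label_rule`` is ``{"p_cutoff": x}`` (label p < x) or
    ``{"top_k": k}`` (k smallest p-values, ties by |effect| then term).
    """
    if arm_a == arm_b:
        raise ValueError("arms must be distinct")
    for arm in (arm_a, arm_b):
        if arm not in trial.arms:
            raise ValueError(f"unknown arm {arm!r}")
    if estimate_kind not in ("risk_difference", "rate_ratio"):
        raise ValueError(f"unknown estimate_kind {estimate_kind!r}")
    label_rule = label_rule or {"p_cutoff": 0.05}

    records_inc = ae_incidence(trial, lag_days=lag_days)
    by_term: dict[str, dict[str, IncidenceRecord]] = {}
    for r in records_inc:
        by_term.setdefault(r.preferred_term, {})[r.arm] = r

    out: list[VolcanoRecord] = []
    for term in sorted(by_term):
        ra, rb = by_term[term].get(arm_a), by_term[term].get(arm_b)
        if ra is None or rb is None:
            continue
        if ra.n_subjects_with_event == 0 and rb.n_subjects_with_event == 0:
            continue
        n_a, n_b = ra.n_at_risk, rb.n_at_risk
        e_a, e_b = ra.n_subjects_with_event, rb.n_subjects_with_event
        if estimate_kind == "risk_difference":
            est = 100.0 * (e_a / n_a - e_b / n_b) if n_a and n_b else float("nan")
        else:
            est = rate_ratio(e_a, ra.person_years, e_b, rb.person_years,
                             continuity=continuity)
        p = fisher_two_sided(e_a, n_a - e_a, e_b, n_b - e_b)
        out.append(VolcanoRecord(
            preferred_term=term, estimate_kind=estimate_kind, estimate=est,
            p_value=p if p is not None else 1.0, fdr_p=1.0,
            n_event_a=e_a, n_event_b=e_b, n_a=n_a, n_b=n_b,
        ))
    if not out:
        return out
    adj = bh_adjust([r.p_value for r in out])
    for r, a in zip(out, adj):
        r.fdr_p = float(a)

    if "p_cutoff" in label_rule:
        cut = float(label_rule["p_cutoff"])
        for r in out:
            r.labeled = r.p_value < cut
    elif "top_k" in label_rule:
        k = int(label_rule["top_k"])
        ranked = sorted(out, key=lambda r: (r.p_value, -abs(
            np.log(r.estimate) if r.estimate_kind == "rate_ratio" and r.estimate > 0
            else r.estimate), r.preferred_term))
        for r in ranked[:k]:
            r.labeled = True
    else:
        raise ValueError("label_rule must contain 'p_cutoff' or 'top_k'")
    return out
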