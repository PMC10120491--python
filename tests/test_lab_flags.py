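"""Laboratory derivations: flagging boundaries, grading monotonicity,
box-whisker statistics against a sort-based oracle, shift conservation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmcreport.lab_flags import (GradingRule, ctc_grade, flag_abnormal,
                                 abnormal_prevalence, select_outlier_subjects,
                                 shift_pairs, shift_table, visit_box_stats)

# ---------------------------------------------------------------------------
# sort-based oracle for box statistics (independent of numpy.quantile)
# ---------------------------------------------------------------------------

def quantile_oracle(values, q):
    """Linear interpolation between order statistics: h = (n-1) q."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def box_oracle(values):
    q1 = quantile_oracle(values, 0.25)
    q3 = quantile_oracle(values, 0.75)
    med = quantile_oracle(values, 0.5)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [v for v in values if lo_f <= v <= hi_f]
    outliers = sorted(v for v in values if v < lo_f or v > hi_f)
    return dict(q1=q1, median=med, q3=q3,
                whisker_lo=min(inside), whisker_hi=max(inside),
                outliers=outliers)


def _one_visit_trial(values):
    from dmcreport.trial_data import assemble_trial
    n = len(values)
    sids = [f"S{i}" for i in range(n)]
    subjects = pd.DataFrame(dict(
        subject_id=sids, arm=["A"] * n, age=[70.0] * n, sex=["F"] * n,
        race=["WHITE"] * n, country=["USA"] * n,
        first_dose_day=[1] * n, last_dose_day=[100] * n,
        randomized_flag=[True] * n, discontinued_flag=[False] * n))
    labs = pd.DataFrame(dict(
        subject_id=sids, param_code=["P"] * n, param_name=["P"] * n,
        visit_index=[1] * n, visit_name=["V1"] * n, day=[28] * n,
        value=[float(v) for v in values], unit=["u"] * n,
        lln=[np.nan] * n, uln=[np.nan] * n, baseline_flag=[False] * n))
    expo = pd.DataFrame(dict(subject_id=sids, start_day=[1] * n,
                             end_day=[100] * n, dose_label=["A"] * n))
    return assemble_trial(subjects, None, labs, expo, arms=["A"],
                          cutoff_day=200)


# ---------------------------------------------------------------------------
# flag_abnormal
# ---------------------------------------------------------------------------

class TestFlagAbnormal:
    @pytest.mark.parametrize("value,lln,uln,expected", [
        (200.0, 30.0, 200.0, "normal"),   # exactly at ULN is normal
        (240.0, 30.0, 200.0, "high"),     # 1.2x ULN
        (29.9, 30.0, 200.0, "low"),
        (100.0, 30.0, 200.0, "normal"),
        (25.0, 30.0, None, "low"),        # low decidable without ULN
        (100.0, 30.0, None, "unknown"),   # high side undecidable
        (250.0, None, 200.0, "high"),
        (150.0, None, 200.0, "unknown"),  # low side undecidable
        (np.nan, 30.0, 200.0, "unknown"),
    ])
    def test_boundary_and_missing_limit_rules(self, value, lln, uln, expected):
        assert flag_abnormal(value, lln, uln) == expected

    def test_non_strict_mode_flags_the_limit_itself(self):
        assert flag_abnormal(200.0, 30.0, 200.0, strict=False) == "high"

    @given(v1=st.floats(1, 1000), v2=st.floats(1, 1000))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_value(self, v1, v2):
        order = {"low": 0, "normal": 1, "high": 2}
        lo, hi = sorted((v1, v2))
        f_lo, f_hi = flag_abnormal(lo, 30.0, 200.0), flag_abnormal(hi, 30.0, 200.0)
        assert order[f_lo] <= order[f_hi]


# ---------------------------------------------------------------------------
# ctc_grade
# ---------------------------------------------------------------------------

class TestCtcGrade:
    RULE = GradingRule("P", "high", (1.0, 1.5, 2.0, 5.0))

    @pytest.mark.parametrize("multiple,expected", [
        (0.5, 0), (1.0, 0), (1.2, 1), (1.5, 1), (1.8, 2), (2.5, 3), (6.0, 4),
    ])
    def test_threshold_lookup_strict(self, multiple, expected):
        assert ctc_grade(multiple * 200.0, 30.0, 200.0, self.RULE) == expected

    def test_missing_required_limit_undetermined(self):
        assert ctc_grade(500.0, 30.0, None, self.RULE) is None

    def test_low_direction(self):
        rule = GradingRule("P", "low", (1.0, 0.8, 0.5, 0.2))
        assert ctc_grade(30.0, 30.0, 200.0, rule) == 0   # at LLN: grade 0
        assert ctc_grade(25.0, 30.0, 200.0, rule) == 1   # < 1.0x but >= 0.8x
        assert ctc_grade(10.0, 30.0, 200.0, rule) == 3   # < 0.5x but >= 0.2x
        assert ctc_grade(1.0, 30.0, 200.0, rule) == 4

    def test_absolute_mode(self):
        rule = GradingRule("P", "high", (10.0, 20.0, 30.0, 40.0),
                           mode="absolute")
        assert ctc_grade(25.0, None, None, rule) == 2

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            GradingRule("P", "high", (1.0, 3.0, 2.0, 5.0))

    @given(v1=st.floats(1, 3000), v2=st.floats(1, 3000))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_value(self, v1, v2):
        lo, hi = sorted((v1, v2))
        assert ctc_grade(lo, 30.0, 200.0, self.RULE) <= \
            ctc_grade(hi, 30.0, 200.0, self.RULE)


# ---------------------------------------------------------------------------
# visit_box_stats
# ---------------------------------------------------------------------------

class TestVisitBoxStats:
    def test_worked_example(self):
        trial = _one_visit_trial([1, 2, 3, 4, 100])
        (box,) = [b for b in visit_box_stats(trial, "P") if b.n > 0]
        assert box.q1 == 2 and box.median == 3 and box.q3 == 4
        assert box.whisker_hi == 4  # fence at 4 + 3 = 7; last point within is 4
        assert box.outlier_values == [100.0]

    def test_single_value_degenerate(self):
        trial = _one_visit_trial([7])
        (box,) = [b for b in visit_box_stats(trial, "P") if b.n > 0]
        assert box.median == box.q1 == box.q3 == 7
        assert box.whisker_lo == box.whisker_hi == 7
        assert box.outlier_values == []

    def test_matches_sort_oracle_on_small_integer_sets(self):
        for size in range(1, 6):
            for values in itertools.combinations_with_replacement(range(5), size):
                trial = _one_visit_trial(list(values))
                (box,) = [b for b in visit_box_stats(trial, "P") if b.n > 0]
                want = box_oracle(values)
                assert box.q1 == pytest.approx(want["q1"]), values
                assert box.median == pytest.approx(want["median"]), values
                assert box.q3 == pytest.approx(want["q3"]), values
                assert box.whisker_lo == pytest.approx(want["whisker_lo"])
                assert box.whisker_hi == pytest.approx(want["whisker_hi"])
                assert box.outlier_values == pytest.approx(want["outliers"])

    def test_log_transform_commutes_with_order_statistics(self):
        values = [1.0, 2.0, 5.0, 9.0, 40.0]
        trial_raw = _one_visit_trial(values)
        trial_log = _one_visit_trial(list(np.log(values)))
        (raw,) = [b for b in visit_box_stats(trial_raw, "P") if b.n > 0]
        (logb,) = [b for b in visit_box_stats(trial_log, "P") if b.n > 0]
        assert logb.median == pytest.approx(np.log(raw.median))
        assert logb.q1 == pytest.approx(np.log(raw.q1))
        assert logb.q3 == pytest.approx(np.log(raw.q3))

    def test_empty_visits_kept_with_n_zero(self, small_trial):
        stats = visit_box_stats(small_trial, "CK")
        visits = {s.visit_index for s in stats}
        for arm in small_trial.arms:
            assert {s.visit_index for s in stats if s.arm == arm} == visits
        # drop-out shrinks n over time
        for arm in small_trial.arms:
            per_visit = sorted((s.visit_index, s.n) for s in stats if s.arm == arm)
            assert per_visit[0][1] >= per_visit[-1][1]

    def test_n_counts_subjects_with_values(self, small_trial):
        stats = visit_box_stats(small_trial, "CK")
        labs = small_trial.labs
        arm_of = small_trial.subjects.set_index("subject_id")["arm"]
        for s in stats:
            sub = labs[(labs["param_code"] == "CK")
                       & (labs["visit_index"] == s.visit_index)
                       & (labs["subject_id"].map(arm_of) == s.arm)]
            assert s.n == sub["value"].notna().sum()


# ---------------------------------------------------------------------------
# abnormal_prevalence
# ---------------------------------------------------------------------------

class TestPrevalence:
    def test_simple_percent(self, tiny_trial):
        out = abnormal_prevalence(tiny_trial, "CK", side="high")
        row = out[(out["arm"] == "Active") & (out["visit_index"] == 2)].iloc[0]
        # A1 at 700 (> 200), A2 at 95 -> 1/2 high
        assert row["n"] == 2 and row["n_abnormal"] == 1
        assert row["percent"] == pytest.approx(50.0)

    def test_either_counts_without_double_counting(self, small_trial):
        low = abnormal_prevalence(small_trial, "CK", side="low")
        high = abnormal_prevalence(small_trial, "CK", side="high")
        either = abnormal_prevalence(small_trial, "CK", side="either")
        merged = low.merge(high, on=["arm", "visit_index"],
                           suffixes=("_lo", "_hi")).merge(
            either, on=["arm", "visit_index"])
        assert (merged["n_abnormal"] <=
                merged["n_abnormal_lo"] + merged["n_abnormal_hi"]).all()
        assert (merged["n_abnormal"] >=
                merged[["n_abnormal_lo", "n_abnormal_hi"]].max(axis=1)).all()

    def test_missing_limits_excluded_from_denominator(self):
        trial = _one_visit_trial([10, 20, 30])  # limits all missing
        out = abnormal_prevalence(trial, "P")
        assert (out["n"] == 0).all()


# ---------------------------------------------------------------------------
# select_outlier_subjects
# ---------------------------------------------------------------------------

class TestOutlierSelection:
    def test_strict_multiplier_boundary(self, tiny_trial):
        # A1 peaks at 700 = 3.5x ULN -> selected at multiplier 3
        sel = select_outlier_subjects(tiny_trial, "CK", multiplier=3.0)
        assert set(sel) == {"A1"}
        # at exactly 3.5x the strict rule drops it
        assert select_outlier_subjects(tiny_trial, "CK", multiplier=3.5) == {}

    def test_grade_rule_union(self, tiny_trial):
        rule = GradingRule("CK", "high", (1.0, 1.5, 2.0, 5.0))
        sel = select_outlier_subjects(tiny_trial, "CK", multiplier=10.0,
                                      grade_rule=rule, min_grade=3)
        assert set(sel) == {"A1"}  # 700 = 3.5x ULN -> grade 3
        assert any("grade 3" in r for r in sel["A1"])

    def test_nonpositive_multiplier_rejected(self, tiny_trial):
        with pytest.raises(ValueError):
            select_outlier_subjects(tiny_trial, "CK", multiplier=0.0)


# ---------------------------------------------------------------------------
# shift_pairs / shift_table
# ---------------------------------------------------------------------------

class TestShift:
    def test_pairs_and_classes(self, tiny_trial):
        pairs = shift_pairs(tiny_trial, "CK")
        by_sid = {p.subject_id: p for p in pairs}
        # B2 has no lab data; A1/A2/B1 each have baseline + post
        assert set(by_sid) == {"A1", "A2", "B1"}
        assert by_sid["A1"].post_value == 700.0  # worst case = max
        assert by_sid["A1"].baseline_abnormal == "normal"
        assert by_sid["A1"].post_abnormal == "high"

    def test_last_value_rule(self, tiny_trial):
        pairs = shift_pairs(tiny_trial, "CK", post_rule="last_value")
        by_sid = {p.subject_id: p for p in pairs}
        assert by_sid["A2"].post_value == 95.0

    def test_conservation_against_table(self, small_trial):
        pairs = shift_pairs(small_trial, "CK")
        tab = shift_table(pairs)
        assert int(tab.to_numpy().sum()) == len(pairs)
        # eligible = subjects with baseline and >=1 post-baseline value
        labs = small_trial.labs[small_trial.labs["param_code"] == "CK"]
        eligible = 0
        for sid, grp in labs.groupby("subject_id"):
            if grp["baseline_flag"].any() and (~grp["baseline_flag"]).any():
                eligible += 1
        assert len(pairs) == eligible

    def test_one_pair_per_subject(self, small_trial):
        pairs = shift_pairs(small_trial, "CHOL")
        sids = [p.subject_id for p in pairs]
        assert len(sids) == len(set(sids))
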