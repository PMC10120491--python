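"""Adverse-event statistics: exact-test values against independent oracles,
BH adjustment properties, incidence counting rules, volcano conventions."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmcreport.safety_stats import (ae_incidence, bh_adjust, fisher_two_sided,
                                    order_terms, person_years_by_arm,
                                    rate_ratio, volcano_stats)

# ---------------------------------------------------------------------------
# independent oracles (never call the implementation under test)
# ---------------------------------------------------------------------------

def fisher_oracle(n11, n12, n21, n22):
    """Exact two-sided Fisher p by full enumeration in integer arithmetic."""
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2
    if n == 0:
        return None
    denom = comb(n, c1)
    obs = comb(r1, n11) * comb(r2, c1 - n11)
    total = 0
    for a in range(max(0, c1 - r2), min(c1, r1) + 1):
        mass = comb(r1, a) * comb(r2, c1 - a)
        if mass <= obs:
            total += mass
    return Fraction(total, denom)


def bh_oracle(p):
    """Naive step-up definition: adjusted(i) = min(1, min_{j>=i} m p(j)/j)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank, i in enumerate(order, start=1):
        candidates = [m * p[order[r - 1]] / r for r in range(rank, m + 1)]
        adj[i] = min(1.0, min(candidates))
    return adj


# ---------------------------------------------------------------------------
# fisher_two_sided
# ---------------------------------------------------------------------------

class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((0, 5, 0, 5), 1.0),
        ((5, 0, 0, 5), 2 / 252),   # only a=0 and a=5 as extreme as observed
        ((3, 1, 1, 3), 34 / 70),   # masses {1,16,36,16,1}/70, observed 16/70
    ])
    def test_hand_enumerated_values(self, table, expected):
        assert fisher_two_sided(*table) == pytest.approx(expected, rel=1e-9)

    def test_all_zero_table_undefined(self):
        assert fisher_two_sided(0, 0, 0, 0) is None

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_matches_integer_oracle_on_moderate_tables(self):
        for n11 in range(0, 7):
            for n12 in range(0, 7):
                for n21 in range(0, 7):
                    for n22 in range(0, 7):
                        if n11 + n12 + n21 + n22 == 0:
                            continue
                        got = fisher_two_sided(n11, n12, n21, n22)
                        want = float(fisher_oracle(n11, n12, n21, n22))
                        assert got == pytest.approx(want, rel=1e-9), \
                            (n11, n12, n21, n22)

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 30, size=4)
            if t.sum() == 0:
                continue
            got = fisher_two_sided(*t)
            _, want = fisher_exact(t.reshape(2, 2))
            assert got == pytest.approx(want, rel=1e-6, abs=1e-12), t


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------

class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.04], [0.04]),
        ([0.05, 0.05, 0.05, 0.05], [0.05] * 4),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
    ])
    def test_worked_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.5])
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40)).tolist()
            got = bh_adjust(p)
            want = multipletests(p, method="fdr_bh")[1]
            assert got == pytest.approx(list(want))

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                              allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_properties(self, p):
        adj = bh_adjust(p)
        # never below raw p
        assert all(a >= pi - 1e-12 for a, pi in zip(adj, p))
        # monotone in the rank ordering of the inputs
        order = sorted(range(len(p)), key=lambda i: p[i])
        ranked = [adj[i] for i in order]
        assert all(ranked[i] <= ranked[i + 1] + 1e-12
                   for i in range(len(ranked) - 1))
        # re-adjustment can only move values up (adjusted >= raw applies
        # to the adjusted vector treated as input)
        assert all(b >= a - 1e-12 for a, b in zip(adj, bh_adjust(adj)))


# ---------------------------------------------------------------------------
# rate_ratio
# ---------------------------------------------------------------------------

class TestRateRatio:
    def test_plain_ratio_without_zero_cells(self):
        assert rate_ratio(4, 2.0, 2, 2.0) == pytest.approx(2.0)

    def test_continuity_applied_only_at_zero(self):
        assert rate_ratio(0, 1.0, 2, 1.0) == pytest.approx(0.5 / 2.5)
        assert rate_ratio(1, 1.0, 2, 1.0) == pytest.approx(0.5)

    def test_symmetry(self):
        assert rate_ratio(3, 1.5, 7, 2.5) * rate_ratio(7, 2.5, 3, 1.5) == \
            pytest.approx(1.0, rel=1e-12)

    def test_time_unit_invariance(self):
        base = rate_ratio(5, 2.0, 3, 4.0)
        for k in (0.01, 12.0, 365.25):
            assert rate_ratio(5, 2.0 * k, 3, 4.0 * k) == pytest.approx(base)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio(1, 0.0, 2, 1.0)


# ---------------------------------------------------------------------------
# incidence and ordering
# ---------------------------------------------------------------------------

class TestIncidence:
    def test_subject_level_counting(self, tiny_trial):
        recs = ae_incidence(tiny_trial)
        active = next(r for r in recs if r.arm == "Active")
        # A1 has 3 Nausea episodes -> 1 subject, 3 events
        assert active.n_subjects_with_event == 1
        assert active.n_events == 3
        assert active.n_at_risk == 2
        assert active.percent == pytest.approx(50.0)

    def test_exposure_adjusted_rate(self, tiny_trial):
        recs = ae_incidence(tiny_trial)
        active = next(r for r in recs if r.arm == "Active")
        py = 2 * 100 / 365.25  # both Active subjects dosed days 1..100
        assert active.person_years == pytest.approx(py)
        assert active.rate_per_100py == pytest.approx(100 * 1 / py)

    def test_filters_subset(self, tiny_trial):
        recs = ae_incidence(tiny_trial, filters=lambda ae: ae["ctc_grade"] >= 2)
        active = next(r for r in recs if r.arm == "Active")
        assert active.n_events == 1

    def test_terms_with_no_events_anywhere_omitted(self, small_trial):
        recs = ae_incidence(small_trial)
        by_term = {}
        for r in recs:
            by_term.setdefault(r.preferred_term, []).append(r)
        for term, rs in by_term.items():
            assert sum(r.n_subjects_with_event for r in rs) >= 1


class TestOrderTerms:
    def _records(self, percents_by_term_arm):
        from dmcreport.safety_stats import IncidenceRecord
        out = []
        for term, by_arm in percents_by_term_arm.items():
            for arm, pct in by_arm.items():
                out.append(IncidenceRecord(term, "SOC", arm, 0, 100, pct,
                                           0, 10.0, None))
        return out

    def test_descending_by_chosen_arm(self):
        recs = self._records({"A": {"X": 10, "P": 1}, "B": {"X": 30, "P": 1},
                              "C": {"X": 20, "P": 1}})
        assert order_terms(recs, by_arm="X") == ["B", "C", "A"]

    def test_tie_broken_by_other_arm(self):
        recs = self._records({"A": {"X": 10, "P": 5}, "B": {"X": 10, "P": 8}})
        assert order_terms(recs, by_arm="X") == ["B", "A"]

    def test_full_tie_alphabetical(self):
        recs = self._records({"B": {"X": 5, "P": 5}, "A": {"X": 5, "P": 5},
                              "C": {"X": 5, "P": 5}})
        assert order_terms(recs, by_arm="X") == ["A", "B", "C"]

    def test_unknown_arm_rejected(self):
        recs = self._records({"A": {"X": 5}})
        with pytest.raises(ValueError):
            order_terms(recs, by_arm="NOPE")


# ---------------------------------------------------------------------------
# volcano_stats
# ---------------------------------------------------------------------------

class TestVolcano:
    def test_identical_incidence_null_point(self, tiny_trial):
        # give both arms the same single-subject incidence
        trial = tiny_trial.copy()
        recs = volcano_stats(trial, "Active", "Placebo")
        nausea = next(r for r in recs if r.preferred_term == "Nausea")
        assert nausea.estimate == pytest.approx(0.0)
        assert nausea.p_value == pytest.approx(1.0)
        assert not nausea.labeled

    def test_single_term_fdr_equals_p(self, tiny_trial):
        recs = volcano_stats(tiny_trial, "Active", "Placebo")
        assert len(recs) == 1
        assert recs[0].fdr_p == recs[0].p_value

    def test_conservation(self, small_trial):
        for r in volcano_stats(small_trial, "Active", "Placebo"):
            assert r.n_event_a + (r.n_a - r.n_event_a) == r.n_a
            assert 0 <= r.n_event_a <= r.n_a
            assert 0 <= r.n_event_b <= r.n_b

    def test_arm_swap_antisymmetry(self, small_trial):
        fwd = volcano_stats(small_trial, "Active", "Placebo")
        rev = volcano_stats(small_trial, "Placebo", "Active")
        f = {r.preferred_term: r for r in fwd}
        b = {r.preferred_term: r for r in rev}
        assert set(f) == set(b)
        for term in f:
            assert f[term].estimate == -b[term].estimate
            assert f[term].p_value == b[term].p_value

    def test_rate_ratio_mode_swap_inverts(self, small_trial):
        fwd = volcano_stats(small_trial, "Active", "Placebo",
                            estimate_kind="rate_ratio")
        rev = volcano_stats(small_trial, "Placebo", "Active",
                            estimate_kind="rate_ratio")
        b = {r.preferred_term: r for r in rev}
        for r in fwd:
            assert r.estimate * b[r.preferred_term].estimate == \
                pytest.approx(1.0, rel=1e-12)

    def test_top_k_label_rule(self, small_trial):
        recs = volcano_stats(small_trial, "Active", "Placebo",
                             label_rule={"top_k": 2})
        assert sum(r.labeled for r in recs) == min(2, len(recs))
        labeled_p = sorted(r.p_value for r in recs if r.labeled)
        unlabeled_p = [r.p_value for r in recs if not r.labeled]
        assert all(lp <= up for lp in labeled_p for up in unlabeled_p)

    def test_fdr_at_least_raw(self, small_trial):
        for r in volcano_stats(small_trial, "Active", "Placebo"):
            assert r.fdr_p >= r.p_value

    def test_identical_arms_rejected(self, small_trial):
        with pytest.raises(ValueError):
            volcano_stats(small_trial, "Active", "Active")


def test_person_years_scale_with_time_unit(tiny_trial):
    py = person_years_by_arm(tiny_trial)
    assert py["Active"] == pytest.approx(200 / 365.25)
    assert py["Placebo"] == pytest.approx(200 / 365.25)
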