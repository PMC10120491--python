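"""Figure-spec contracts: completeness (no silent dropping), display
conventions, caption self-description, and deterministic rendering."""

import hashlib

import pytest

from dmcreport.figures import (fig_abnormal_prevalence, fig_ae_dotplot,
                               fig_demographics, fig_lab_boxes, fig_shift_scatter,
                               fig_spaghetti, fig_volcano, render_figure)
from dmcreport.lab_flags import (abnormal_prevalence, select_outlier_subjects,
                                 shift_pairs, visit_box_stats)
from dmcreport.safety_stats import ae_incidence, order_terms, volcano_stats


class TestDemographics:
    def test_binary_variable_single_category(self, small_trial):
        spec = fig_demographics(small_trial, ["sex"])
        (panel,) = spec.panels
        assert panel["geometry"] == "bar"
        assert [r["arm"] for r in panel["records"]] == list(small_trial.arms)
        assert {r["category"] for r in panel["records"]} == {"F"}

    def test_no_p_value_annotations_anywhere(self, small_trial):
        spec = fig_demographics(small_trial, ["age", "sex"])
        assert spec.annotations() == []
        assert "p-value" not in str(spec.panels).lower()
        assert "No significance tests" in spec.caption

    def test_continuous_variable_has_mean_and_median(self, small_trial):
        spec = fig_demographics(small_trial, ["age"])
        for rec in spec.panels[0]["records"]:
            assert rec["mean"] != rec["median"] or rec["n"] <= 1
            assert rec["q1"] <= rec["median"] <= rec["q3"]

    def test_unknown_variable_rejected(self, small_trial):
        with pytest.raises(ValueError, match="unknown"):
            fig_demographics(small_trial, ["shoe_size"])


class TestDotplot:
    def test_point_count_and_order(self, small_trial):
        recs = ae_incidence(small_trial)
        order = order_terms(recs, by_arm="Active")
        spec = fig_ae_dotplot(recs, order)
        panel = spec.panels[0]
        n_terms = len(order)
        n_arms = len({r.arm for r in recs})
        assert len(panel["records"]) == n_terms * n_arms
        assert panel["row_order"] == order

    def test_single_arm_term_drawn_at_zero(self, small_trial):
        recs = ae_incidence(small_trial)
        one_sided = [t for t in {r.preferred_term for r in recs}
                     if sum(x.n_subjects_with_event > 0 for x in recs
                            if x.preferred_term == t) == 1]
        spec = fig_ae_dotplot(recs, order_terms(recs, by_arm="Active"))
        if one_sided:
            t = one_sided[0]
            pts = [r for r in spec.panels[0]["records"] if r["term"] == t]
            assert len(pts) == 2 and min(p["x"] for p in pts) == 0.0

    def test_exposure_adjusted_toggles_metric(self, small_trial):
        recs = ae_incidence(small_trial)
        order = order_terms(recs, by_arm="Active")
        plain = fig_ae_dotplot(recs, order, exposure_adjusted=False)
        adj = fig_ae_dotplot(recs, order, exposure_adjusted=True)
        assert "person-years" in adj.panels[0]["x_label"]
        assert "person-years" not in plain.panels[0]["x_label"]
        assert "person-years" in adj.caption


class TestVolcano:
    def test_only_labeled_records_annotated(self, small_trial):
        recs = volcano_stats(small_trial, "Active", "Placebo")
        spec = fig_volcano(recs)
        labeled_terms = {r.preferred_term for r in recs if r.labeled}
        assert set(spec.annotations()) == labeled_terms

    def test_fdr_y_never_above_raw_y(self, small_trial):
        recs = volcano_stats(small_trial, "Active", "Placebo")
        y_p = {r["term"]: r["y"] for r in fig_volcano(recs, "p").panels[0]["records"]}
        y_f = {r["term"]: r["y"]
               for r in fig_volcano(recs, "fdr_p").panels[0]["records"]}
        for term in y_p:
            assert y_f[term] <= y_p[term] + 1e-12

    def test_reference_line_matches_estimate_kind(self, small_trial):
        rd = fig_volcano(volcano_stats(small_trial, "Active", "Placebo"))
        assert rd.panels[0]["reference_x"] == 0.0 and not rd.panels[0]["log_x"]
        rr = fig_volcano(volcano_stats(small_trial, "Active", "Placebo",
                                       estimate_kind="rate_ratio"))
        assert rr.panels[0]["reference_x"] == 1.0 and rr.panels[0]["log_x"]

    def test_caption_names_test_and_adjustment(self, small_trial):
        recs = volcano_stats(small_trial, "Active", "Placebo")
        assert "Fisher exact" in fig_volcano(recs).caption
        assert "Benjamini-Hochberg" in fig_volcano(recs, "fdr_p").caption


class TestLabBoxes:
    def test_annotation_row_complete_including_zero(self, small_trial):
        stats = visit_box_stats(small_trial, "CK")
        spec = fig_lab_boxes(stats)
        ann = spec.panels[0]["annotations"]
        assert len(ann) == len(stats)
        for a, s in zip(ann, sorted(stats, key=lambda s: (
                s.visit_index, list(small_trial.arms).index(s.arm)))):
            assert a["n"] == s.n

    def test_caption_states_whisker_rule(self, small_trial):
        spec = fig_lab_boxes(visit_box_stats(small_trial, "CK"))
        assert "1.5 times the interquartile range" in spec.caption

    def test_visits_in_schedule_order_even_if_shuffled(self, small_trial):
        stats = visit_box_stats(small_trial, "CK")
        spec = fig_lab_boxes(list(reversed(stats)))
        assert spec.panels[0]["visit_order"] == sorted(
            {s.visit_index for s in stats})


class TestPrevalenceFigure:
    def test_records_match_input(self, small_trial):
        prev = abnormal_prevalence(small_trial, "CK")
        spec = fig_abnormal_prevalence(prev, "CK")
        assert len(spec.panels[0]["records"]) == len(prev)


class TestSpaghetti:
    def test_annotations_equal_selected(self, small_trial):
        sel = select_outlier_subjects(small_trial, "CK", 3.0)
        spec = fig_spaghetti(small_trial, "CK", set(sel), show_limits=False)
        assert set(spec.annotations()) == set(sel)
        drawn = {r["subject_id"] for r in spec.panels[0]["records"]}
        with_data = set(small_trial.labs.loc[
            small_trial.labs["param_code"] == "CK", "subject_id"])
        assert drawn == with_data  # context lines keep everyone

    def test_subject_specific_limits_suppress_lines(self, small_trial):
        spec = fig_spaghetti(small_trial, "CK", set(), show_limits=True)
        assert spec.panels[0]["reference_lines"] == []
        assert "omitted because the limits differ" in spec.caption

    def test_common_limits_draw_lines(self, small_trial):
        spec = fig_spaghetti(small_trial, "CHOL", set(), show_limits=True)
        labels = {l["label"] for l in spec.panels[0]["reference_lines"]}
        assert labels == {"LLN", "ULN"}

    def test_empty_selection_all_context(self, small_trial):
        spec = fig_spaghetti(small_trial, "CK", set())
        assert spec.annotations() == []
        assert not any(r["selected"] for r in spec.panels[0]["records"])


class TestShiftScatter:
    def test_point_count_equals_pair_count(self, small_trial):
        pairs = shift_pairs(small_trial, "CHOL")
        spec = fig_shift_scatter(pairs, 2.8, 7.0)
        assert len(spec.panels[0]["records"]) == len(pairs)

    def test_limit_lines_partition_plane(self, small_trial):
        pairs = shift_pairs(small_trial, "CHOL")
        spec = fig_shift_scatter(pairs, 2.8, 7.0)
        lines = spec.panels[0]["reference_lines"]
        assert {(l["axis"], l["value"]) for l in lines} == \
            {("x", 2.8), ("x", 7.0), ("y", 2.8), ("y", 7.0)}
        # a (normal, high) pair falls in the corresponding cell
        for p, rec in zip(pairs, spec.panels[0]["records"]):
            if p.baseline_abnormal == "normal" and p.post_abnormal == "high":
                assert 2.8 <= rec["x"] <= 7.0 and rec["y"] > 7.0

    def test_missing_limits_suppressed_with_note(self, small_trial):
        pairs = shift_pairs(small_trial, "CK")
        spec = fig_shift_scatter(pairs, None, None)
        assert spec.panels[0]["reference_lines"] == []
        assert "omitted" in spec.caption


class TestRendering:
    def test_svg_rendering_deterministic(self, small_trial, tmp_path):
        recs = volcano_stats(small_trial, "Active", "Placebo")
        spec = fig_volcano(recs)
        h = []
        for run in ("a", "b"):
            files = render_figure(spec, tmp_path / run / "volcano",
                                  formats=("svg",))
            svg = next(f for f in files if f.suffix == ".svg")
            h.append(hashlib.sha256(svg.read_bytes()).hexdigest())
        assert h[0] == h[1]

    def test_backing_csv_written_next_to_image(self, small_trial, tmp_path):
        spec = fig_demographics(small_trial, ["age", "sex"])
        files = render_figure(spec, tmp_path / "demo")
        suffixes = {f.suffix for f in files}
        assert suffixes == {".svg", ".png", ".csv"}
        csv = next(f for f in files if f.suffix == ".csv")
        assert csv.stat().st_size > 0
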