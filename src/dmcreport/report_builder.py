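"""Assembly of the single, continuously page-numbered DMC report.

The report follows a deliberate reviewer-first structure:

1. front matter — protocol synopsis, new amendments, previous DMC
   recommendations, a summary of previously noted safety imbalances, and
   (when a previous run's manifest is supplied) what has changed since;
2. baseline — graphical demographics plus a selected subset of medical
   history and concomitant medication;
3. adverse events — the overview dot plot (exposure-adjusted on request),
   a volcano display per configured arm comparison, the AESI incidence
   table, and the list of subjects with grade >= 3 events;
4. laboratory — per parameter the distribution-over-time and
   abnormal-prevalence displays, spaghetti plots for flagged parameters,
   optionally the shift scatter;
5. vitals — the same operators applied to the vitals parameter list;
6. appendix — detailed AE/SAE and conmed listings;

followed by the one-page patient profiles.  Every section gets a table of
contents entry with the page it starts on; empty inputs produce explicit
"no events" statements rather than silently absent sections.

Two renderings come from one intermediate representation: hyperlinked
HTML (anchor TOC) and paginated plain text with computed page numbers
(the TOC integrity checks run against the latter).  A manifest (JSON)
records every emitted artifact with input hashes plus the subject/event
inventories that the what-has-changed comparison consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import lab_flags, safety_stats
from .figures import (FigureSpec, fig_abnormal_prevalence, fig_ae_dotplot,
                      fig_demographics, fig_lab_boxes, fig_shift_scatter,
                      fig_spaghetti, fig_volcano, provenance_hash,
                      render_figure)
from .lab_flags import GradingRule, default_grading_rules
from .patient_profile import PatientProfile, build_profile, select_profile_subjects
from .trial_data import TrialData

__all__ = [
    "ReportConfig",
    "Report",
    "Section",
    "build_report",
    "render_text",
    "render_html",
    "diff_since_previous",
    "format_profile",
]

MANIFEST_VERSION = 1
PAGE_LINES = 50  # lines per page in the paginated text rendering


@dataclass
class LabParamConfig:
    param_code: str
    log_scale: bool = False
    side: str = "either"
    direction: str = "high"
    spaghetti_multiplier: float = 3.0
    include_shift_scatter: bool = False


@dataclass
class ReportConfig:
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    demographics_variables: list[str] = field(default_factory=lambda: ["age", "sex"])
    aesi_terms: list[str] = field(default_factory=list)
    lab_params: list[LabParamConfig] = field(default_factory=list)
    vitals_params: list[LabParamConfig] = field(default_factory=list)
    front_matter: dict = field(default_factory=dict)
    include_vitals: bool = True
    include_appendix: bool = True
    efficacy_placeholder: str | None = None
    label_rule: dict = field(default_factory=lambda: {"p_cutoff": 0.05})
    estimate_kind: str = "risk_difference"
    exposure_adjusted: bool = False
    blind_arms: bool = False
    grading_rules: dict[str, GradingRule] = field(default_factory=default_grading_rules)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReportConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        lab = [LabParamConfig(**p) for p in raw.pop("lab_params", [])]
        vit = [LabParamConfig(**p) for p in raw.pop("vitals_params", [])]
        rules = {code: GradingRule(param_code=code, **spec)
                 for code, spec in raw.pop("grading_rules", {}).items()}
        comps = [tuple(c) for c in raw.pop("comparisons", [])]
        cfg = cls(comparisons=comps, lab_params=lab, vitals_params=vit, **raw)
        if rules:
            cfg.grading_rules = rules
        return cfg


@dataclass
class Section:
    section_id: str
    title: str
    lines: list[str] = field(default_factory=list)
    figures: list[tuple[str, FigureSpec]] = field(default_factory=list)

    def text(self, note: str) -> None:
        self.lines.append(note)

    def figure(self, name: str, spec: FigureSpec) -> None:
        self.figures.append((name, spec))
        self.lines.append(f"[Figure {name}] {spec.caption}")

    def table(self, df: pd.DataFrame, title: str) -> None:
        self.lines.append(f"Table: {title}")
        if df.empty:
            self.lines.append("  (no entries)")
        else:
            for line in df.to_string(index=False).splitlines():
                self.lines.append("  " + line)


@dataclass
class Report:
    title: str
    sections: list[Section]
    profiles: list[PatientProfile]
    manifest: dict


def _check_config(trial: TrialData, config: ReportConfig) -> None:
    for a, b in config.comparisons:
        for arm in (a, b):
            if arm not in trial.arms:
                raise ValueError(
                    f"comparison references arm {arm!r} absent from trial arms "
                    f"{list(trial.arms)}")
    lab_codes = set(trial.labs["param_code"].unique()) if not trial.labs.empty else set()
    for p in config.lab_params:
        if p.param_code not in lab_codes:
            raise ValueError(f"lab parameter {p.param_code!r} absent from data")


def _blind(trial: TrialData) -> TrialData:
    mapping = {arm: f"Arm {chr(65 + i)}" for i, arm in enumerate(trial.arms)}
    out = trial.copy()
    out.subjects["arm"] = out.subjects["arm"].map(mapping)
    out.exposure["dose_label"] = out.exposure["dose_label"].map(
        lambda v: mapping.get(v, v))
    out.arms = [mapping[a] for a in trial.arms]
    out.reference_arm = mapping.get(trial.reference_arm, trial.reference_arm)
    return out


def _lab_section_blocks(section: Section, trial: TrialData,
                        params: Sequence[LabParamConfig],
                        grading_rules: dict[str, GradingRule],
                        prefix: str) -> dict[str, list[str]]:
    """Shared machinery for the laboratory and vitals sections."""
    flagged: dict[str, list[str]] = {}
    if trial.labs.empty:
        section.text("No measurements available at this data cut.")
        return flagged
    if not params:
        section.text("No parameters configured for this section.")
        return flagged
    for p in params:
        stats = lab_flags.visit_box_stats(trial, p.param_code, log_scale=p.log_scale)
        section.figure(f"{prefix}_{p.param_code}_boxes",
                       fig_lab_boxes(stats, log_scale=p.log_scale))
        prev = lab_flags.abnormal_prevalence(trial, p.param_code, side=p.side)
        section.figure(f"{prefix}_{p.param_code}_prevalence",
                       fig_abnormal_prevalence(prev, p.param_code, side=p.side))
        selected = lab_flags.select_outlier_subjects(
            trial, p.param_code, multiplier=p.spaghetti_multiplier,
            grade_rule=grading_rules.get(p.param_code), min_grade=3)
        flagged[p.param_code] = sorted(selected)
        if selected:
            section.figure(f"{prefix}_{p.param_code}_spaghetti",
                           fig_spaghetti(trial, p.param_code, selected,
                                         show_limits=True,
                                         multiplier_note=p.spaghetti_multiplier))
            section.text(f"{p.param_code}: {len(selected)} subject(s) flagged "
                         f"(> {p.spaghetti_multiplier:g}x ULN or grade >= 3): "
                         + ", ".join(f"{sid} ({'; '.join(selected[sid])})"
                                     for sid in sorted(selected)))
        else:
            section.text(f"{p.param_code}: no subject exceeded "
                         f"{p.spaghetti_multiplier:g}x ULN or reached grade 3; "
                         "no individual trajectories to display.")
        if p.include_shift_scatter:
            pairs = lab_flags.shift_pairs(trial, p.param_code,
                                          direction=p.direction)
            if pairs:
                sub = trial.labs[trial.labs["param_code"] == p.param_code]
                lln = sub["lln"].dropna().unique()
                uln = sub["uln"].dropna().unique()
                common = len(lln) == 1 and len(uln) == 1
                section.figure(
                    f"{prefix}_{p.param_code}_shift",
                    fig_shift_scatter(pairs,
                                      float(lln[0]) if common else None,
                                      float(uln[0]) if common else None))
                tab = lab_flags.shift_table(pairs)
                section.table(tab.reset_index(),
                              f"{p.param_code} shift cross-tabulation "
                              "(same pairs as the scatter)")
            else:
                section.text(f"{p.param_code}: no subject has both a baseline "
                             "and a post-baseline value; shift display omitted.")
    return flagged


def build_report(
    trial: TrialData,
    config: ReportConfig | None = None,
    out_dir: str | Path | None = None,
    previous_manifest: dict | None = None,
) -> Report:
    """Assemble the full report; optionally render figures into ``out_dir``.

    Raises a config error (ValueError) before any rendering when a
    comparison references an unknown arm or a configured lab parameter is
    absent from the data.
    """
    config = config or ReportConfig()
    if not config.comparisons:
        ref = trial.reference_arm
        config.comparisons = [(a, ref) for a in trial.arms if a != ref]
    _check_config(trial, config)
    if config.blind_arms:
        trial = _blind(trial)
        config.comparisons = [
            (f"Arm {chr(65 + i)}", trial.arms[-1])
            for i, a in enumerate(trial.arms[:-1])]

    sections: list[Section] = []

    # (i) front matter ---------------------------------------------------
    fm = config.front_matter
    front = Section("front_matter", "Front matter")
    front.text("Protocol synopsis: "
               + fm.get("protocol_synopsis", "(not supplied)"))
    amendments = fm.get("amendments", [])
    front.text("New protocol amendments since the previous review: "
               + ("; ".join(amendments) if amendments else "none reported."))
    recs = fm.get("previous_recommendations", [])
    front.text("Previous DMC recommendations: "
               + ("; ".join(recs) if recs else "none on record."))
    imb = fm.get("previous_imbalances", [])
    front.text("Safety imbalances noted at the previous DMC review: "
               + ("; ".join(imb) if imb else "none noted."))
    sections.append(front)

    # (ii) baseline ------------------------------------------------------
    baseline = Section("baseline", "Baseline characteristics")
    baseline.figure("demographics",
                    fig_demographics(trial, config.demographics_variables))
    if not trial.medhistory.empty:
        top = (trial.medhistory.groupby("term")["subject_id"].nunique()
               .sort_values(ascending=False).head(10).reset_index())
        top.columns = ["term", "n_subjects"]
        baseline.table(top, "Most frequent medical history terms (selected subset)")
    else:
        baseline.text("No medical history records supplied.")
    if not trial.conmeds.empty:
        top = (trial.conmeds.groupby("term")["subject_id"].nunique()
               .sort_values(ascending=False).head(10).reset_index())
        top.columns = ["term", "n_subjects"]
        baseline.table(top, "Most frequent concomitant medications (selected subset)")
    else:
        baseline.text("No concomitant medication records supplied.")
    sections.append(baseline)

    # (iii) adverse events -----------------------------------------------
    ae_sec = Section("adverse_events", "Adverse events")
    incidence = safety_stats.ae_incidence(trial)
    volcano_by_comparison: dict[str, list] = {}
    if not incidence:
        ae_sec.text("No treatment-emergent adverse events have been "
                    "reported at this data cut.")
    else:
        order = safety_stats.order_terms(incidence, by_arm=trial.arms[0],
                                         exposure_adjusted=config.exposure_adjusted)
        ae_sec.figure("ae_dotplot",
                      fig_ae_dotplot(incidence, order,
                                     exposure_adjusted=config.exposure_adjusted))
        for arm_a, arm_b in config.comparisons:
            recs = safety_stats.volcano_stats(
                trial, arm_a, arm_b, estimate_kind=config.estimate_kind,
                label_rule=config.label_rule)
            volcano_by_comparison[f"{arm_a} vs {arm_b}"] = recs
            if recs:
                ae_sec.figure(f"volcano_{arm_a}_vs_{arm_b}".replace(" ", "_"),
                              fig_volcano(recs))
            else:
                ae_sec.text(f"{arm_a} vs {arm_b}: no term with events in "
                            "either arm; volcano display omitted.")
    if config.aesi_terms:
        aesi = [r for r in incidence if r.preferred_term in config.aesi_terms]
        df = pd.DataFrame([vars(r) for r in aesi])
        ae_sec.table(df, "Adverse events of special interest")
    else:
        aesi_flagged = (trial.adverse_events[trial.adverse_events["aesi_flag"]]
                        if not trial.adverse_events.empty else pd.DataFrame())
        if not aesi_flagged.empty:
            terms = sorted(aesi_flagged["preferred_term"].unique())
            df = pd.DataFrame([vars(r) for r in incidence
                               if r.preferred_term in terms])
            ae_sec.table(df, "Adverse events of special interest")
        else:
            ae_sec.text("No adverse events of special interest defined or "
                        "observed.")
    grade3 = (trial.adverse_events[trial.adverse_events["ctc_grade"] >= 3]
              if not trial.adverse_events.empty else pd.DataFrame())
    if grade3.empty:
        ae_sec.text("No adverse events of CTC grade 3 or higher have been "
                    "reported.")
    else:
        df = grade3[["subject_id", "preferred_term", "onset_day", "ctc_grade",
                     "serious_flag"]].sort_values(["subject_id", "onset_day"])
        ae_sec.table(df, "Subjects with CTC grade >= 3 adverse events")
    sections.append(ae_sec)

    # (iv) laboratory ----------------------------------------------------
    lab_sec = Section("laboratory", "Laboratory data")
    flagged = _lab_section_blocks(lab_sec, trial, config.lab_params,
                                  config.grading_rules, "lab")
    sections.append(lab_sec)

    # (v) vitals ---------------------------------------------------------
    if config.include_vitals:
        vit_sec = Section("vitals", "Vital signs")
        _lab_section_blocks(vit_sec, trial, config.vitals_params,
                            config.grading_rules, "vitals")
        if not config.vitals_params:
            vit_sec.lines = ["No vital-sign parameters configured for this "
                             "report."]
        sections.append(vit_sec)

    # efficacy placeholder ------------------------------------------------
    if config.efficacy_placeholder is not None:
        eff = Section("efficacy", "Efficacy (placeholder)")
        eff.text(config.efficacy_placeholder)
        eff.text("Note: no efficacy statistics are computed by this report. "
                 "The handling of interim efficacy looks and any multiplicity "
                 "adjustment should be clearly spelled out in the DMC charter.")
        sections.append(eff)

    # profiles -----------------------------------------------------------
    prof_sec = Section("profiles", "Patient profiles")
    selected = select_profile_subjects(trial, config.grading_rules)
    profiles = [build_profile(trial, sid, config.grading_rules)
                for sid in sorted(selected)]
    if profiles:
        prof_sec.text(f"{len(profiles)} subject(s) selected for detailed "
                      "review (serious AE, grade >= 3 AE, or grade >= 3 "
                      "laboratory value): "
                      + ", ".join(p.subject_id for p in profiles))
    else:
        prof_sec.text("No subject met the profile selection criteria "
                      "(serious AE, grade >= 3 AE, or grade >= 3 laboratory "
                      "value).")
    sections.append(prof_sec)

    # (vi) appendix ------------------------------------------------------
    if config.include_appendix:
        app = Section("appendix", "Appendix: detailed listings")
        if trial.adverse_events.empty:
            app.text("No adverse events to list.")
        else:
            df = trial.adverse_events.sort_values(
                ["subject_id", "onset_day", "preferred_term"])
            app.table(df[["subject_id", "preferred_term", "system_organ_class",
                          "onset_day", "ctc_grade", "serious_flag"]],
                      "All adverse events")
            sae = df[df["serious_flag"]]
            if sae.empty:
                app.text("No serious adverse events to list.")
            else:
                app.table(sae[["subject_id", "preferred_term", "onset_day",
                               "ctc_grade"]], "Serious adverse events")
        if trial.conmeds.empty:
            app.text("No concomitant medications to list.")
        else:
            app.table(trial.conmeds.sort_values(["subject_id", "start_day"]),
                      "All concomitant medications")
        sections.append(app)

    manifest = _build_manifest(trial, config, sections, flagged,
                               sorted(selected), volcano_by_comparison)

    if previous_manifest is not None:
        changes = diff_since_previous(manifest, previous_manifest)
        front.lines.insert(0, _format_changes(changes))

    report = Report(title="DMC safety report", sections=sections,
                    profiles=profiles, manifest=manifest)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fig_dir = out_dir / "figures"
        for sec in sections:
            for name, spec in sec.figures:
                render_figure(spec, fig_dir / name)
        (out_dir / "report.txt").write_text(render_text(report))
        (out_dir / "report.html").write_text(render_html(report))
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        prof_dir = out_dir / "profiles"
        if profiles:
            prof_dir.mkdir(exist_ok=True)
            for p in profiles:
                (prof_dir / f"{p.subject_id}.txt").write_text(
                    "\n".join(_profile_lines(p)) + "\n")
    return report


def _build_manifest(trial, config, sections, flagged, profile_subjects,
                    volcano_by_comparison) -> dict:
    ae = trial.adverse_events
    ae_events = ([] if ae.empty else
                 sorted([str(r["subject_id"]), str(r["preferred_term"]),
                         int(r["onset_day"])] for _, r in ae.iterrows()))
    artifacts = []
    for sec in sections:
        for name, spec in sec.figures:
            artifacts.append(dict(section=sec.section_id, name=name,
                                  kind=spec.kind,
                                  input_hash=spec.provenance.get("inputs")))
    return dict(
        version=MANIFEST_VERSION,
        title="DMC safety report",
        arms=list(trial.arms),
        reference_arm=trial.reference_arm,
        cutoff_day=trial.cutoff_day,
        sections=[dict(id=s.section_id, title=s.title) for s in sections],
        subject_ids=sorted(trial.subjects["subject_id"].astype(str)),
        ae_events=ae_events,
        lab_outliers={k: sorted(v) for k, v in flagged.items()},
        profile_subjects=list(profile_subjects),
        comparisons=[list(c) for c in config.comparisons],
        input_hash=provenance_hash(trial.subjects, trial.adverse_events,
                                   trial.labs, trial.exposure),
    )


def _format_changes(changes: dict) -> str:
    bits = []
    for key, label in [("new_subjects", "new subjects"),
                       ("new_ae_by_term", "new adverse events"),
                       ("new_lab_outliers", "newly flagged lab outliers"),
                       ("new_profile_subjects", "newly selected profile subjects")]:
        val = changes.get(key)
        if not val:
            continue
        if isinstance(val, dict):
            bits.append(label + ": " + "; ".join(
                f"{k} ({', '.join(map(str, v)) if isinstance(v, list) else v})"
                for k, v in sorted(val.items())))
        else:
            bits.append(label + ": " + ", ".join(map(str, val)))
    if not bits:
        return ("Changes since the previous DMC data cut: none — the data "
                "are unchanged.")
    return "Changes since the previous DMC data cut: " + " | ".join(bits)


def diff_since_previous(current: dict, previous: dict) -> dict:
    """What is new at this data cut relative to a previous run's manifest."""
    if current.get("version") != previous.get("version"):
        raise ValueError("manifest version mismatch")
    cur_subj, prev_subj = set(current["subject_ids"]), set(previous["subject_ids"])
    cur_ae = {tuple(e) for e in current["ae_events"]}
    prev_ae = {tuple(e) for e in previous["ae_events"]}
    new_ae_by_term: dict[str, list[str]] = {}
    for sid, term, _day in sorted(cur_ae - prev_ae):
        new_ae_by_term.setdefault(term, []).append(sid)
    new_outliers: dict[str, list[str]] = {}
    for param, sids in current.get("lab_outliers", {}).items():
        prev_sids = set(previous.get("lab_outliers", {}).get(param, []))
        fresh = sorted(set(sids) - prev_sids)
        if fresh:
            new_outliers[param] = fresh
    return dict(
        new_subjects=sorted(cur_subj - prev_subj),
        new_ae_by_term=new_ae_by_term,
        new_lab_outliers=new_outliers,
        new_profile_subjects=sorted(
            set(current.get("profile_subjects", []))
            - set(previous.get("profile_subjects", []))),
    )


# ---------------------------------------------------------------------------
# renderings
# ---------------------------------------------------------------------------

def _profile_lines(p: PatientProfile) -> list[str]:
    lines = [f"--- Patient profile: {p.subject_id} ---"]
    d = p.demographics
    lines.append(f"Demographics: arm={d['arm']}, age={d['age']}, sex={d['sex']}, "
                 f"race={d.get('race')}, country={d.get('country')}")
    lines.append("Medical history: "
                 + ("; ".join(p.medhistory) if p.medhistory else "none recorded")
                 + (f" (+{p.medhistory_more} more)" if p.medhistory_more else ""))
    if p.conmeds:
        cm = "; ".join(f"{c['term']} (day {c['start_day']}-"
                       f"{c['end_day'] if c['end_day'] is not None else 'ongoing'})"
                       for c in p.conmeds)
        lines.append("Concomitant medication: " + cm
                     + (f" (+{p.conmeds_more} more)" if p.conmeds_more else ""))
    else:
        lines.append("Concomitant medication: none recorded")
    for e in p.exposure:
        lines.append(f"Treatment: {e['dose_label']} day {e['start_day']}-"
                     f"{e['end_day']}")
    if p.adverse_events:
        for a in p.adverse_events:
            res = a["resolution_day"] if a["resolution_day"] is not None else "ongoing"
            lines.append(f"AE: {a['preferred_term']} onset day {a['onset_day']}, "
                         f"resolution {res}, grade {a['ctc_grade']}"
                         + (", SERIOUS" if a["serious"] else ""))
    else:
        lines.append("AE: none reported")
    if p.labs:
        for l in p.labs:
            base = f"{l.baseline_value:g}" if l.baseline_value is not None else "NA"
            grade = l.worst_grade if l.worst_grade is not None else "NA"
            lines.append(f"Lab {l.param_code}: baseline {base}, worst "
                         f"{l.worst_value:g} (day {l.worst_day}, grade {grade}), "
                         f"last {l.last_value:g} (day {l.last_day})")
    else:
        lines.append("Lab: no abnormal parameters")
    lines.append("Timeline:")
    for e in p.timeline:
        span = (f" to day {e.end_day}" if e.end_day is not None else "")
        lines.append(f"  day {e.day}{span} [{e.track}] {e.label}"
                     + (" (ongoing)" if e.ongoing else ""))
    return lines


def format_profile(profile: PatientProfile) -> str:
    """Plain-text rendering of one patient profile (one page's worth)."""
    return "\n".join(_profile_lines(profile))


def _wrap(line: str, width: int = 90) -> list[str]:
    if len(line) <= width:
        return [line]
    out = []
    while len(line) > width:
        cut = line.rfind(" ", 0, width)
        cut = width if cut <= 0 else cut
        out.append(line[:cut])
        line = line[cut:].lstrip()
    out.append(line)
    return out


def render_text(report: Report) -> str:
    """Paginated plain-text rendering with a page-numbered TOC.

    Every section (and every profile) starts on a fresh page; the TOC at
    the front lists the actual page each section starts on.  Page breaks
    are marked with a footer line ``-- page N --``.
    """
    blocks: list[tuple[str, str, list[str]]] = []  # (id, title, lines)
    for sec in report.sections:
        lines: list[str] = []
        for raw in sec.lines:
            lines.extend(_wrap(raw))
        blocks.append((sec.section_id, sec.title, lines))
        if sec.section_id == "profiles":
            for p in report.profiles:
                plines: list[str] = []
                for raw in _profile_lines(p):
                    plines.extend(_wrap(raw))
                blocks.append((f"profile_{p.subject_id}",
                               f"Profile: {p.subject_id}", plines))

    # A page holds PAGE_LINES-1 content lines plus one footer line.
    capacity = PAGE_LINES - 1

    def n_pages(n_lines: int) -> int:
        return max(1, -(-n_lines // capacity))

    toc_lines_count = 2 + len(blocks)  # title + header + one entry per block
    toc_pages = n_pages(toc_lines_count)
    start_pages: dict[str, int] = {}
    page = toc_pages + 1
    for bid, _title, lines in blocks:
        start_pages[bid] = page
        page += n_pages(2 + len(lines))  # heading + underline + body

    def paginate(content: list[str], out: list[str], pageno: int) -> int:
        for i in range(0, max(len(content), 1), capacity):
            chunk = content[i:i + capacity]
            chunk += [""] * (capacity - len(chunk))
            out.extend(chunk)
            out.append(f"-- page {pageno} --")
            pageno += 1
        return pageno

    toc: list[str] = [report.title, "Table of contents"]
    for bid, title, _ in blocks:
        dots = "." * max(2, 70 - len(title))
        toc.append(f"{title} {dots} {start_pages[bid]}")
    out: list[str] = []
    pageno = paginate(toc, out, 1)
    for bid, title, lines in blocks:
        body = [f"== {title} ==", "=" * (len(title) + 6)] + lines
        pageno = paginate(body, out, pageno)
    return "\n".join(out) + "\n"


def render_html(report: Report) -> str:
    """Single-document HTML rendering with an anchor-linked TOC."""
    def esc(s: str) -> str:
        return (str(s).replace("&", "&amp;").replace("<", "&lt;")
                .replace(">", "&gt;"))

    parts = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
             f"<title>{esc(report.title)}</title></head><body>",
             f"<h1>{esc(report.title)}</h1>", "<h2>Table of contents</h2>",
             "<ul>"]
    for sec in report.sections:
        parts.append(f"<li><a href='#{sec.section_id}'>{esc(sec.title)}</a></li>")
    parts.append("</ul>")
    for sec in report.sections:
        parts.append(f"<h2 id='{sec.section_id}'>{esc(sec.title)}</h2>")
        for line in sec.lines:
            parts.append(f"<p>{esc(line)}</p>")
        if sec.section_id == "profiles":
            for p in report.profiles:
                parts.append(f"<h3 id='profile_{esc(p.subject_id)}'>"
                             f"Profile: {esc(p.subject_id)}</h3>")
                parts.append("<pre>" + esc("\n".join(_profile_lines(p)))
                             + "</pre>")
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"
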