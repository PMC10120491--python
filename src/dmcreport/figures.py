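"""Figure builders for the seven DMC display types.

Each builder turns derived statistics into a :class:`FigureSpec` — a
declarative, renderer-independent description of the display (geometry
records, axis metadata, reference lines, annotations, a self-describing
caption, and a provenance hash of the inputs).  :func:`render_figure`
draws a spec with matplotlib and writes SVG + PNG plus the backing data
as CSV next to the image, so every plotted point is traceable.

Display conventions, fixed across the report:

* one colorblind-safe palette (Okabe-Ito), with arms mapped to the same
  colors in every figure;
* box-whisker panels use linear-interpolation quartiles and whiskers at
  the last data point within 1.5x the interquartile range — stated in
  each caption;
* the demographics display never carries p-values (baseline significance
  testing is deliberately absent);
* rendering is deterministic: fixed SVG hash salt, no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lab_flags import BoxStats, ShiftPair, _box_from_values
from .safety_stats import IncidenceRecord, VolcanoRecord
from .trial_data import TrialData

__all__ = [
    "PALETTE",
    "FigureSpec",
    "fig_demographics",
    "fig_ae_dotplot",
    "fig_volcano",
    "fig_lab_boxes",
    "fig_abnormal_prevalence",
    "fig_spaghetti",
    "fig_shift_scatter",
    "render_figure",
]

# Okabe-Ito, colorblind safe
PALETTE = ("#0072B2", "#D55E00", "#009E73", "#CC79A7", "#E69F00", "#56B4E9")

WHISKER_NOTE = ("Whiskers extend to the last data point within 1.5 times "
                "the interquartile range; points beyond are drawn "
                "individually.")


@dataclass
class FigureSpec:
    kind: str
    panels: list[dict]
    caption: str
    provenance: dict = field(default_factory=dict)

    def annotations(self) -> list[str]:
        out: list[str] = []
        for p in self.panels:
            out.extend(a.get("text", "") for a in p.get("annotations", []))
        return out


def _to_jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    return str(obj)


def provenance_hash(*inputs: Any) -> str:
    payload = json.dumps(_to_jsonable(list(inputs)), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _arm_colors(arms: Sequence[str]) -> dict[str, str]:
    return {arm: PALETTE[i % len(PALETTE)] for i, arm in enumerate(arms)}


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def fig_demographics(trial: TrialData, variables: Sequence[str]) -> FigureSpec:
    """Graphical baseline comparison: horizontal box-whiskers per arm for
    continuous variables (mean marked distinctly from the median), a
    single-category bar per arm for binary variables.  No p-values.
    """
    panels: list[dict] = []
    colors = _arm_colors(trial.arms)
    for var in variables:
        if var not in trial.subjects.columns:
            raise ValueError(f"unknown subject variable {var!r}")
        col = trial.subjects[var]
        if var == "sex" or (col.dtype == object and col.nunique(dropna=True) <= 2):
            cats = sorted(col.dropna().unique())
            shown = "F" if "F" in cats else (cats[0] if cats else "")
            rows = []
            for arm in trial.arms:
                sub = col[trial.subjects["arm"] == arm]
                n = int(sub.notna().sum())
                pct = 100.0 * float((sub == shown).sum()) / n if n else 0.0
                rows.append(dict(arm=arm, category=shown, percent=pct, n=n,
                                 color=colors[arm]))
            panels.append(dict(variable=var, geometry="bar", records=rows,
                               x_label=f"% {shown}", annotations=[]))
        else:
            rows = []
            for arm in trial.arms:
                vals = pd.to_numeric(col[trial.subjects["arm"] == arm],
                                     errors="coerce").dropna().to_numpy(float)
                rec = dict(arm=arm, n=int(vals.size), color=colors[arm])
                if vals.size:
                    rec.update(_box_from_values(vals))
                    rec["mean"] = float(vals.mean())
                rows.append(rec)
            panels.append(dict(variable=var, geometry="box", records=rows,
                               x_label=var, annotations=[]))
    caption = ("Baseline comparison by treatment arm. Boxes cover the second "
               "and third quartile with the line at the median and a dot at "
               f"the mean. {WHISKER_NOTE} For binary variables only one "
               "category is shown. No significance tests are displayed.")
    return FigureSpec("demographics", panels, caption,
                      {"inputs": provenance_hash(trial.subjects, list(variables))})


def fig_ae_dotplot(
    records: Sequence[IncidenceRecord],
    ordering: Sequence[str],
    exposure_adjusted: bool = False,
) -> FigureSpec:
    """Adverse-event overview dot plot: one row per term in the supplied
    order, one dot per arm; x is the subject-level percent or the rate per
    100 person-years when exposure adjusted.  A term absent from an arm is
    drawn at zero incidence."""
    if not records:
        raise ValueError("no incidence records supplied")
    arms = list(dict.fromkeys(r.arm for r in records))
    colors = _arm_colors(arms)
    by_term: dict[str, dict[str, IncidenceRecord]] = {}
    for r in records:
        by_term.setdefault(r.preferred_term, {})[r.arm] = r
    rows = []
    for term in ordering:
        for arm in arms:
            r = by_term.get(term, {}).get(arm)
            if exposure_adjusted:
                x = (r.rate_per_100py if r and r.rate_per_100py is not None else 0.0)
            else:
                x = r.percent if r else 0.0
            rows.append(dict(term=term, arm=arm, x=float(x), color=colors[arm],
                             n_subjects=r.n_subjects_with_event if r else 0))
    x_label = ("Subjects with event per 100 person-years" if exposure_adjusted
               else "Subjects with event (%)")
    panel = dict(geometry="dot", records=rows, row_order=list(ordering),
                 x_label=x_label, arms=arms, annotations=[])
    metric_phrase = ("adjusted for time at risk (rate per 100 person-years)"
                     if exposure_adjusted
                     else "as percentage of the dosed (safety) population")
    caption = ("Adverse event overview: subject-level incidence per preferred "
               f"term and arm, {metric_phrase}; rows ordered as supplied.")
    return FigureSpec("ae_dotplot", [panel], caption,
                      {"inputs": provenance_hash(list(records), list(ordering),
                                                 exposure_adjusted)})


def _greedy_label_positions(points: list[tuple[float, float, str]]) -> list[dict]:
    """Deterministic greedy vertical displacement for label collisions."""
    placed: list[dict] = []
    for x, y, text in sorted(points, key=lambda t: (t[1], t[0], t[2])):
        dy = 0.0
        step = 0.12
        while any(abs(p["y"] + p["dy"] - (y + dy)) < step and
                  abs(p["x"] - x) < 1e-9 for p in placed):
            dy += step
        placed.append(dict(x=x, y=y, dx=0.0, dy=dy, text=text))
    return placed


def fig_volcano(records: Sequence[VolcanoRecord], y_mode: str = "p") -> FigureSpec:
    """Volcano display: per-term effect estimate against -log10 p (raw or
    FDR-adjusted), with a null reference line (0 for risk differences on a
    linear axis, 1 for rate ratios on a log axis) and deterministic label
    placement for the flagged terms."""
    if not records:
        raise ValueError("no volcano records supplied")
    if y_mode not in ("p", "fdr_p"):
        raise ValueError("y_mode must be 'p' or 'fdr_p'")
    kind = records[0].estimate_kind
    log_x = kind == "rate_ratio"
    rows = []
    label_pts = []
    for r in records:
        y = -np.log10(r.p_value if y_mode == "p" else r.fdr_p)
        rows.append(dict(term=r.preferred_term, x=float(r.estimate),
                         y=float(y), labeled=bool(r.labeled),
                         p_value=r.p_value, fdr_p=r.fdr_p,
                         n_event_a=r.n_event_a, n_event_b=r.n_event_b))
        if r.labeled:
            label_pts.append((float(r.estimate), float(y), r.preferred_term))
    panel = dict(
        geometry="scatter", records=rows,
        x_label=("Rate ratio (log scale)" if log_x
                 else "Risk difference (percentage points)"),
        y_label=("-log10 " + ("p-value" if y_mode == "p" else "FDR-adjusted p-value")),
        log_x=log_x, reference_x=1.0 if log_x else 0.0,
        annotations=_greedy_label_positions(label_pts),
    )
    caption = ("Adverse event volcano display: per preferred term, the "
               f"{'exposure-adjusted incidence rate ratio' if log_x else 'risk difference'} "
               "against the two-sided Fisher exact p-value"
               + (" after Benjamini-Hochberg FDR adjustment" if y_mode == "fdr_p" else "")
               + " on a -log10 scale. P-values are descriptive screening "
                 "quantities, not confirmatory tests.")
    return FigureSpec("volcano", [panel], caption,
                      {"inputs": provenance_hash(list(records), y_mode)})


def fig_lab_boxes(stats: Sequence[BoxStats], log_scale: bool = False) -> FigureSpec:
    """Per-visit, per-arm box-whisker panels with the per-visit n
    annotation row (every arm's n at every visit, including n=0)."""
    if not stats:
        raise ValueError("no box statistics supplied")
    arms = list(dict.fromkeys(s.arm for s in stats))
    colors = _arm_colors(arms)
    visits = sorted({s.visit_index for s in stats})
    rows = [dict(**asdict(s), color=colors[s.arm])
            for s in sorted(stats, key=lambda s: (s.visit_index, arms.index(s.arm)))]
    annotations = [dict(visit_index=s.visit_index, arm=s.arm, n=s.n,
                        text=f"n_{s.arm[:1]}={s.n}")
                   for s in sorted(stats, key=lambda s: (s.visit_index,
                                                         arms.index(s.arm)))]
    panel = dict(geometry="box_by_visit", records=rows, visit_order=visits,
                 arms=arms, log_scale=log_scale,
                 x_label="Visit", y_label=stats[0].param_code,
                 annotations=annotations)
    caption = (f"{stats[0].param_code} distribution over time by arm. Boxes "
               f"cover the second and third quartile, line at the median. "
               f"{WHISKER_NOTE} The n row gives the number of subjects with "
               "a value at each visit."
               + (" Values drawn on a logarithmic scale." if log_scale else ""))
    return FigureSpec("lab_boxes", [panel], caption,
                      {"inputs": provenance_hash(list(stats), log_scale)})


def fig_abnormal_prevalence(prevalence: pd.DataFrame, param_code: str,
                            side: str = "either") -> FigureSpec:
    """Percent of evaluable subjects abnormal per visit and arm, with the
    per-visit n annotation row."""
    if prevalence.empty:
        raise ValueError("empty prevalence table")
    arms = list(dict.fromkeys(prevalence["arm"]))
    colors = _arm_colors(arms)
    rows = [dict(arm=r["arm"], visit_index=int(r["visit_index"]), n=int(r["n"]),
                 n_abnormal=int(r["n_abnormal"]),
                 percent=(None if pd.isna(r["percent"]) else float(r["percent"])),
                 color=colors[r["arm"]])
            for _, r in prevalence.iterrows()]
    annotations = [dict(visit_index=r["visit_index"], arm=r["arm"], n=r["n"],
                        text=f"n_{r['arm'][:1]}={r['n']}") for r in rows]
    panel = dict(geometry="prevalence", records=rows, arms=arms,
                 visit_order=sorted({r["visit_index"] for r in rows}),
                 x_label="Visit", y_label=f"% abnormal ({side})",
                 annotations=annotations)
    caption = (f"Abnormal {param_code} values over time ({side} side of the "
               "normal range; a value exactly at a limit counts as normal). "
               "Denominators are subjects with an evaluable value at the "
               "visit; the n row shows them per arm.")
    return FigureSpec("abnormal_prevalence", [panel], caption,
                      {"inputs": provenance_hash(prevalence, param_code, side)})


def fig_spaghetti(
    trial: TrialData,
    param_code: str,
    selected: Iterable[str],
    show_limits: bool = False,
    multiplier_note: float | None = 3.0,
) -> FigureSpec:
    """Individual trajectories for one parameter: all subjects as muted
    context lines, selected subjects colored and annotated with their id.
    Limit-of-normal reference lines are drawn only when the limits are
    common to every subject; otherwise they are suppressed and the caption
    says so."""
    labs = trial.labs[trial.labs["param_code"] == param_code]
    if labs.empty:
        raise ValueError(f"parameter {param_code!r} not present")
    selected = sorted(set(selected))
    have_data = set(labs["subject_id"])
    missing = [s for s in selected if s not in have_data]
    if missing:
        raise ValueError(f"selected subjects without {param_code} data: {missing}")
    rows = []
    colors = {}
    for i, sid in enumerate(selected):
        colors[sid] = PALETTE[i % len(PALETTE)]
    for sid, grp in labs.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        rows.append(dict(
            subject_id=str(sid), selected=sid in colors,
            color=colors.get(sid, "#bbbbbb"),
            days=[int(d) for d in grp["day"]],
            values=[float(v) for v in grp["value"]],
        ))
    lln_vals = labs["lln"].dropna().unique()
    uln_vals = labs["uln"].dropna().unique()
    common_limits = len(lln_vals) <= 1 and len(uln_vals) <= 1
    reference_lines = []
    limit_note = ""
    if show_limits:
        if common_limits:
            if len(lln_vals) == 1:
                reference_lines.append(dict(y=float(lln_vals[0]), label="LLN"))
            if len(uln_vals) == 1:
                reference_lines.append(dict(y=float(uln_vals[0]), label="ULN"))
        else:
            limit_note = (" Reference lines for the limits of normal are "
                          "omitted because the limits differ between "
                          "subjects.")
    annotations = [dict(subject_id=sid, text=sid) for sid in selected]
    panel = dict(geometry="spaghetti", records=rows,
                 reference_lines=reference_lines,
                 x_label="Study day", y_label=param_code,
                 annotations=annotations)
    caption = (f"{param_code} over time per subject. "
               + (f"Trajectories exceeding {multiplier_note:g} times the "
                  "subject's own upper limit of normal are colored and "
                  "annotated with the subject id; "
                  if multiplier_note is not None else "Selected trajectories "
                  "are colored and annotated; ")
               + "all other subjects are shown in gray for context."
               + limit_note)
    return FigureSpec("spaghetti", [panel], caption,
                      {"inputs": provenance_hash(labs, selected, show_limits)})


def fig_shift_scatter(
    pairs: Sequence[ShiftPair],
    lln: float | None,
    uln: float | None,
) -> FigureSpec:
    """Baseline vs post-baseline scatter replacing the classic shift table:
    the identity diagonal plus the limit-of-normal lines on both axes
    partition the plane into the 3x3 shift cells; one point per subject."""
    if not pairs:
        raise ValueError("no shift pairs supplied")
    rows = [dict(subject_id=p.subject_id, x=p.baseline_value, y=p.post_value,
                 baseline_abnormal=p.baseline_abnormal,
                 post_abnormal=p.post_abnormal) for p in pairs]
    have_limits = lln is not None and uln is not None
    reference_lines = []
    if have_limits:
        reference_lines = [dict(axis="x", value=float(lln), label="LLN"),
                           dict(axis="x", value=float(uln), label="ULN"),
                           dict(axis="y", value=float(lln), label="LLN"),
                           dict(axis="y", value=float(uln), label="ULN")]
    note = ("" if have_limits else
            " Limit-of-normal lines are omitted because the limits differ "
            "between subjects.")
    panel = dict(geometry="shift_scatter", records=rows,
                 reference_lines=reference_lines, diagonal=True,
                 x_label="Baseline value", y_label="Post-baseline value",
                 annotations=[])
    caption = (f"Baseline against post-baseline {pairs[0].param_code} per "
               "subject; the diagonal marks no change and the black limit-of-"
               "normal lines partition the plane into the cells of the "
               "classic shift table." + note)
    return FigureSpec("shift_scatter", [panel], caption,
                      {"inputs": provenance_hash(list(pairs), lln, uln)})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_demographics(spec: FigureSpec, axes) -> None:
    for ax, panel in zip(axes, spec.panels):
        recs = panel["records"]
        ypos = np.arange(len(recs))[::-1]
        if panel["geometry"] == "bar":
            ax.barh(ypos, [r["percent"] for r in recs],
                    color=[r["color"] for r in recs])
        else:
            for y, r in zip(ypos, recs):
                if r.get("median") is None:
                    continue
                ax.barh(y, r["q3"] - r["q1"], left=r["q1"], height=0.5,
                        color="none", edgecolor=r["color"])
                ax.plot([r["median"]] * 2, [y - 0.25, y + 0.25], color=r["color"])
                ax.plot([r["whisker_lo"], r["q1"]], [y, y], color=r["color"])
                ax.plot([r["q3"], r["whisker_hi"]], [y, y], color=r["color"])
                ax.plot(r["mean"], y, "o", color="#D55E00", ms=5)
                for v in r["outlier_values"]:
                    ax.plot(v, y, ".", color=r["color"], ms=3)
        ax.set_yticks(ypos)
        ax.set_yticklabels([r["arm"] for r in recs])
        ax.set_xlabel(panel["x_label"])


def _render_dotplot(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    order = panel["row_order"]
    ypos = {t: len(order) - i for i, t in enumerate(order)}
    for r in panel["records"]:
        ax.plot(r["x"], ypos[r["term"]], "o", color=r["color"], ms=5,
                label=r["arm"])
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7, loc="lower right")
    ax.set_yticks([ypos[t] for t in order])
    ax.set_yticklabels(order, fontsize=7)
    ax.set_xlabel(panel["x_label"])
    ax.grid(axis="y", lw=0.3, alpha=0.5)


def _render_volcano(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    xs = [r["x"] for r in panel["records"]]
    ys = [r["y"] for r in panel["records"]]
    ax.scatter(xs, ys, s=18, color="#0072B2", alpha=0.8)
    if panel["log_x"]:
        ax.set_xscale("log")
    ax.axvline(panel["reference_x"], color="0.4", lw=0.8)
    for a in panel["annotations"]:
        ax.annotate(a["text"], (a["x"], a["y"]),
                    xytext=(a["x"] + a["dx"], a["y"] + a["dy"]),
                    fontsize=7)
    ax.set_xlabel(panel["x_label"])
    ax.set_ylabel(panel["y_label"])


def _render_box_by_visit(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    arms = panel["arms"]
    width = 0.8 / max(len(arms), 1)
    visits = panel["visit_order"]
    vx = {v: i for i, v in enumerate(visits)}
    for r in panel["records"]:
        if r["n"] == 0 or r.get("median") is None:
            continue
        x = vx[r["visit_index"]] + (arms.index(r["arm"]) - (len(arms) - 1) / 2) * width
        ax.add_patch(plt.Rectangle((x - width * 0.4, r["q1"]), width * 0.8,
                                   r["q3"] - r["q1"], fill=False,
                                   edgecolor=r["color"]))
        ax.plot([x - width * 0.4, x + width * 0.4], [r["median"]] * 2,
                color=r["color"])
        ax.plot([x, x], [r["whisker_lo"], r["q1"]], color=r["color"])
        ax.plot([x, x], [r["q3"], r["whisker_hi"]], color=r["color"])
        for v in r["outlier_values"]:
            ax.plot(x, v, ".", color=r["color"], ms=3)
    for a in panel["annotations"]:
        arm_i = arms.index(a["arm"])
        ax.annotate(a["text"], (vx[a["visit_index"]], -0.06 - 0.05 * arm_i),
                    xycoords=("data", "axes fraction"), fontsize=6,
                    ha="center", annotation_clip=False)
    if panel.get("log_scale"):
        ax.set_yscale("log")
    ax.set_xticks(range(len(visits)))
    ax.set_xticklabels([str(v) for v in visits])
    ax.set_xlabel(panel["x_label"])
    ax.set_ylabel(panel["y_label"])


def _render_prevalence(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    visits = panel["visit_order"]
    vx = {v: i for i, v in enumerate(visits)}
    for arm in panel["arms"]:
        pts = [(vx[r["visit_index"]], r["percent"], r["color"])
               for r in panel["records"] if r["arm"] == arm and r["percent"] is not None]
        if pts:
            ax.plot([p[0] for p in pts], [p[1] for p in pts], "o-",
                    color=pts[0][2], label=arm, ms=4)
    for a in panel["annotations"]:
        arm_i = panel["arms"].index(a["arm"])
        ax.annotate(a["text"], (vx[a["visit_index"]], -0.06 - 0.05 * arm_i),
                    xycoords=("data", "axes fraction"), fontsize=6,
                    ha="center", annotation_clip=False)
    ax.legend(fontsize=7)
    ax.set_xticks(range(len(visits)))
    ax.set_xticklabels([str(v) for v in visits])
    ax.set_xlabel(panel["x_label"])
    ax.set_ylabel(panel["y_label"])


def _render_spaghetti(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    for r in panel["records"]:
        if not r["selected"]:
            ax.plot(r["days"], r["values"], color=r["color"], lw=0.6, alpha=0.6)
    for r in panel["records"]:
        if r["selected"]:
            ax.plot(r["days"], r["values"], color=r["color"], lw=1.5)
            ax.annotate(r["subject_id"], (r["days"][-1], r["values"][-1]),
                        fontsize=7, color=r["color"])
    for line in panel["reference_lines"]:
        ax.axhline(line["y"], color="k", lw=0.8, ls="--")
        ax.annotate(line["label"], (0.01, line["y"]),
                    xycoords=("axes fraction", "data"), fontsize=6)
    ax.set_xlabel(panel["x_label"])
    ax.set_ylabel(panel["y_label"])


def _render_shift_scatter(spec: FigureSpec, ax) -> None:
    panel = spec.panels[0]
    xs = [r["x"] for r in panel["records"]]
    ys = [r["y"] for r in panel["records"]]
    ax.scatter(xs, ys, s=14, color="#0072B2", alpha=0.8)
    lims = (min(xs + ys) * 0.9, max(xs + ys) * 1.1)
    ax.plot(lims, lims, color="0.6", lw=0.8)
    for line in panel["reference_lines"]:
        if line["axis"] == "x":
            ax.axvline(line["value"], color="k", lw=0.8)
        else:
            ax.axhline(line["value"], color="k", lw=0.8)
    ax.set_xlabel(panel["x_label"])
    ax.set_ylabel(panel["y_label"])


def _backing_frame(spec: FigureSpec) -> pd.DataFrame:
    rows = []
    for i, panel in enumerate(spec.panels):
        for r in panel["records"]:
            row = {"panel": i}
            for k, v in r.items():
                row[k] = json.dumps(v) if isinstance(v, (list, dict)) else v
            rows.append(row)
    return pd.DataFrame(rows)


def render_figure(
    spec: FigureSpec,
    basepath: str | Path,
    formats: Sequence[str] = ("svg", "png"),
    write_data: bool = True,
) -> list[Path]:
    """Draw a FigureSpec and write it as SVG/PNG plus backing-data CSV.

    Output is deterministic for identical specs: fixed SVG hash salt and
    no embedded timestamps.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": "dmcreport",
                                "figure.dpi": 100}):
        if spec.kind == "demographics":
            fig, axes = plt.subplots(len(spec.panels), 1,
                                     figsize=(6.5, 1.4 * len(spec.panels) + 1),
                                     squeeze=False)
            _render_demographics(spec, axes[:, 0])
        else:
            n_terms = len(spec.panels[0].get("row_order", []))
            height = max(3.2, 0.28 * n_terms) if spec.kind == "ae_dotplot" else 4.0
            fig, ax = plt.subplots(figsize=(6.5, height))
            {"ae_dotplot": _render_dotplot,
             "volcano": _render_volcano,
             "lab_boxes": _render_box_by_visit,
             "abnormal_prevalence": _render_prevalence,
             "spaghetti": _render_spaghetti,
             "shift_scatter": _render_shift_scatter}[spec.kind](spec, ax)
        fig.suptitle("", fontsize=1)
        fig.tight_layout()
        written: list[Path] = []
        for fmt in formats:
            out = basepath.with_suffix(f".{fmt}")
            fig.savefig(out, format=fmt, metadata=_no_date_metadata(fmt))
            written.append(out)
        plt.close(fig)
    if write_data:
        data_path = basepath.with_suffix(".csv")
        _backing_frame(spec).to_csv(data_path, index=False)
        written.append(data_path)
    return written


def _no_date_metadata(fmt: str) -> dict | None:
    if fmt == "svg":
        return {"Date": None}
    if fmt == "png":
        return {"Software": "dmcreport"}
    return None
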