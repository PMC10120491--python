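"""Seeded generator of CDISC-shaped synthetic trials.

The generator emulates the shape of a late-phase safety dataset — two to
three arms, per-arm demographics, MedDRA-style preferred-term strings,
visit-scheduled labs with subject-specific limits of normal, exposure
intervals — with *injectable* safety imbalances so that every downstream
display has a known ground truth:

* adverse events follow a per-arm constant-hazard (exponential
  time-to-first-event) model, so an injected hazard ratio is recoverable
  from the incidence statistics;
* laboratory outliers are injected multiplicatively above the subject's
  own upper limit of normal, so trajectory-selection rules have an exact
  expected answer;
* all randomness flows from one master seed, split into one independent
  stream per output table, so adding a lab parameter to a config does not
  perturb the adverse-event draws.

Study days are per-subject (day 1 = first dose), so enrollment timing
enters only through how much exposure a subject can accrue before the
administrative end of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import TrialData, assemble_trial

__all__ = [
    "ArmSpec",
    "AEModel",
    "LabModel",
    "SynthConfig",
    "GroundTruth",
    "generate_trial",
    "xanomeline_like_fixture",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ArmSpec:
    label: str
    n_subjects: int
    sex_female_prob: float = 0.5


@dataclass
class AEModel:
    """Constant-hazard first-event model for one preferred term."""

    preferred_term: str
    system_organ_class: str
    hazard_per_year: dict[str, float]  # arm label -> events/person-year
    serious_prob: float = 0.0
    grade_probs: tuple[float, ...] = (0.5, 0.3, 0.15, 0.04, 0.01)
    related_prob: float = 0.3
    aesi: bool = False


@dataclass
class LabModel:
    """Lognormal lab parameter with arm-specific drift and injected outliers.

    ``arm_drift`` gives, per arm, an additive shift on the log scale at each
    scheduled visit (first entry is baseline, normally 0).  Outliers are
    injected at post-baseline visits with probability ``outlier_prob`` by
    setting the value to ``outlier_multiplier`` times the subject's own ULN.
    ``limit_jitter_sd`` (log scale) jitters both limits of normal per
    subject with a common factor, keeping ``lln < uln``.
    """

    param_code: str
    param_name: str
    unit: str
    baseline_log_mu: float
    baseline_log_sigma: float
    visit_schedule: tuple[int, ...]
    arm_drift: dict[str, tuple[float, ...]]
    sd_within: float = 0.05
    outlier_prob: float = 0.0
    outlier_multiplier: float = 3.5
    lln: float | None = None
    uln: float | None = None
    limit_jitter_sd: float = 0.0
    direction: str = "high"  # side on which toxicity is graded


@dataclass
class SynthConfig:
    arms: list[ArmSpec]
    reference_arm: str
    ae_models: list[AEModel] = field(default_factory=list)
    lab_models: list[LabModel] = field(default_factory=list)
    age_mean: float = 75.0
    age_sd: float = 8.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    enrollment_window_days: int = 90
    exposure_mean_days: float = 150.0
    study_length_days: int = 182
    dropout_prob: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for arm in self.arms:
            if arm.n_subjects <= 0:
                raise ValueError(f"arm {arm.label!r}: n_subjects must be positive")
            if not 0 <= arm.sex_female_prob <= 1:
                raise ValueError(f"arm {arm.label!r}: sex_female_prob outside [0,1]")
        labels = [a.label for a in self.arms]
        if self.reference_arm not in labels:
            raise ValueError("reference_arm not among declared arms")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob outside [0,1]")
        for m in self.ae_models:
            if abs(sum(m.grade_probs) - 1.0) > 1e-9:
                raise ValueError(f"{m.preferred_term}: grade_probs must sum to 1")
            if any(h < 0 for h in m.hazard_per_year.values()):
                raise ValueError(f"{m.preferred_term}: negative hazard")
        for m in self.lab_models:
            if list(m.visit_schedule) != sorted(set(m.visit_schedule)):
                raise ValueError(f"{m.param_code}: visit_schedule must be strictly increasing")
            if m.lln is not None and m.uln is not None and m.lln >= m.uln:
                raise ValueError(f"{m.param_code}: lln must be below uln")


@dataclass
class GroundTruth:
    """What the generator injected, for exact-recovery checks."""

    sae_subjects: set[str] = field(default_factory=set)
    ae_grade3_subjects: set[str] = field(default_factory=set)
    lab_outlier_subjects: dict[str, set[str]] = field(default_factory=dict)


RACES = ("WHITE", "BLACK OR AFRICAN AMERICAN", "ASIAN", "OTHER")
RACE_PROBS = (0.78, 0.12, 0.07, 0.03)
COUNTRIES = ("USA", "CAN", "DEU", "ESP")
COUNTRY_PROBS = (0.6, 0.15, 0.15, 0.1)


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample; bounds are wide, so this terminates fast
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_trial(
    config: SynthConfig, return_truth: bool = False
) -> TrialData | tuple[TrialData, GroundTruth]:
    """Draw one synthetic trial; byte-identical tables for identical seeds."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_subj, rng_ae, rng_lab = (np.random.default_rng(s) for s in ss.spawn(3))
    truth = GroundTruth()

    # ---- subjects + exposure -------------------------------------------
    rows = []
    expo_rows = []
    sid_counter = 0
    arm_of: dict[str, str] = {}
    duration_of: dict[str, int] = {}
    for arm in config.arms:
        n = arm.n_subjects
        age = _truncated_normal(rng_subj, config.age_mean, config.age_sd,
                                *config.age_bounds, n)
        sex = np.where(rng_subj.random(n) < arm.sex_female_prob, "F", "M")
        race = rng_subj.choice(RACES, size=n, p=RACE_PROBS)
        country = rng_subj.choice(COUNTRIES, size=n, p=COUNTRY_PROBS)
        enroll = rng_subj.uniform(0, config.enrollment_window_days, n)
        max_dur = np.maximum(config.study_length_days - enroll, 1.0)
        dur = np.minimum(rng_subj.exponential(config.exposure_mean_days, n), max_dur)
        dropped = rng_subj.random(n) < config.dropout_prob
        dur = np.where(dropped, dur * rng_subj.uniform(0.1, 1.0, n), dur)
        dur_days = np.maximum(np.ceil(dur).astype(int), 1)
        for k in range(n):
            sid_counter += 1
            sid = f"S{sid_counter:04d}"
            arm_of[sid] = arm.label
            duration_of[sid] = int(dur_days[k])
            rows.append(dict(
                subject_id=sid, arm=arm.label, age=round(float(age[k]), 1),
                sex=str(sex[k]), race=str(race[k]), country=str(country[k]),
                first_dose_day=1, last_dose_day=int(dur_days[k]),
                randomized_flag=True, discontinued_flag=bool(dropped[k]),
            ))
            expo_rows.append(dict(subject_id=sid, start_day=1,
                                  end_day=int(dur_days[k]),
                                  dose_label=arm.label))
    subjects = pd.DataFrame(rows)
    exposure = pd.DataFrame(expo_rows)
    sids = list(arm_of)

    # ---- adverse events -------------------------------------------------
    ae_rows = []
    for model in config.ae_models:
        for sid in sids:
            haz = model.hazard_per_year.get(arm_of[sid], 0.0)
            # one uniform per subject regardless of hazard keeps streams stable
            u = rng_ae.random()
            extra = rng_ae.random(4)  # grade/serious/related/resolution draws
            if haz <= 0:
                continue
            t = -np.log(u) * DAYS_PER_YEAR / haz  # Exp(hazard) via inversion
            if t > duration_of[sid]:
                continue
            onset = 1 + int(np.floor(t))
            grade = 1 + int(np.searchsorted(np.cumsum(model.grade_probs), extra[0],
                                            side="right"))
            grade = min(grade, 5)
            serious = bool(extra[1] < model.serious_prob)
            related = bool(extra[2] < model.related_prob)
            dur_ae = int(np.ceil(-np.log(max(extra[3], 1e-12)) * 10))
            resolution = onset + dur_ae
            ongoing = resolution > duration_of[sid] + 30
            ae_rows.append(dict(
                subject_id=sid, preferred_term=model.preferred_term,
                system_organ_class=model.system_organ_class,
                onset_day=onset,
                resolution_day=pd.NA if ongoing else resolution,
                ctc_grade=grade, serious_flag=serious, related_flag=related,
                discontinuation_flag=False, aesi_flag=model.aesi,
            ))
            if serious:
                truth.sae_subjects.add(sid)
            if grade >= 3:
                truth.ae_grade3_subjects.add(sid)
    adverse_events = pd.DataFrame(ae_rows)

    # ---- laboratory measurements ---------------------------------------
    lab_rows = []
    for model in config.lab_models:
        truth.lab_outlier_subjects.setdefault(model.param_code, set())
        drift_default = tuple(0.0 for _ in model.visit_schedule)
        for sid in sids:
            jitter = float(np.exp(rng_lab.normal(0.0, model.limit_jitter_sd))) \
                if model.limit_jitter_sd > 0 else 1.0
            lln = None if model.lln is None else model.lln * jitter
            uln = None if model.uln is None else model.uln * jitter
            log_base = rng_lab.normal(model.baseline_log_mu, model.baseline_log_sigma)
            drift = model.arm_drift.get(arm_of[sid], drift_default)
            noise = rng_lab.normal(0.0, model.sd_within, len(model.visit_schedule))
            out_u = rng_lab.random(len(model.visit_schedule))
            for vi, day in enumerate(model.visit_schedule):
                if vi > 0 and day > duration_of[sid]:
                    continue  # subject off treatment: visit not performed
                value = float(np.exp(log_base + drift[vi] + noise[vi]))
                is_outlier = (vi > 0 and uln is not None
                              and out_u[vi] < model.outlier_prob)
                if is_outlier:
                    value = model.outlier_multiplier * uln
                    truth.lab_outlier_subjects[model.param_code].add(sid)
                lab_rows.append(dict(
                    subject_id=sid, param_code=model.param_code,
                    param_name=model.param_name, visit_index=vi,
                    visit_name="Baseline" if vi == 0 else f"Week {day // 7}",
                    day=int(day), value=round(value, 4), unit=model.unit,
                    lln=np.nan if lln is None else round(lln, 4),
                    uln=np.nan if uln is None else round(uln, 4),
                    baseline_flag=vi == 0,
                ))
    labs = pd.DataFrame(lab_rows)

    trial = assemble_trial(
        subjects,
        adverse_events if not adverse_events.empty else None,
        labs if not labs.empty else None,
        exposure,
        arms=[a.label for a in config.arms],
        reference_arm=config.reference_arm,
        cutoff_day=config.study_length_days + 60,
    )
    if return_truth:
        return trial, truth
    return trial


def xanomeline_like_fixture(seed: int = 20230421) -> SynthConfig:
    """A canned two-arm config echoing the shape of the public CDISC pilot
    study: a Placebo and a High Dose arm, an elderly population, a handful
    of skin/nervous-system preferred terms with treatment-elevated hazards,
    a cholesterol-like parameter with common limits of normal and a
    creatine-kinase-like parameter with subject-jittered limits and
    injected outliers.  The data themselves are synthetic.
    """
    visits = (1, 14, 28, 56, 84, 126, 168)
    no_drift = tuple(0.0 for _ in visits)
    return SynthConfig(
        arms=[ArmSpec("High Dose", 84, sex_female_prob=0.55),
              ArmSpec("Placebo", 86, sex_female_prob=0.60)],
        reference_arm="Placebo",
        age_mean=75.0, age_sd=8.0,
        enrollment_window_days=90,
        exposure_mean_days=150.0,
        study_length_days=182,
        dropout_prob=0.25,
        seed=seed,
        ae_models=[
            AEModel("Pruritus", "Skin and subcutaneous tissue disorders",
                    {"High Dose": 1.2, "Placebo": 0.25}, serious_prob=0.02,
                    related_prob=0.7),
            AEModel("Application site pruritus", "General disorders and administration site conditions",
                    {"High Dose": 0.9, "Placebo": 0.15}, related_prob=0.8),
            AEModel("Erythema", "Skin and subcutaneous tissue disorders",
                    {"High Dose": 0.6, "Placebo": 0.2}, related_prob=0.6),
            AEModel("Dizziness", "Nervous system disorders",
                    {"High Dose": 0.5, "Placebo": 0.3}, serious_prob=0.05,
                    aesi=True),
            AEModel("Syncope", "Nervous system disorders",
                    {"High Dose": 0.15, "Placebo": 0.05}, serious_prob=0.5,
                    grade_probs=(0.1, 0.3, 0.4, 0.15, 0.05), aesi=True),
            AEModel("Nausea", "Gastrointestinal disorders",
                    {"High Dose": 0.45, "Placebo": 0.3}),
            AEModel("Diarrhoea", "Gastrointestinal disorders",
                    {"High Dose": 0.3, "Placebo": 0.3}),
            AEModel("Headache", "Nervous system disorders",
                    {"High Dose": 0.35, "Placebo": 0.35}),
            AEModel("Fall", "Injury, poisoning and procedural complications",
                    {"High Dose": 0.2, "Placebo": 0.2}, serious_prob=0.3,
                    grade_probs=(0.3, 0.3, 0.3, 0.08, 0.02)),
            AEModel("Urinary tract infection", "Infections and infestations",
                    {"High Dose": 0.15, "Placebo": 0.18}, serious_prob=0.1),
        ],
        lab_models=[
            LabModel(
                param_code="CHOL", param_name="Cholesterol", unit="mmol/L",
                baseline_log_mu=float(np.log(5.2)), baseline_log_sigma=0.15,
                visit_schedule=visits,
                arm_drift={"High Dose": (0.0, 0.02, 0.04, 0.06, 0.08, 0.09, 0.10),
                           "Placebo": no_drift},
                sd_within=0.06, lln=2.8, uln=7.0, limit_jitter_sd=0.0,
            ),
            LabModel(
                param_code="CK", param_name="Creatine Kinase", unit="U/L",
                baseline_log_mu=float(np.log(95.0)), baseline_log_sigma=0.20,
                visit_schedule=visits,
                arm_drift={"High Dose": no_drift, "Placebo": no_drift},
                sd_within=0.10, lln=30.0, uln=200.0, limit_jitter_sd=0.08,
                outlier_prob=0.01, outlier_multiplier=3.5,
            ),
        ],
    )
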