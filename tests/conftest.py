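import numpy as np
import pandas as pd
import pytest

from dmcreport.synth_trial import (AEModel, ArmSpec, LabModel, SynthConfig,
                                   generate_trial, xanomeline_like_fixture)


def small_config(seed: int = 0, n_per_arm: int = 40,
                 outlier_prob: float = 0.02) -> SynthConfig:
    """A scaled-down two-arm trial for fast repeated generation in tests."""
    visits = (1, 28, 84, 168)
    no_drift = (0.0, 0.0, 0.0, 0.0)
    return SynthConfig(
        arms=[ArmSpec("Active", n_per_arm), ArmSpec("Placebo", n_per_arm)],
        reference_arm="Placebo",
        exposure_mean_days=150.0, study_length_days=182, dropout_prob=0.2,
        seed=seed,
        ae_models=[
            AEModel("Pruritus", "Skin", {"Active": 1.0, "Placebo": 0.2},
                    serious_prob=0.05),
            AEModel("Nausea", "GI", {"Active": 0.5, "Placebo": 0.4}),
            AEModel("Headache", "Nervous", {"Active": 0.4, "Placebo": 0.4}),
            AEModel("Fall", "Injury", {"Active": 0.25, "Placebo": 0.25},
                    serious_prob=0.3,
                    grade_probs=(0.3, 0.3, 0.3, 0.08, 0.02)),
        ],
        lab_models=[
            LabModel("CK", "Creatine Kinase", "U/L",
                     baseline_log_mu=float(np.log(95.0)),
                     baseline_log_sigma=0.2,
                     visit_schedule=visits,
                     arm_drift={"Active": no_drift, "Placebo": no_drift},
                     sd_within=0.1, lln=30.0, uln=200.0,
                     limit_jitter_sd=0.08, outlier_prob=outlier_prob,
                     outlier_multiplier=3.5),
            LabModel("CHOL", "Cholesterol", "mmol/L",
                     baseline_log_mu=float(np.log(5.2)),
                     baseline_log_sigma=0.15,
                     visit_schedule=visits,
                     arm_drift={"Active": (0.0, 0.03, 0.06, 0.09),
                                "Placebo": no_drift},
                     sd_within=0.06, lln=2.8, uln=7.0),
        ],
    )


@pytest.fixture(scope="session")
def fixture_trial():
    return generate_trial(xanomeline_like_fixture())


@pytest.fixture(scope="session")
def small_trial():
    return generate_trial(small_config(seed=7))


@pytest.fixture()
def tiny_trial():
    """Hand-built four-subject trial with known counts for exact checks."""
    from dmcreport.trial_data import assemble_trial

    subjects = pd.DataFrame(dict(
        subject_id=["A1", "A2", "B1", "B2"],
        arm=["Active", "Active", "Placebo", "Placebo"],
        age=[70.0, 75.0, 72.0, 68.0],
        sex=["F", "M", "F", "F"],
        race=["WHITE"] * 4, country=["USA"] * 4,
        first_dose_day=[1, 1, 1, 1],
        last_dose_day=[100, 100, 100, 100],
        randomized_flag=[True] * 4, discontinued_flag=[False] * 4,
    ))
    ae = pd.DataFrame(dict(
        subject_id=["A1", "A1", "A1", "B1"],
        preferred_term=["Nausea", "Nausea", "Nausea", "Nausea"],
        system_organ_class=["GI"] * 4,
        onset_day=[5, 20, 40, 10],
        resolution_day=[7, 22, pd.NA, 12],
        ctc_grade=[1, 2, 1, 1],
        serious_flag=[False] * 4, related_flag=[False] * 4,
        discontinuation_flag=[False] * 4, aesi_flag=[False] * 4,
    ))
    labs = pd.DataFrame(dict(
        subject_id=["A1"] * 3 + ["A2"] * 3 + ["B1"] * 3,
        param_code=["CK"] * 9, param_name=["Creatine Kinase"] * 9,
        visit_index=[0, 1, 2] * 3, visit_name=["V"] * 9,
        day=[1, 28, 84] * 3,
        value=[100.0, 150.0, 700.0, 90.0, 110.0, 95.0, 120.0, 180.0, 150.0],
        unit=["U/L"] * 9,
        lln=[30.0] * 9, uln=[200.0] * 9,
        baseline_flag=[True, False, False] * 3,
    ))
    exposure = pd.DataFrame(dict(
        subject_id=["A1", "A2", "B1", "B2"],
        start_day=[1] * 4, end_day=[100] * 4,
        dose_label=["Active", "Active", "Placebo", "Placebo"],
    ))
    return assemble_trial(subjects, ae, labs, exposure,
                          arms=["Active", "Placebo"], cutoff_day=200)
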