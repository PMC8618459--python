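import numpy as np
import pandas as pd
import pytest

from readmitrisk.features import FeaturePanel
from readmitrisk.labels import PatientMeta, RiskTrajectory, TrajectoryConfig, build_trajectory
from readmitrisk.synth import SyntheticCohortSpec, generate_cohort


def make_panel(data: dict[str, dict[int, list[float]]], tags=None) -> FeaturePanel:
    """Build a small panel from {patient: {day-start-1 implicit}}-style data.

    ``data`` maps patient id -> {feature name -> list of per-day values}
    (np.nan for missing); all features of a patient must share length.
    """
    rows = []
    for pid, feats in data.items():
        n_days = len(next(iter(feats.values())))
        for d in range(n_days):
            row = {"patient_id": pid, "day": d + 1}
            row.update({name: vals[d] for name, vals in feats.items()})
            rows.append(row)
    return FeaturePanel.from_frame(pd.DataFrame(rows), tags=tags)


@pytest.fixture(scope="session")
def tiny_cohort():
    spec = SyntheticCohortSpec(
        n_patients=6,
        n_sensor_features=4,
        n_symptoms=3,
        missing_rate=0.08,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture()
def nonreadmitted_meta():
    # LACE 10 / HOSPITAL 8 -> average initial probability ~0.53
    return PatientMeta("nr", False, lace=10, hospital=8)


@pytest.fixture()
def readmitted_meta():
    # the worked example: readmission on day 16, second discharge day 21
    return PatientMeta("r", True, lace=10, hospital=8,
                       readmission_day=16, second_discharge_day=21)
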