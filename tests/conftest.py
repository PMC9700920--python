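import pandas as pd
import pytest

from readmit.cohort import build_cohort
from readmit.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_bundle():
    """A 300-patient synthetic population shared by read-only tests."""
    return generate(SynthConfig(n_patients=300, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    cohort, episodes, log = build_cohort(small_bundle, seed=11)
    return cohort, episodes, log


def make_hosp_frame(rows):
    """Build a hospitalizations frame from (admit, discharge, dispo, dx, proc) tuples."""
    return pd.DataFrame(
        {
            "record_id": range(len(rows)),
            "patient_id": ["p1"] * len(rows),
            "institution": ["INST01"] * len(rows),
            "admit_date": [pd.Timestamp(r[0]) for r in rows],
            "discharge_date": [pd.Timestamp(r[1]) for r in rows],
            "discharge_disposition": [r[2] for r in rows],
            "diagnosis_codes": [r[3] if len(r) > 3 else "K65" for r in rows],
            "procedure_codes": [r[4] if len(r) > 4 else "" for r in rows],
            "admitted_via_ed": [True] * len(rows),
        }
    )
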