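import numpy as np
import pandas as pd
import pytest

from tbinflam.cohort_io import MEDIATOR_PANEL, MediatorCohort, normalize_cohort
from tbinflam.core_model import ModelParameters
from tbinflam.synthetic import CohortSpec, generate_cohort


@pytest.fixture
def unit_params() -> ModelParameters:
    """All 25 parameters set to 1."""
    return ModelParameters.from_array(np.ones(25))


@pytest.fixture
def two_patient_cohort() -> MediatorCohort:
    """Tiny hand-built cohort: one survivor, one non-survivor, 26 series."""
    clinical = pd.DataFrame(
        {
            "patient_id": ["p1", "p2"],
            "age": [30.0, 45.0],
            "sex": ["M", "F"],
            "gcs": [7, 5],
            "gos6": [4, 1],
            "gos12": [4, 1],
        }
    )
    rows = []
    rng = np.random.default_rng(1234)
    for pid, scale in (("p1", 1.0), ("p2", 2.0)):
        for mediator in MEDIATOR_PANEL:
            for t in (0.0, 20.0, 45.0, 70.0, 100.0):
                rows.append(
                    {
                        "patient_id": pid,
                        "mediator": mediator,
                        "time_h": t,
                        "conc_pg_ml": float(scale * (1 + rng.uniform(0, 9))),
                    }
                )
    clinical["group"] = ["survivor", "non-survivor"]
    return MediatorCohort(clinical=clinical, series=pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_noisefree_cohort() -> MediatorCohort:
    """Mechanistic 6+3 cohort without measurement or patient noise."""
    spec = CohortSpec(
        n_survivors=6, n_nonsurvivors=3, noise_sigma=0.0, patient_sigma=0.0, seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort_normalized() -> MediatorCohort:
    """One default-condition cohort draw (29+5 patients), normalized."""
    return normalize_cohort(generate_cohort(CohortSpec(seed=2024)))
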