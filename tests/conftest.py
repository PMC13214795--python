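import numpy as np
import pandas as pd
import pytest

from akipipe.containers import FusedEpisode
from akipipe.synth import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient cohort with 10% missingness, shared across tests."""
    spec = CohortSpec(n_patients=200, seed=42, missingness=0.1)
    his, pdms, ledger = generate_cohort(spec)
    return spec, his, pdms, ledger


def make_episode(
    patient_id="P1",
    urine=None,
    creatinine=None,
    weight=None,
    dialysis=None,
    preop_creatinine=1.0,
    **covariates,
):
    """Hand-built fused episode for detector unit tests.

    ``urine``/``creatinine``/``weight`` are lists of (time_h, value).
    """
    def _df(pairs):
        pairs = pairs or []
        return pd.DataFrame(
            {"time_h": [p[0] for p in pairs], "value": [p[1] for p in pairs]}
        )

    t0 = pd.Timestamp("2021-06-01 08:00:00")
    return FusedEpisode(
        patient_id=patient_id,
        procedure="OPCAB",
        surgery_start=t0,
        surgery_end=t0 + pd.Timedelta(hours=3),
        icu_admission=t0 + pd.Timedelta(hours=4),
        icu_discharge=t0 + pd.Timedelta(hours=76),
        creatinine=_df(creatinine),
        urine=_df(urine),
        weight=_df(weight),
        dialysis_times_h=list(dialysis or []),
        death=False,
        hospital_los_days=8.0,
        icu_los_days=3.0,
        covariates={"preop_creatinine": preop_creatinine, **covariates},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
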