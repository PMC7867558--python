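import numpy as np
import pytest

import tailored_tacs as tt


@pytest.fixture(scope="session")
def small_spec():
    """Fast synthesis conditions: 500 Hz native rate, 20 s (9 usable epochs)."""
    return tt.CohortSpec(fs=500.0, duration_s=20.0)


@pytest.fixture(scope="session")
def theta_patient_tables(small_spec):
    """21 control band-power tables plus one patient with a theta excess
    planted at C3 (amplitude gain 3), all run through the spectral pipeline."""
    controls = [
        tt.band_power_pipeline(rec)
        for rec in tt.generate_control_cohort(21, small_spec, seed=42)
    ]
    anomaly = tt.AnomalySpec("theta", ("C3",), 3.0)
    patient = tt.band_power_pipeline(
        tt.generate_recording(small_spec, anomaly, seed=1042)
    )
    return controls, patient


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
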