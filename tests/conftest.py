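import numpy as np
import pytest

import vitalcast as vc


@pytest.fixture(scope="session")
def zol_table():
    return vc.load_zol_table()


@pytest.fixture(scope="session")
def learnable_instances():
    """Seeded learnable cohort featurized at horizon +1 h (shared: it is the
    expensive fixture of the suite)."""
    cohort = vc.generate_learnable_cohort(n_patients=10, snr=5.0, seed=1)
    instances = []
    for rec, _ in cohort:
        den = vc.denoise_recording(rec)
        instances.extend(vc.enumerate_instances(den, horizons=(1,)))
    return instances


@pytest.fixture(scope="session")
def short_recording():
    """A 4 h dialysis-profile recording with artefacts, for pipeline tests."""
    rec, truth = vc.generate_recording(vc.make_profile("dialysis", seed=11))
    return rec, truth


@pytest.fixture()
def constant_recording():
    """Noise-free recording where every channel is constant (HR 80, etc.)."""
    spec = vc.make_profile(
        "cardiology", duration_min=150, seed=0,
        trend_amplitude={c: 0.0 for c in ("hr", "rr", "dbp", "pp", "spo2")},
        noise_sd={c: 0.0 for c in ("hr", "rr", "dbp", "pp", "spo2")},
        artefact_rate_per_hour=0.0,
        baseline={"hr": 80.0, "rr": 14.0, "sbp": 120.0, "dbp": 70.0,
                  "spo2": 97.0},
    )
    rec, _ = vc.generate_recording(spec)
    return rec


def rng(seed=0):
    return np.random.default_rng(seed)
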