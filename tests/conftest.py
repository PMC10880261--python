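import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flowbind as fb

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    """Standard operating point: 3.2 mL/h, 0.16 mL, 0.5 ug/mL at 100 kBq/ug,
    3 h uptake + 2 h washout, 1-min channels."""
    return fb.AssayConfig()


@pytest.fixture(scope="session")
def calib():
    return fb.DetectorCalib()


@pytest.fixture(scope="session")
def truth():
    """Typical kinetics: k_on and N_ar near the batch means, k_off at the
    median of the identifiable runs."""
    return fb.KineticParams(k_on=4.5e4, k_off=0.45e-5, n_antigens_total=1.1e12)


# The 17 published application runs: (k_on x1e3, k_off x1e-5 or None when
# imputed, B_max x1e6).  Runs 1-7 terminated before washout, so their k_off
# was imputed at the batch median 0.45e-5.
TABLE_ROWS = [
    (44.8, None, 1.58),
    (36.5, None, 2.25),
    (34.4, None, 2.12),
    (36.8, None, 1.30),
    (34.6, None, 1.44),
    (44.2, None, 1.19),
    (35.4, None, 1.34),
    (34.1, 0.29, 1.45),
    (33.9, 1.70, 0.93),
    (45.0, 0.78, 0.53),
    (71.6, 0.58, 0.28),
    (31.8, 4.20, 1.64),
    (51.2, 0.11, 0.76),
    (79.4, 0.19, 0.47),
    (39.8, 0.21, 0.84),
    (47.2, 0.32, 0.60),
    (58.6, 1.02, 0.39),
]


@pytest.fixture(scope="session")
def published_batch_rows():
    """The 17 runs as summarize_batch records (SI units)."""
    return [
        {
            "k_on": k * 1e3,
            "k_off": (0.45 if f is None else f) * 1e-5,
            "b_max_per_cell": b * 1e6,
            "koff_imputed": f is None,
        }
        for (k, f, b) in TABLE_ROWS
    ]
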