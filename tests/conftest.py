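import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import biaffm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort() -> pd.DataFrame:
    """One default synthetic cohort (n=396), shared across tests."""
    return biaffm.generate(biaffm.default_config(), seed=11)


@pytest.fixture(scope="session")
def reference_ffm(cohort) -> np.ndarray:
    return biaffm.add_derived(cohort)["ffm_dxa_kg"].to_numpy(dtype=float)


@pytest.fixture()
def small_cohort() -> pd.DataFrame:
    """Six hand-written subjects with DXA reference, mass-closed."""
    rows = []
    base = [
        (19.0, 68.0, 174.0, 470.0, 61.0, 12.0),
        (20.5, 75.5, 181.2, 450.0, 58.5, 14.2),
        (18.2, 62.3, 169.5, 520.0, 66.0, 10.1),
        (22.1, 80.0, 186.0, 430.0, 55.0, 16.0),
        (19.8, 71.4, 176.8, 485.0, 63.5, 13.0),
        (21.0, 66.0, 172.3, 505.0, 60.0, 11.5),
    ]
    for i, (age, wt, st, r, xc, fm) in enumerate(base):
        ffm = wt - fm
        bmc = 0.05 * ffm
        rows.append(
            {
                "subject_id": f"C{i + 1}",
                "age": age,
                "sex": 1,
                "weight_kg": wt,
                "stature_cm": st,
                "resistance_ohm": r,
                "reactance_ohm": xc,
                "fm_kg": fm,
                "bmc_kg": bmc,
                "lst_kg": ffm - bmc,
            }
        )
    return pd.DataFrame(rows, columns=biaffm.COHORT_COLUMNS)
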