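import numpy as np
import pandas as pd
import pytest

from trichoselect.annotation import CalibrationSeries
from trichoselect.simulate import SimConfig


@pytest.fixture
def small_config():
    """A fast, small synthetic screen for unit tests."""
    return SimConfig(
        n_accessions=8,
        n_resistant=3,
        n_features=12,
        n_planted=1,
        n_replicates=3,
        n_larvae=12,
        seed=42,
    )


@pytest.fixture
def alkane_calibration():
    """C8-C20 ladder with retention times from a smooth, increasing ramp."""
    ns = list(range(8, 21))
    return CalibrationSeries.from_pairs((n, 2.0 + 1.7 * (n - 8) + 0.01 * (n - 8) ** 2)
                                        for n in ns)


@pytest.fixture
def whitefly_two_group():
    """Two accessions, aggregated counts 32/40 alive (baseline) vs 8/40."""
    rows = []
    for plant in range(1, 5):
        rows.append(("BASE", f"BASE-P{plant}", f"BASE-C{plant}", 8, 2))
        rows.append(("TEST", f"TEST-P{plant}", f"TEST-C{plant}", 2, 8))
    return pd.DataFrame(
        rows, columns=["accession", "plant_id", "cage_id", "n_alive", "n_dead"]
    )


def exponential_cox_oracle(df):
    """Closed-form exponential MLE of the log hazard ratio and its SE.

    With observed times T and death indicators d per arm, the exponential
    rate MLE is d/sum(T); the log-HR estimate is the log rate ratio with
    SE sqrt(1/d1 + 1/d0).
    """
    out = {}
    for arm, g in df.groupby("arm"):
        out[arm] = (g["status"].sum(), g["day"].sum())
    (d0, t0), (d1, t1) = out[0], out[1]
    log_hr = np.log((d1 / t1) / (d0 / t0))
    se = np.sqrt(1 / d1 + 1 / d0)
    return log_hr, se
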