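import numpy as np
import pandas as pd
import pytest

from combiscreen import simdata


@pytest.fixture
def hill_curve():
    """Curve with effect exactly 0.4 at dose 1 (emax 0.8, ec50 1, h 1)."""
    return simdata.HillCurve(emax=0.8, ec50=1.0, h=1.0)


@pytest.fixture
def tiny_plate():
    """Hand-built plate: blank 0.05, control 1.05, treated 0.55 -> viability 0.5."""
    rows = []
    for rep in range(1, 4):
        rows.append(("B%d" % rep, "blank", "", np.nan, rep, 0.05))
        rows.append(("C%d" % rep, "control", "drug", 0.0, rep, 1.05))
        rows.append(("T%d" % rep, "treated", "drug", 1.0, rep, 0.55))
    return pd.DataFrame(rows, columns=["well", "role", "drug", "dose", "replicate", "od"])


@pytest.fixture
def small_cohort():
    """Two-arm cohort with true HR 2, n = 300."""
    return simdata.simulate_two_group_cohort(300, hr=2.0, seed=11)
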