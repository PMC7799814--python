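import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from paleodem import (
    AnalysisConfig,
    DemographyScenario,
    generate_study,
    identity_curve,
    synthetic_calibration_curve,
)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def ident():
    """Identity curve (c14 = cal, zero curve error): calibration reduces to
    a discretized Gaussian, making closed-form oracles exact."""
    return identity_curve(0, 10000, sigma=0.0)


@pytest.fixture(scope="session")
def synth_curve():
    return synthetic_calibration_curve()


@pytest.fixture(scope="session")
def small_study(synth_curve):
    """A modest synthetic study reused by read-only tests."""
    scenario = DemographyScenario(
        n_dates=300,
        n_sites=40,
        n_survey_sites=150,
        n_survey_phases=360,
        n_urban_sites=25,
        n_urban_phases=50,
        seed=21,
    )
    return generate_study(scenario, synth_curve)


@pytest.fixture()
def toy_dates():
    """Ten hand-written dates, three of which violate a filtering rule."""
    return pd.DataFrame(
        {
            "lab_id": [f"L{i}" for i in range(10)],
            "site_id": ["S1"] * 5 + ["S2"] * 5,
            "cra": [4500, 4520, 4600, 5000, 7000, 4000, 4040, 4080, 3500, 3600],
            "error": [30, 40, 25, 350, 30, 30, 30, 30, 30, 30],
            "anthropogenic": [True] * 10,
            "marine": [False] * 9 + [True],
            "zone": ["above300"] * 5 + ["below300"] * 5,
            "region": ["A"] * 5 + ["B"] * 5,
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
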