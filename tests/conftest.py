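import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dpnflow.atc import default_class_map
from dpnflow.exposure import Window
from dpnflow.simulate import SimulationConfig, simulate_registry


@pytest.fixture(scope="session")
def cmap():
    return default_class_map()


@pytest.fixture(scope="session")
def window_2018():
    return Window(dt.date(2018, 1, 1), dt.date(2018, 12, 31))


def make_record(
    patient_id="P1",
    sex="female",
    birth_year=1980,
    atc_code="N06AB06",
    dispense_date="2018-03-01",
    days_supplied=30,
    ddd_ratio=0.8,
):
    return {
        "patient_id": patient_id,
        "sex": sex,
        "birth_year": birth_year,
        "atc_code": atc_code,
        "dispense_date": pd.Timestamp(dispense_date),
        "days_supplied": days_supplied,
        "ddd_ratio": ddd_ratio,
    }


@pytest.fixture
def records_frame():
    """Small hand-built registry: 3 patients, mixed classes."""
    rows = [
        make_record("P1", atc_code="N06AB06", dispense_date="2018-01-01", days_supplied=7),
        make_record("P1", atc_code="N05BA01", dispense_date="2018-01-03", days_supplied=7),
        make_record("P2", sex="male", atc_code="C10AA01", dispense_date="2018-02-01"),
        make_record("P2", sex="male", atc_code="N06AX11", dispense_date="2018-02-10"),
        make_record("P3", atc_code="A10BA02", dispense_date="2018-05-01"),
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sim_registry_small():
    """Session-cached simulated registry: 250 patients, two years."""
    cfg = SimulationConfig(
        n_patients=250,
        window_start=dt.date(2018, 1, 1),
        window_end=dt.date(2019, 12, 31),
        seed=11,
    )
    return cfg, simulate_registry(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
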