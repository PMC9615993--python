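import datetime as dt

import numpy as np
import pandas as pd
import pytest

from sympatric import Deployment, ScatTable


@pytest.fixture
def twelve_day_deployment():
    return [Deployment("st1", dt.date(2017, 6, 1), dt.date(2017, 6, 12))]


@pytest.fixture
def toy_scats():
    """Three scats: two single-prey, one multi-prey."""
    rows = [
        ("s1", "snow_leopard", "bharal"),
        ("s2", "snow_leopard", "livestock"),
        ("s3", "snow_leopard", "bharal"),
        ("s3", "snow_leopard", "marmot"),
    ]
    return ScatTable(pd.DataFrame(rows, columns=["scat_id", "predator", "prey"]))


@pytest.fixture
def rng():
    return np.random.default_rng(20170601)
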