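import numpy as np
import pytest

import pkquant as pq


@pytest.fixture(scope="session")
def schedule():
    return pq.default_schedule()


@pytest.fixture(scope="session")
def blood(schedule):
    return pq.gen_input(pq.InputModelParams(), schedule)


@pytest.fixture(scope="session")
def classes(blood, schedule):
    return pq.make_population_class_set(blood, schedule)


@pytest.fixture(scope="session")
def typical_params():
    return pq.TwoTCMParams(K1=0.10, k2=0.375, k3=0.05, k4=0.03,
                           vB=0.05, delay=0.0)
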