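import numpy as np
import pytest
from hypothesis import settings

from stmrf.dictionary_engine import ParameterGrid, generate_dictionary
from stmrf.sequence_model import (
    AcquisitionSchedule,
    Pool,
    PoolSystem,
    SaturationEvent,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def single_pool_system():
    """Water only: decoupled Bloch dynamics with closed-form limits."""
    return PoolSystem(water=Pool("water", t1=1.0, t2=0.1), solutes=(), b0=7.0)


@pytest.fixture
def two_pool_system():
    """Water + an amide-like CEST solute at 3 ppm (L-arginine-ish)."""
    water = Pool("water", t1=2.8, t2=0.6)
    solute = Pool("solute", t1=2.8, t2=0.04, f=1.35e-3, k=400.0, delta=3.0)
    return PoolSystem(water=water, solutes=(solute,), b0=7.0)


@pytest.fixture
def cw_event():
    return SaturationEvent(b1=2.0, offset=3.0, t_sat=3.0)


@pytest.fixture
def cw_schedule(cw_event):
    """4-image continuous-wave protocol: Tsat 3 s, Trec 1 s, FA 60 deg."""
    return AcquisitionSchedule(events=(cw_event,) * 4, t_rec=1.0, flip_angle=60.0)


@pytest.fixture
def small_grid():
    return ParameterGrid(
        fs_values=np.linspace(5e-4, 5e-3, 5),
        ksw_values=np.linspace(100.0, 1200.0, 5),
    )


@pytest.fixture
def small_dictionary(two_pool_system, small_grid, cw_schedule):
    return generate_dictionary(two_pool_system, small_grid, cw_schedule)
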