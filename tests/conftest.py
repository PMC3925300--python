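from datetime import datetime

import numpy as np
import pytest

from medfoes.engine import ModelParams, PopulationState
from medfoes.life_history import FixedMortality
from medfoes.params import (
    EngineConfig,
    InterventionParams,
    ReproductionParams,
    StageParams,
)
from medfoes.temperature import TemperatureSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def const_temps(days: int, T: float = 26.0) -> TemperatureSeries:
    return TemperatureSeries(datetime(2009, 9, 1), np.full(days * 24, float(T)))


@pytest.fixture
def simple_stage_params() -> StageParams:
    """Uniform base temperatures and round thermal constants, no variation."""
    return StageParams(
        T_min_e=12.0, T_min_l=12.0, T_min_p=12.0, T_min_a=12.0,
        K_e=30.0, K_l=100.0, K_p=150.0, K_a=60.0, gamma=0.0,
    )


def immortal_params(sp: StageParams, r: float = 0.0, **interv) -> ModelParams:
    """No deaths, optional reproduction — for bookkeeping-focused tests."""
    return ModelParams(
        stage=sp,
        repro=ReproductionParams(r=r, r_var=0.0, female_fraction=1.0),
        interv=InterventionParams(**interv) if interv else InterventionParams(t_S=1e6),
        engine=EngineConfig(),
        fixed_mortality=FixedMortality(0.0, 0.0, 0.0, 0.0),
    )


def mature_adults(n: int) -> PopulationState:
    return PopulationState(
        stage=[4] * n,
        accumulated=[0.0] * n,
        threshold=[np.inf] * n,
        fertile=[True] * n,
        birth_hour=[0] * n,
    )
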