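import numpy as np
import pytest

from cav3perm.constants import PhysicalConstants
from cav3perm.simulate import GatingParams, IonSpecies, ChannelModel, VoltageProtocol


@pytest.fixture(scope="session")
def constants() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture
def simple_gating() -> GatingParams:
    return GatingParams(
        act_v_half=-50.0, act_slope=5.0, inact_v_half=-75.0, inact_slope=5.0,
        tau_act=2.0, tau_inact=20.0,
    )


@pytest.fixture
def short_protocol() -> VoltageProtocol:
    """Small, fast protocol for unit tests."""
    return VoltageProtocol(
        holding_mV=-110.0, step_start_mV=-80.0, step_stop_mV=80.0,
        step_increment_mV=20.0, step_duration_ms=50.0, baseline_ms=5.0,
        sampling_rate_hz=10_000.0,
    )


@pytest.fixture
def ohmic_model(simple_gating) -> ChannelModel:
    """Pure leak cell: no permeant species, no noise."""
    return ChannelModel(
        ions=(IonSpecies("Na", 1, 0.0, 140.0, permeability=0.0),),
        gating=simple_gating,
        leak_conductance_nS=2.0,
        leak_reversal_mV=-10.0,
        noise_sd_pA=0.0,
        seed=0,
    )
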