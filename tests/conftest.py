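import numpy as np
import pytest

from phormidium import simulate as sim
from phormidium.kinetics import KineticParams, params_for_agar


@pytest.fixture
def anchor_params_15() -> KineticParams:
    """Kinetic parameters of the 1.5% agar condition."""
    return params_for_agar(1.5)


@pytest.fixture
def anchor_params_20() -> KineticParams:
    return params_for_agar(2.0)


@pytest.fixture
def constant_speed_params() -> KineticParams:
    """Degenerate law: v_max = v_term (no decay)."""
    return KineticParams(v_term=0.2, v_max=0.2, tau=100.0)


def single_filament_state(
    params: KineticParams,
    kappa: float = 0.0,
    length: float = 50.0,
    heading: float = 0.0,
    next_reversal: float = 1e12,
    seed: int = 0,
    seed_trail: bool = True,
) -> sim.PlateState:
    """One filament on an otherwise empty plate, encounters off."""
    fil = sim.make_filament(
        (0.0, 0.0), heading, length, params, next_reversal=next_reversal
    )
    substrate = sim.SubstrateParams(
        kinetics=params, kappa=kappa, submerged=False, agar_percent=1.5
    )
    state = sim.PlateState(
        filaments=[fil],
        trails=sim.SheathTrailStore(radius=fil.width / 2.0),
        substrate=substrate,
        clock=0.0,
        rng=np.random.default_rng(seed),
        encounters_enabled=False,
    )
    if seed_trail:
        sim._deposit_along_polyline(state.trails, fil)
    return state
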