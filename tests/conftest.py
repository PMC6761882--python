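import numpy as np
import pytest

from tta2d.kinetics import (
    DiffusionKineticsParams,
    FractalParams,
    SecondOrderParams,
    second_order_solution,
    solve_tta_2d,
)
from tta2d.simulate import SimulationConfig, simulate_brownian


@pytest.fixture(scope="session")
def second_order_params():
    # magnitudes of the dilute-interface regime: k ~ 3e14 m^2/mol/s,
    # T0 ~ 1e-7 mol/m^2 give a half-life of ~33 ns
    return SecondOrderParams(k=3.05e14, T0=1e-7)


@pytest.fixture(scope="session")
def diffusion_params():
    return DiffusionKineticsParams(D=1.1e-9, T0=1e-7)


@pytest.fixture(scope="session")
def fractal_params():
    return FractalParams(k_frac=3e14, h=0.13, T0=1e-7)


@pytest.fixture(scope="session")
def second_order_trace(second_order_params):
    t = np.linspace(0.0, 1e-6, 200)
    return second_order_solution(second_order_params, t)


@pytest.fixture(scope="session")
def diffusion_trace(diffusion_params):
    t = np.geomspace(2e-8, 5e-6, 60)
    return solve_tta_2d(diffusion_params, t)


@pytest.fixture(scope="session")
def brownian_traj():
    cfg = SimulationConfig(seed=11, n_particles=60, n_steps=600,
                           D=2e-9, L=30e-9)
    return simulate_brownian(cfg)
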