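import numpy as np
import pytest

from efptrack.cellgeom import Spherocylinder
from efptrack.kinetic_sim import SimConfig, TwoStateModel


@pytest.fixture(scope="session")
def cell() -> Spherocylinder:
    """The reference 4 x 0.9 µm cell geometry."""
    return Spherocylinder(total_length=4.0, diameter=0.9)


@pytest.fixture(scope="session")
def giant_cell() -> Spherocylinder:
    """A cell scaled x100 so confinement is irrelevant (free diffusion)."""
    return Spherocylinder(total_length=400.0, diameter=90.0)


@pytest.fixture(scope="session")
def efp_model() -> TwoStateModel:
    """Wild-type two-state parameters with exchange lifetimes."""
    return TwoStateModel.with_lifetimes(
        D_slow=0.2, D_fast=4.3, tau_free=16.0, tau_bound=7.0,
        sigma_slow=50.0, sigma_fast=75.0,
    )


@pytest.fixture(scope="session")
def efp_static_model() -> TwoStateModel:
    """Static (non-exchanging) wild-type mixture at f_slow = 0.30."""
    return TwoStateModel(
        D_slow=0.2, D_fast=4.3, f_slow=0.30, sigma_slow=50.0, sigma_fast=75.0
    )


@pytest.fixture(scope="session")
def seven_frame_config(cell) -> SimConfig:
    """Seven frames at 2 ms in the reference cell (six analysis steps)."""
    return SimConfig(n_frames=7, cell=cell)
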