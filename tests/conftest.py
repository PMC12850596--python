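import numpy as np
import pytest

from stentshield import StentSpec


@pytest.fixture
def ring_spec():
    """Reference circular-loop stack: R = 8 mm, rho = 0.2 mm, l2 = 10 mm."""
    return StentSpec(
        radius=8e-3,
        strut_radius=0.2e-3,
        length=100e-3,
        cell_length=10e-3,
        loop_types=("circular",),
    )


@pytest.fixture
def cage_spec():
    """Reference rectangular cage: N = 8 bars, L = 100 mm, rho = 0.2 mm."""
    return StentSpec(
        radius=8e-3,
        strut_radius=0.2e-3,
        length=100e-3,
        n_bars=8,
        loop_types=("rectangular",),
    )


@pytest.fixture
def grid_spec():
    """Grid stent [N, l2] = [6, 10 mm] at L = 100 mm."""
    return StentSpec(
        radius=8e-3,
        strut_radius=0.2e-3,
        length=100e-3,
        cell_length=10e-3,
        n_bars=6,
        angle_to_b0_deg=90.0,
    )


@pytest.fixture
def commercial_spec():
    """Commercial laser-cut geometry: [N, l2] = [4, 6 mm], L = 120 mm."""
    return StentSpec(
        radius=8e-3,
        strut_radius=0.05e-3,
        length=120e-3,
        cell_length=6e-3,
        n_bars=4,
        angle_to_b0_deg=0.0,
    )
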