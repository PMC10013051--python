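"""Shared fixtures: small masks, curves, networks and synthetic slices.

Everything is generated programmatically; expensive objects are session-
scoped so the mechanics-heavy tests share one equilibrated template.
"""

import numpy as np
import pytest

from laaspring.calibration import generate_synthetic_laa
from laaspring.config import RunConfig
from laaspring.geometry import BoundaryCurve
from laaspring.network import apply_lung_template, build_hex_network, solve_equilibrium


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture
def square_mask():
    m = np.zeros((20, 20), dtype=bool)
    m[5:15, 5:15] = True
    return m


@pytest.fixture
def disc_mask():
    rr, cc = np.ogrid[:64, :64]
    return (rr - 32) ** 2 + (cc - 32) ** 2 < 13**2


def circle_curve(radius: float, n: int = 256, center=(0.0, 0.0)) -> BoundaryCurve:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    return BoundaryCurve.from_samples(pts)


@pytest.fixture
def blob_mask():
    return generate_synthetic_laa(1, 500, seed=3)


@pytest.fixture(scope="session")
def small_template(config):
    """64x64 full-lung template network with its initial equilibrium."""
    lung = np.ones((64, 64), dtype=bool)
    net = build_hex_network(
        (64, 64),
        lattice_edge=config.lattice_edge,
        prestress_ratio=config.prestress_ratio,
        tension_only=config.tension_only,
    )
    net = apply_lung_template(net, lung, fixed_band=config.fixed_band)
    state = solve_equilibrium(net, config=config)
    return net, state, lung
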