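"""Shared fixtures: physics config and forward-simulated phantom fields.

The expensive forward solves are session-scoped and reused across test
modules; every stochastic test seeds its own generator.
"""

import dataclasses

import numpy as np
import pytest

from hfcmri import (
    Disk,
    GridSpec,
    PhysicsConfig,
    Rectangle,
    birdcage_field,
    derive_hplus,
    make_phantom,
    solve_forward_ez,
)


@pytest.fixture(scope="session")
def physics():
    return PhysicsConfig()  # 3 T defaults


@pytest.fixture(scope="session")
def homog_case(physics):
    """Homogeneous GM-like phantom (sigma 0.59, eps_r 70) with its field."""
    n, dx = 65, 2e-3
    grid = GridSpec(n, n, dx, dx)
    half = (n - 1) / 2 * dx
    phantom = make_phantom(grid, [(Rectangle(-half, half, -half, half), 0.59, 70.0, 1)])
    illum = birdcage_field(grid, physics, 0.59, 70.0)
    ez = solve_forward_ez(phantom, physics, illum)
    hplus = derive_hplus(ez, physics)
    return dict(grid=grid, phantom=phantom, ez=ez, hplus=hplus, sigma=0.59, eps_r=70.0)


@pytest.fixture(scope="session")
def two_comp_case(physics):
    """Two-compartment head phantom (WM-like disk, GM-like inclusion)."""
    n, dx = 96, 1.8e-3
    grid = GridSpec(n, n, dx, dx)
    phantom = make_phantom(
        grid,
        [
            (Disk(0.0, 0.0, 0.07), 0.34, 52.0, 1),
            (Disk(0.012, 0.0, 0.04), 0.59, 73.0, 2),
        ],
    )
    mask = phantom.object_mask()
    illum = birdcage_field(grid, physics, phantom.sigma[mask].mean(), phantom.eps_r[mask].mean())
    ez = solve_forward_ez(phantom, physics, illum)
    hplus = derive_hplus(ez, physics)
    return dict(grid=grid, phantom=phantom, ez=ez, hplus=hplus, mask=mask)


def replace_values(field_map, values):
    return dataclasses.replace(field_map, values=values)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
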