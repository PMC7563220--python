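"""Shared fixtures.

The FDTD solves are the expensive part of the suite, so field sets for the
standard benchmark fixtures are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from htplan.fdtd import ApplicatorModel, SolverSettings, assign_material_grids, solve_all_channels
from htplan.fixtures import disk_phantom
from htplan.phantom import PhantomParams, generate_phantom
from htplan.tissues import build_scheme, default_property_table


@pytest.fixture(scope="session")
def table():
    return default_property_table()


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomParams(), seed=1)


@pytest.fixture(scope="session")
def disk_applicator():
    """Compact symmetric ring around the homogeneous disk fixture."""
    return ApplicatorModel(
        n_channels=12, ring_radius_mm=200.0, shell_inner_radius_mm=220.0,
        air_margin_mm=30.0,
    )


@pytest.fixture(scope="session")
def disk_setup(table, disk_applicator):
    """(materials, fieldset) for the centered-target muscle disk."""
    settings = SolverSettings()
    phantom = disk_phantom(radius_mm=80.0, target_radius_mm=25.0)
    mats = assign_material_grids(
        phantom, build_scheme("detailed"), table, disk_applicator, settings
    )
    fields = solve_all_channels(mats, disk_applicator, settings)
    return mats, fields


@pytest.fixture(scope="session")
def disk_setup_3ch(table):
    """3-channel reduction of the disk fixture for exhaustive phase search."""
    settings = SolverSettings()
    app = ApplicatorModel(
        n_channels=3, ring_radius_mm=200.0, shell_inner_radius_mm=220.0,
        air_margin_mm=30.0,
    )
    phantom = disk_phantom(radius_mm=80.0, target_radius_mm=25.0)
    mats = assign_material_grids(
        phantom, build_scheme("detailed"), table, app, settings
    )
    fields = solve_all_channels(mats, app, settings)
    return mats, fields, app
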