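"""Shared fixtures: the default phantom at working resolution and the
solved optimal (60-degree, over-tumor holes) configuration, reused across
test modules to keep the suite inside a desk-scale budget."""

import numpy as np
import pytest

from ttdose import (
    HeadGeometry,
    assign_conductivities,
    default_pathology,
    layout_circumferential,
    make_sr_phantom,
    solve_fields,
)

WORK_VOXEL_MM = 3.0


@pytest.fixture(scope="session")
def geom():
    return HeadGeometry()


@pytest.fixture(scope="session")
def pathology(geom):
    return default_pathology(geom)


@pytest.fixture(scope="session")
def phantom_holes(geom, pathology):
    """Default phantom with pathology and the over-tumor quincunx."""
    vol, path, quincunx = make_sr_phantom(geom, WORK_VOXEL_MM, "over_tumor", pathology=pathology)
    return vol, quincunx


@pytest.fixture(scope="session")
def phantom_control(geom, pathology):
    vol, _, _ = make_sr_phantom(geom, WORK_VOXEL_MM, "none", pathology=pathology)
    return vol


@pytest.fixture(scope="session")
def cv_holes(phantom_holes):
    return assign_conductivities(phantom_holes[0])


@pytest.fixture(scope="session")
def cv_control(phantom_control):
    return assign_conductivities(phantom_control)


@pytest.fixture(scope="session")
def pair60(geom):
    return layout_circumferential(60.0, geom)


@pytest.fixture(scope="session")
def sol_holes_60(cv_holes, pair60):
    return solve_fields(cv_holes, pair60)


@pytest.fixture(scope="session")
def sol_control_60(cv_control, pair60):
    return solve_fields(cv_control, pair60)


@pytest.fixture(scope="session")
def brain_mask(phantom_control):
    return phantom_control.mask(4, 5)  # GM | WM
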