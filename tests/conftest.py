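"""Shared fixtures.

Cheap geometric fixtures are module-independent; the calibrated reference
model (stiffness + growth-rate calibration and the 22-40 week run) is
expensive and built once per session, shared by the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fetallv import (
    FetalLVGrowthModel,
    GeometryParams,
    PassiveMaterial,
    build_lv_mesh,
    inflate,
    reference_geometry,
)


@pytest.fixture(scope="session")
def ref_params() -> GeometryParams:
    return reference_geometry()


@pytest.fixture(scope="session")
def ref_mesh(ref_params):
    return build_lv_mesh(ref_params)


@pytest.fixture(scope="session")
def soft_material() -> PassiveMaterial:
    # fetal-scale stiffness near the calibrated value; fixed here so unit
    # tests do not depend on the calibration loop
    return PassiveMaterial(C=0.6)


@pytest.fixture(scope="session")
def ed_state(ref_mesh, soft_material):
    """Reference mesh inflated to the median end-diastolic pressure."""
    return inflate(ref_mesh, soft_material, 0.75)


@pytest.fixture(scope="session")
def fitted_reference():
    """Fully calibrated reference model (stiffness + growth rate + run)."""
    return FetalLVGrowthModel().fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
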