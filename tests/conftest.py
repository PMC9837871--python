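"""Shared fixtures: moderately sized meshes so the suite stays fast."""

import numpy as np
import pytest

from oosme_eit import (ConductivityField, ForwardSolver, build_disk_mesh,
                       build_protocol, compute_sensitivity)
from oosme_eit.phantoms import SIGMA_FAT


@pytest.fixture(scope="session")
def mesh_small():
    """16-electrode disk at reduced resolution (~800 elements)."""
    return build_disk_mesh(100.0, 16, 900, refinement_seed=2)


@pytest.fixture(scope="session")
def mesh_tiny():
    """8-electrode disk for cheap FEM checks."""
    return build_disk_mesh(60.0, 8, 320, refinement_seed=3)


@pytest.fixture(scope="session")
def protocol_qa16():
    return build_protocol(16, 2, 2)


@pytest.fixture(scope="session")
def protocol_adj8():
    return build_protocol(8, 1, 1)


@pytest.fixture(scope="session")
def sigma_bg_small(mesh_small):
    return ConductivityField(np.full(mesh_small.n_elements, SIGMA_FAT), mesh_small)


@pytest.fixture(scope="session")
def frame_bg_small(mesh_small, sigma_bg_small, protocol_qa16):
    return ForwardSolver(mesh_small, sigma_bg_small).measure(protocol_qa16)


@pytest.fixture(scope="session")
def S_bg_small(mesh_small, sigma_bg_small, protocol_qa16):
    return compute_sensitivity(mesh_small, sigma_bg_small, protocol_qa16)
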