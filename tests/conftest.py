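import numpy as np
import pytest

import lungtomo as lt


@pytest.fixture(scope="session")
def lung64():
    """The 64x64 lung phantom used by the replication-protocol tests."""
    return lt.make_lung_phantom(64, seed=7)


@pytest.fixture(scope="session")
def protocol_setup(lung64):
    """Phantom, geometry, system matrix and clean sinogram of the
    90-degree limited-angle protocol (built once per session)."""
    cfg = lt.bo_protocol()
    orig = lung64.image
    geo = cfg.make_geometry(orig.pixel_size)
    matrix = lt.build_system_matrix(orig, geo)
    clean = lt.forward_project(orig, matrix)
    return cfg, orig, geo, matrix, clean


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
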