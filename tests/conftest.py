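import numpy as np
import pytest

import voxdose as vd


@pytest.fixture(scope="session")
def template():
    return vd.default_template()


@pytest.fixture(scope="session")
def truth(template):
    return vd.SimulationTruth(effect_region=vd.default_effect_region(template))


@pytest.fixture(scope="session")
def small_cohort(template, truth):
    """Shared 60-patient cohort with a planted dysuria effect (seed fixed)."""
    cfg = vd.CohortConfig(n_patients=60, template=template, seed=42)
    grids, records, cov = vd.simulate_cohort(
        cfg, truth, endpoints=[vd.DEFAULT_ENDPOINTS["dysuria"]])
    return grids, records, cov


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_grid(rng, dims=(5, 4, 3), spacing=(1.0, 1.0, 2.0), kind="dose"):
    data = rng.random(dims).astype(np.float32) * 50
    return vd.VoxelGrid(data, spacing=spacing, payload_kind=kind)


@pytest.fixture()
def make_grid(rng):
    def _make(dims=(5, 4, 3), **kw):
        return random_grid(rng, dims, **kw)
    return _make


def full_mask(grid):
    return grid.with_payload(np.ones(grid.dims, dtype=np.uint8), "mask")


@pytest.fixture()
def make_mask():
    return full_mask
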