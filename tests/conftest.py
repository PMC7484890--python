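import numpy as np
import pytest

import cinemv as cm


@pytest.fixture(scope="session")
def geom():
    return cm.LinacGeometry()


@pytest.fixture(scope="session")
def bb_suite(tmp_path_factory):
    """Synthetic BB-phantom planning suite (CT + RTSTRUCT + RTPLAN) on disk,
    with the readers already applied."""
    out = tmp_path_factory.mktemp("bb_suite")
    spec = cm.FixtureSpec.bb_validation(seed=1)
    paths = cm.write_fixture_suite(spec, out)
    ct = cm.read_ct_geometry(paths["ct_dir"])
    structures = cm.read_structure_set(paths["rtstruct"], ct)
    plan = cm.read_plan(paths["rtplan"])
    return {"spec": spec, "paths": paths, "ct": ct, "structures": structures, "plan": plan}


@pytest.fixture(scope="session")
def bb_grid(bb_suite):
    return cm.voxelize_roi(bb_suite["structures"]["BB"], bb_suite["ct"])


@pytest.fixture(scope="session")
def bb_pset(bb_suite):
    """Full 720-angle precomputed projection set for the BB ROI."""
    return cm.precompute_set(bb_suite["structures"], bb_suite["plan"], bb_suite["ct"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
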