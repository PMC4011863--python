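import numpy as np
import pytest

import spadefoot as sf


@pytest.fixture
def three_tip():
    """((a:1,b:1):1,c:2); — the worked 3-tip example used throughout."""
    return sf.read_newick("((a:1,b:1):1,c:2);")


@pytest.fixture(scope="session")
def yule16():
    return sf.sim_yule_tree(16, 150.0, seed=42)


@pytest.fixture(scope="session")
def yule64():
    return sf.sim_yule_tree(64, 150.0, seed=43)


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """One full synthetic study data set, also written to disk."""
    from spadefoot.simulate import make_study_fixture

    out = tmp_path_factory.mktemp("fixture")
    fx = make_study_fixture(20140506, out_dir=out)
    return fx, out


def assert_symmetric_psd(V: np.ndarray, jitter_scale: float = 1e-10):
    assert np.allclose(V, V.T)
    jitter = jitter_scale * np.trace(V) / len(V)
    np.linalg.cholesky(V + jitter * np.eye(len(V)))
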