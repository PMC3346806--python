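import pytest

from ckscreen.config import RunConfig
from ckscreen.fixtures import make_chemokine_fixture, make_toy_foldspace
from ckscreen.threading_engine import derive_potentials


@pytest.fixture(scope="session")
def foldspace():
    """Mixed toy fold-space library (chemokine fixture + 5 distinct folds)."""
    library, scop_map = make_toy_foldspace(seed=0)
    return library, scop_map


@pytest.fixture(scope="session")
def potentials(foldspace):
    library, _ = foldspace
    return derive_potentials(list(library))


@pytest.fixture(scope="session")
def ck_template(foldspace):
    library, _ = foldspace
    return library.get("ckfx_A")


@pytest.fixture()
def chemokine_fixture():
    return make_chemokine_fixture(seed=7)


@pytest.fixture(scope="session")
def fast_config():
    """Small synthetic end-to-end configuration (kept light for CI speed)."""
    from ckscreen.pipeline_fixture import build_fixture_config

    cfg = RunConfig(seed=11, n_shuffles=40)
    return build_fixture_config(cfg, n_decoys=30, n_homologs=5)
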