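import numpy as np
import pytest

from decmscore.pipeline import RunConfig, run_pipeline
from decmscore.simulate import SceneConfig, render_slide


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def he_slide():
    """A small mixed HE scene reused across detection/morphometry tests."""
    cfg = SceneConfig(stain="he",
                      counts={"nucleus_1": 6, "nucleus_2": 4, "dust": 8},
                      rng_seed=7)
    return render_slide(cfg)


@pytest.fixture(scope="session")
def dapi_slide():
    cfg = SceneConfig(stain="dapi", counts={"nucleus_1": 5, "dust": 20}, rng_seed=3)
    return render_slide(cfg)


@pytest.fixture(scope="session")
def study_report():
    """One full default synthetic study (5 groups x 4 stains x 15 sections),
    shared by the end-to-end and acceptance tests."""
    return run_pipeline(RunConfig(master_seed=0, log_level="WARNING"))
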