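import numpy as np
import pytest

from cropseries.pipeline import run_pipeline
from cropseries.synthetic_data import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def e2e_results():
    """Full 13-year 64x64 pipeline run on the default study conditions."""
    return run_pipeline({"scene": {"seed": 1}})


@pytest.fixture()
def small_scene():
    """One-year 16x16 scene with modest contamination."""
    spec = SceneSpec(n_rows=16, n_cols=16, years=(2016, 2016), seed=3)
    return spec, generate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
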