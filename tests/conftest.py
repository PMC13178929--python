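import numpy as np
import pytest

from isolens.hier_model import ModelSpec
from isolens.synthetic import default_presets, generate_lake

TINY_LAYER_CSV = """\
fish_id,lake,species,eye,layer_index,diameter_mm,d13C,d15N,role,measured,sample_kind
F1,Floods,Arctic Charr,right,1,4.9,-27.5,11.2,outermost,True,primary
F1,Floods,Arctic Charr,right,2,2.9,-28.1,10.4,hard,True,primary
F1,Floods,Arctic Charr,right,3,1.8,-29.0,9.1,hard,True,primary
F1,Floods,Arctic Charr,right,4,0.7,-30.2,9.6,core,True,primary
"""


@pytest.fixture
def tiny_layer_csv(tmp_path):
    path = tmp_path / "layers.csv"
    path.write_text(TINY_LAYER_CSV)
    return path


@pytest.fixture(scope="session")
def fast_spec():
    """Short MCMC settings for unit tests (kept length still >= 100)."""
    return ModelSpec(n_chains=3, n_iter=1500, n_burnin=500, seed=7)


@pytest.fixture(scope="session")
def floods_sim():
    """One simulated Floods lake with its generating truth."""
    preset = default_presets()["Floods"]
    layers, fishes, truth = generate_lake(preset, seed=42)
    return preset, layers, fishes, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
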