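import pytest

from svarcall.pipeline import train_on_simulated
from svarcall.simulate import make_worked_example


@pytest.fixture(scope="session")
def trained_model(tmp_path_factory):
    """Classifier + conformal predictor trained on the simulated labeled cohort."""
    tmp = tmp_path_factory.mktemp("training")
    model, mcp = train_on_simulated(seed=7, tmp_dir=str(tmp))
    return model, mcp


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The bundled tiny study: 12 SVs, purity 0.6, ploidy 2.0, generated fresh."""
    tmp = tmp_path_factory.mktemp("worked_example")
    return make_worked_example(str(tmp), seed=11)
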