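import numpy as np
import pytest

from qsarprofiler.base import DescriptorSpec, ModelMetadata, TrainingRecord
from qsarprofiler.fixtures import FixtureConfig, make_lda_fixture, make_mlr_fixture
from qsarprofiler.mlr import fit_mlr


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


@pytest.fixture
def mlr_fixture():
    return make_mlr_fixture(FixtureConfig(n=30, p=3, seed=7))


@pytest.fixture
def lda_fixture():
    return make_lda_fixture(FixtureConfig(n=40, p=3, class_separation=5.0, seed=7))


@pytest.fixture
def simple_line_model():
    """Noiseless y = 1 + 2x on x = 1..5: an exact fit with s = 0."""
    specs = [DescriptorSpec(name="x", source="supplied")]
    training = [
        TrainingRecord(id=f"c{i}", descriptor_values=(float(i),), y=1.0 + 2.0 * i)
        for i in range(1, 6)
    ]
    return fit_mlr(specs, training, metadata=ModelMetadata(model_id="line"))
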