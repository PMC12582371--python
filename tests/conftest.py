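import numpy as np
import pytest

from ace.config import RunConfig
from ace.pipeline import preprocess_dataset
from ace.synthetic import easy_mosaic


@pytest.fixture(scope="session")
def easy():
    """The canonical 700-cell mosaic fixture plus its ground truth."""
    return easy_mosaic()


@pytest.fixture(scope="session")
def easy_inputs(easy):
    """Reduced, center-corrected per-modality inputs for the easy mosaic."""
    ds, _ = easy
    return preprocess_dataset(ds, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
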