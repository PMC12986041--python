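import numpy as np
import pandas as pd
import pytest

from ddrcoupling.panel import STAGES
from ddrcoupling.synthetic import default_spec, generate_dataset


@pytest.fixture(scope="session")
def default_cohort():
    """One clean (batchless) draw at the full cohort sizes (158/170/352)."""
    spec = default_spec(seed=101, batch_effects=False)
    X, ann = generate_dataset(spec)
    return spec, X, ann


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-size draw for fast tests (40/40/60 samples)."""
    spec = default_spec(seed=202, batch_effects=False)
    spec.stage_sizes = {"normal": 40, "adenoma": 40, "carcinoma": 60}
    X, ann = generate_dataset(spec)
    return spec, X, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def stage_labels():
    return {s: i for i, s in enumerate(STAGES)}
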