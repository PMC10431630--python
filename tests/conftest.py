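import numpy as np
import pytest

from graphts.model import GraphTS
from graphts.synthetic import generate, planted_spec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def fit_planted(seed, n_anomalies=1, length=110, window=80, n_cells=100, **kw):
    """Generate the standard study-condition series and fit the model."""
    ts, truth = generate(planted_spec(n_anomalies, length, seed=seed, **kw))
    res = GraphTS(ts, window=window, n_cells=n_cells).fit()
    return ts, truth, res
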