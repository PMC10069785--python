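import numpy as np
import pandas as pd
import pytest

from eivfit import GlmFitter, MeasurementErrorSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def logistic_data(rng):
    """Small quadratic-logistic dataset with a contaminated covariate."""
    n = 300
    x = rng.standard_normal(n)
    eta = 0.5 + x - 0.3 * x**2
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta))).astype(float)
    w = x + rng.normal(0.0, 0.5, n)
    return y, x, pd.DataFrame({"w": w})


@pytest.fixture
def quad_fitter(logistic_data):
    _, _, data = logistic_data
    f = GlmFitter("binomial", ["poly(w, 2)"])
    f.builder.freeze(data)
    return f


@pytest.fixture
def me_spec():
    return MeasurementErrorSpec(["w"], 0.25)
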