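import numpy as np
import pytest

from priodyn import ModelSpec, TimeSeriesPair, build_model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def scalar_linear_model():
    """Fully linear scalar model with hand-set weights A'=0.5, K=1, Cy=1, Cz=1."""
    spec = ModelSpec(n_y=1, n_z=1, n_x=1, n_1=1)
    model = build_model(spec, seed=0)
    model.section1.cell.A.W[...] = [[0.5]]
    model.section1.cell.K.W[...] = [[1.0]]
    model.Cy1.W[...] = [[1.0]]
    model.Cz1.W[...] = [[1.0]]
    return model


@pytest.fixture()
def small_linear_data(rng):
    """Short series from a stable 3-state predictor-form linear system."""
    T, n_y, n_z, n_x = 600, 2, 1, 3
    A = 0.8 * np.eye(n_x) + 0.05 * rng.standard_normal((n_x, n_x))
    K = 0.1 * rng.standard_normal((n_x, n_y))
    Cy = rng.standard_normal((n_y, n_x))
    Cz = rng.standard_normal((n_z, n_x))
    x = np.zeros(n_x)
    Y = np.empty((T, n_y))
    Z = np.empty((T, n_z))
    for t in range(T):
        Y[t] = Cy @ x + 0.3 * rng.standard_normal(n_y)
        Z[t] = Cz @ x + 0.1 * rng.standard_normal(n_z)
        x = A @ x + K @ Y[t]
    return TimeSeriesPair(Y=Y, Z=Z)
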