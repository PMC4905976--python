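import numpy as np
import pytest

from cnpmr import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def white_noise_pair(rng):
    """Two independent white-noise channels."""
    return TimeSeriesSet(rng.standard_normal((400, 2)), ("a", "b"))


@pytest.fixture
def small_design(rng):
    """A 20 x 4 random design for oracle comparisons."""
    from cnpmr.embedding import EmbeddedDesign

    X = rng.standard_normal((20, 4))
    y = rng.standard_normal(20)
    labels = tuple(("u", k) for k in (1, 2)) + tuple(("v", k) for k in (1, 2))
    return EmbeddedDesign(response=y, predictors=X, labels=labels, tau=1, dim_d=2, t_offset=2)


def naive_npmr_predictions(y, X, sigmas, queries=None):
    """Literal double-loop leave-one-out NPMR, the independent oracle.

    ``queries`` optionally overrides the query coordinates per point
    (used to check nudged sensitivity predictions).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Q = X if queries is None else np.asarray(queries, float)
    T, m = X.shape
    sigmas = np.broadcast_to(np.asarray(sigmas, float), (m,))
    out = np.empty(T)
    for t in range(T):
        num = 0.0
        den = 0.0
        for i in range(T):
            if i == t:
                continue
            w = 1.0
            for j in range(m):
                w *= np.exp(-0.5 * ((X[i, j] - Q[t, j]) / sigmas[j]) ** 2)
            num += y[i] * w
            den += w
        out[t] = num / den if den > 0 else np.nan
    return out
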