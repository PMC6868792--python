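import numpy as np
import pytest

import myoknn as mk


@pytest.fixture(scope="session")
def trained_small():
    """Decoder trained on a reduced cue protocol (2 repetitions) for unit tests."""
    return mk.train_decoder(mk.RunConfig(repetitions=2))


@pytest.fixture(scope="session")
def trained_full():
    """Decoder trained on the full 27-posture x 5-repetition protocol."""
    return mk.train_decoder(mk.RunConfig(repetitions=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_knn(X, T, k, eps, q):
    """Independent KNN oracle: explicit loop distances, full stable sort,
    explicit inverse-distance weighted mean.  Deliberately naive."""
    d = [float(np.sqrt(np.sum((np.asarray(q) - X[i]) ** 2))) for i in range(len(X))]
    order = sorted(range(len(X)), key=lambda i: (d[i], i))[:k]
    weights = [1.0 / (d[i] + eps) for i in order]
    num = sum(w * T[i] for w, i in zip(weights, order))
    return np.clip(num / sum(weights), -1.0, 1.0)
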