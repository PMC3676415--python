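import numpy as np
import pandas as pd
import pytest

from saltgenes.preprocess import ExpressionMatrix


def make_matrix(values: np.ndarray, labels: list[int], probe_prefix: str = "P") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a raw array and a label list."""
    values = np.asarray(values, dtype=float)
    probes = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        labels={s: l for s, l in zip(samples, labels)},
    )


@pytest.fixture
def two_group_matrix() -> ExpressionMatrix:
    """20 probes x 8 samples; probes 0-4 separate the classes cleanly."""
    rng = np.random.default_rng(42)
    labels = [1, 1, 1, 1, -1, -1, -1, -1]
    X = rng.normal(0, 1, size=(20, 8))
    X[:5, 4:] += 4.0
    return make_matrix(X, labels)


@pytest.fixture
def random_matrix() -> ExpressionMatrix:
    """Pure-noise 30 x 10 matrix, balanced labels."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(8, 1, size=(30, 10)), [1] * 5 + [-1] * 5)
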