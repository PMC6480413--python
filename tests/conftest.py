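import numpy as np
import pytest

from vanbc import VADataset, generate, make_separable_spec


@pytest.fixture
def toy_dataset():
    """The hand-countable 4-record, 2-symptom, 2-cause training set."""
    return VADataset(
        record_ids=["a", "b", "c", "d"],
        symptom_names=["s1", "s2"],
        X=np.array([[1, 0], [1, 1], [0, 1], [0, 1]]),
        y=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def separable_dataset():
    """15 causes, each with a deterministic private signature symptom."""
    return generate(make_separable_spec(M=15, N=3000, seed=11))


def random_dataset(rng, n=40, s=6, m=3):
    """Small random valid VADataset (every cause guaranteed present)."""
    causes = [f"c{i}" for i in range(m)]
    y = np.array(causes * (n // m) + causes[: n % m], dtype=object)
    rng.shuffle(y)
    X = rng.integers(0, 2, size=(n, s))
    # ensure validity: nothing else required, X already binary
    return VADataset(
        record_ids=[f"r{i}" for i in range(n)],
        symptom_names=[f"s{j}" for j in range(s)],
        X=X,
        y=y,
    )
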