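import numpy as np
import pandas as pd
import pytest

from rearnet.discretize import DiscreteDataset


def binary_dataset(columns: dict[str, np.ndarray]) -> DiscreteDataset:
    """Wrap integer-coded columns into a DiscreteDataset with generic maps."""
    df = pd.DataFrame({k: np.asarray(v, dtype=np.int64) for k, v in columns.items()})
    maps = {
        k: {int(s): str(s) for s in range(int(df[k].max()) + 1)}
        for k in df.columns
    }
    return DiscreteDataset(df, maps)


@pytest.fixture(scope="session")
def chain_dataset():
    """A -> B -> C with strong binary CPTs (10% flip noise), n=2000."""
    rng = np.random.default_rng(42)
    n = 2000
    a = rng.integers(0, 2, n)
    b = (a ^ (rng.random(n) < 0.1)).astype(np.int64)
    c = (b ^ (rng.random(n) < 0.1)).astype(np.int64)
    return binary_dataset({"A": a, "B": b, "C": c})


@pytest.fixture(scope="session")
def collider_dataset():
    """A -> C <- B (v-structure): C = XOR(A, B) with 10% flip, n=2000."""
    rng = np.random.default_rng(43)
    n = 2000
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    c = ((a ^ b) ^ (rng.random(n) < 0.1)).astype(np.int64)
    return binary_dataset({"A": a, "B": b, "C": c})


@pytest.fixture(scope="session")
def small_study():
    from rearnet.simulate import simulate_study

    return simulate_study(n_dams=400, n_snps=40, n_causal=3, seed=11)
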