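import numpy as np
import pytest

from crossmas import CountMatrix, SampleTable, SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A modest 300-gene, 3x3-sample simulated experiment with effects."""
    cfg = SimulationConfig(
        n_genes=300,
        n_per_group=3,
        class_counts={"kd_up": 5, "kd_down": 5, "oe_up": 5, "shared_up": 5},
        seed=42,
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def nb_matrix():
    """Seeded 300-gene x 4-sample overdispersed count matrix."""
    rng = np.random.default_rng(3)
    G = 300
    mu = np.exp(rng.normal(5, 1.5, G))
    depth = np.array([1.0, 1.3, 0.8, 1.1])
    Y = rng.poisson(rng.gamma(10, mu[:, None] / 10, (G, 4)) * depth).astype(int)
    return CountMatrix(
        tuple(f"g{i}" for i in range(G)), ("s1", "s2", "s3", "s4"), Y
    )


@pytest.fixture
def three_group_samples():
    return SampleTable(
        tuple(f"{c}_{i}" for c in ("WT", "KD", "OE") for i in (1, 2, 3, 4)),
        tuple(c for c in ("WT", "KD", "OE") for _ in range(4)),
    )
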