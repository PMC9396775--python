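import numpy as np
import pytest

from abfold import ABSequence, HybridConfig, PSOConfig, TabuConfig, fibonacci_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fib13():
    return fibonacci_sequence(13)


@pytest.fixture
def tiny_config():
    """Small, fast configuration for functional (non-benchmark) tests."""
    return HybridConfig(
        total_iterations=120,
        pso=PSOConfig(swarm_size=30, iterations=120),
        tabu=TabuConfig(iterations=120),
        window=30,
    )


def random_instance(rng, n_min=3, n_max=20):
    """Random (sequence string, angle vector) pair for cross-checks."""
    n = int(rng.integers(n_min, n_max + 1))
    seq = "".join(rng.choice(list("AB"), size=n))
    angles = rng.uniform(-np.pi, np.pi, size=n - 2)
    return seq, angles
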