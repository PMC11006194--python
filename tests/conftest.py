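import numpy as np
import pytest

from moranamp import random_connected_weighted_graph


@pytest.fixture(scope="session")
def random_graphs():
    """Factory for reproducible batches of small random weighted graphs."""

    def make(n_graphs: int, max_n: int = 8, seed: int = 0, min_n: int = 3):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_graphs):
            N = int(rng.integers(min_n, max_n + 1))
            out.append(
                random_connected_weighted_graph(
                    N,
                    edge_density=float(rng.uniform(0.1, 0.8)),
                    weight_range=(0.2, 5.0),
                    seed=int(rng.integers(0, 2**31)),
                )
            )
        return out

    return make
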