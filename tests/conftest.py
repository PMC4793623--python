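import numpy as np
import pytest

from daspfind import DTIDataset, FixtureSpec, ScoreParams, build_graph, generate_dataset


def random_dataset(rng: np.random.Generator, n_drugs: int, n_targets: int) -> DTIDataset:
    """Unstructured random dataset for oracle comparisons."""

    def sim(n):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        return m

    inter = (rng.random((n_drugs, n_targets)) < 0.3).astype(float)
    if inter.sum() == 0:
        inter[rng.integers(n_drugs), rng.integers(n_targets)] = 1.0
    return DTIDataset(
        [f"D{i}" for i in range(n_drugs)],
        [f"T{j}" for j in range(n_targets)],
        inter,
        sim(n_drugs),
        sim(n_targets),
    )


@pytest.fixture
def toy_dataset() -> DTIDataset:
    """2 drugs (sim 0.8), 2 targets (sim 0.3), single interaction d1-t1."""
    return DTIDataset(
        ["d1", "d2"],
        ["t1", "t2"],
        np.array([[1.0, 0.0], [0.0, 0.0]]),
        np.array([[1.0, 0.8], [0.8, 1.0]]),
        np.array([[1.0, 0.3], [0.3, 1.0]]),
    )


@pytest.fixture
def toy_graph(toy_dataset):
    return build_graph(toy_dataset, ScoreParams())


@pytest.fixture
def fixture_10x8() -> DTIDataset:
    """Small clustered dataset used across modules."""
    return generate_dataset(
        FixtureSpec(n_drugs=10, n_targets=8, n_clusters=2, seed=11)
    )


@pytest.fixture
def planted_dataset() -> DTIDataset:
    """Noise-free planted clusters: every removed link is recoverable via a
    similarity-1 twin, so cross-validation should retrieve it at rank 1."""
    return generate_dataset(
        FixtureSpec(
            n_drugs=8,
            n_targets=8,
            n_clusters=2,
            within_cluster_sim=1.0,
            between_cluster_sim=0.0,
            interaction_density=1.0,
            noise_sd=0.0,
            seed=3,
        )
    )
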