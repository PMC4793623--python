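"""Synthetic dataset generation and brute-force test oracles.

The generator emulates the statistical structure the path-decay predictor
relies on: chemically similar drugs tend to share protein targets.  Drugs
and targets are partitioned into matched clusters; within-cluster
similarities are high, between-cluster similarities low, and interactions
are planted inside matched clusters.  Gaussian noise on the similarity
entries (symmetrised by averaging, then clipped to [0, 1]) stresses the
similarity cutoff and the ranking logic.

The brute-force path enumerator here is the independent oracle for the
depth-first traversal: it tries every ordered node sequence and keeps the
ones that are genuine simple paths.  It is deliberately exponential and
guarded to tiny graphs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dataset_io import DTIDataset
from .hetgraph import HetGraph, NodeKey
from .pathscore import Path

#: node-count guard for the exhaustive oracle
BRUTE_FORCE_MAX_NODES = 20


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-cluster synthetic dataset.

    Drugs and targets are split into ``n_clusters`` matched groups
    (cluster i of drugs is paired with cluster i of targets).  Similarity
    entries are drawn around ``within_cluster_sim`` inside a group and
    ``between_cluster_sim`` across groups, with ``noise_sd`` Gaussian
    noise; interactions are Bernoulli(``interaction_density``) within
    matched clusters only.
    """

    n_drugs: int = 12
    n_targets: int = 10
    n_clusters: int = 3
    within_cluster_sim: float = 0.9
    between_cluster_sim: float = 0.1
    interaction_density: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_targets, self.n_clusters) < 1:
            raise ValueError("sizes and cluster count must be positive")
        if self.n_clusters > min(self.n_drugs, self.n_targets):
            raise ValueError("more clusters than drugs or targets")
        if not 0.0 < self.within_cluster_sim <= 1.0:
            raise ValueError("within_cluster_sim must lie in (0, 1]")
        if not 0.0 <= self.between_cluster_sim < 1.0:
            raise ValueError("between_cluster_sim must lie in [0, 1)")
        if self.within_cluster_sim <= self.between_cluster_sim:
            raise ValueError("within-cluster similarity must exceed between-cluster")
        if not 0.0 < self.interaction_density <= 1.0:
            raise ValueError("interaction_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _clusters(n: int, k: int) -> np.ndarray:
    """Assign n items to k contiguous, near-equal clusters."""
    return np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))


def _similarity(labels: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    base = np.where(same, spec.within_cluster_sim, spec.between_cluster_sim)
    noisy = base + rng.normal(0.0, spec.noise_sd, base.shape) if spec.noise_sd else base
    sym = (noisy + noisy.T) / 2.0
    sym = np.clip(sym, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return sym


def generate_dataset(spec: FixtureSpec) -> DTIDataset:
    """Generate a planted-cluster dataset; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"D{i:03d}" for i in range(spec.n_drugs)]
    target_ids = [f"T{j:03d}" for j in range(spec.n_targets)]
    dlab = _clusters(spec.n_drugs, spec.n_clusters)
    tlab = _clusters(spec.n_targets, spec.n_clusters)

    drug_sim = _similarity(dlab, spec, rng)
    target_sim = _similarity(tlab, spec, rng)

    matched = dlab[:, None] == tlab[None, :]
    draws = rng.random((spec.n_drugs, spec.n_targets))
    interactions = (matched & (draws < spec.interaction_density)).astype(float)
    if interactions.sum() == 0:
        raise ValueError(
            "interaction_density produced zero interactions; raise the density "
            "or change the seed"
        )
    return DTIDataset(drug_ids, target_ids, interactions, drug_sim, target_sim)


def brute_force_paths(
    hg: HetGraph, source: NodeKey, sink: NodeKey, max_len: int
) -> list[Path]:
    """Exhaustive simple-path oracle over all node sequences.

    Enumerates every ordered selection of distinct intermediate nodes up to
    ``max_len - 1`` long and keeps sequences whose consecutive pairs are
    all edges.  Guarded to graphs of at most ``BRUTE_FORCE_MAX_NODES``.
    """
    g = hg.graph
    if g.number_of_nodes() > BRUTE_FORCE_MAX_NODES:
        raise ValueError(
            f"brute-force oracle limited to {BRUTE_FORCE_MAX_NODES} nodes"
        )
    if source not in g or sink not in g:
        raise KeyError("source or sink not in graph")
    others = [n for n in g.nodes if n not in (source, sink)]
    found: list[Path] = []
    for n_mid in range(0, max(max_len, 0)):
        for mids in itertools.permutations(others, n_mid):
            seq = (source, *mids, sink)
            if all(g.has_edge(a, b) for a, b in itertools.pairwise(seq)):
                found.append(
                    Path(
                        seq,
                        tuple(
                            g.edges[a, b]["weight"]
                            for a, b in itertools.pairwise(seq)
                        ),
                    )
                )
    return found
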