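"""Heterogeneous drug/target graph construction.

The prediction graph has one node per drug and one per protein target and
three edge types:

* drug-drug edges weighted by chemical similarity,
* target-target edges weighted by sequence similarity,
* drug-target edges of weight exactly 1 for each known interaction.

Similarity edges below ``sim_cutoff`` are dropped at construction time
(similarity exactly equal to the cutoff is kept); self-similarity never
creates an edge.  Nodes are keyed internally as ``("d", id)`` / ``("t", id)``
tuples so drug and target identifier namespaces can overlap.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

from .dataset_io import DTIDataset

DRUG = "d"
TARGET = "t"

NodeKey = tuple[str, str]


def drug_node(drug_id: str) -> NodeKey:
    return (DRUG, drug_id)


def target_node(target_id: str) -> NodeKey:
    return (TARGET, target_id)


@dataclass(frozen=True)
class ScoreParams:
    """Scoring parameters.

    alpha:
        Decay exponent applied as ``alpha * len(path)`` to each path's
        edge-weight product; larger values penalise long paths harder.
        Default 2.26.
    max_len:
        Maximum number of edges per path.  Default 3.
    sim_cutoff:
        Similarity edges strictly below this value are excluded from the
        graph.  Default 0.5; set to 0 to keep every positive similarity.
    """

    alpha: float = 2.26
    max_len: int = 3
    sim_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.max_len < 1:
            raise ValueError(f"max_len must be >= 1, got {self.max_len}")
        if not 0.0 <= self.sim_cutoff <= 1.0:
            raise ValueError(f"sim_cutoff must lie in [0, 1], got {self.sim_cutoff}")


@dataclass
class HetGraph:
    """Weighted undirected heterogeneous graph plus the label order it was
    built from.  ``graph`` is a :class:`networkx.Graph` whose edges carry
    ``weight`` and ``kind`` (``dd``, ``tt`` or ``dt``) attributes."""

    graph: nx.Graph
    drug_ids: list[str]
    target_ids: list[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_interaction(self, drug_id: str, target_id: str) -> bool:
        return self.graph.has_edge(drug_node(drug_id), target_node(target_id))

    def interaction_edges(self) -> list[tuple[str, str]]:
        return [
            (u[1], v[1]) if u[0] == DRUG else (v[1], u[1])
            for u, v, k in self.graph.edges(data="kind")
            if k == "dt"
        ]

    def copy(self) -> "HetGraph":
        return HetGraph(self.graph.copy(), list(self.drug_ids), list(self.target_ids))

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency over drugs-then-targets node order."""
        order = [drug_node(d) for d in self.drug_ids] + [
            target_node(t) for t in self.target_ids
        ]
        return nx.to_numpy_array(self.graph, nodelist=order, weight="weight")


def build_graph(dataset: DTIDataset, params: ScoreParams | None = None) -> HetGraph:
    """Build the heterogeneous graph for a dataset.

    One drug-target edge of weight 1 is added per known interaction; one
    similarity edge per off-diagonal similarity entry at or above
    ``params.sim_cutoff``, weighted by that similarity.  Zero similarities
    never create edges regardless of the cutoff.
    """
    params = params or ScoreParams()
    g = nx.Graph()
    g.add_nodes_from((drug_node(d) for d in dataset.drug_ids), kind=DRUG)
    g.add_nodes_from((target_node(t) for t in dataset.target_ids), kind=TARGET)

    _add_similarity_edges(
        g, dataset.drug_sim, dataset.drug_ids, drug_node, "dd", params.sim_cutoff
    )
    _add_similarity_edges(
        g, dataset.target_sim, dataset.target_ids, target_node, "tt", params.sim_cutoff
    )
    di, ti = np.nonzero(dataset.interactions)
    for i, j in zip(di, ti):
        g.add_edge(
            drug_node(dataset.drug_ids[i]),
            target_node(dataset.target_ids[j]),
            weight=1.0,
            kind="dt",
        )
    return HetGraph(g, list(dataset.drug_ids), list(dataset.target_ids))


def _add_similarity_edges(g, sim, ids, make_node, kind, cutoff) -> None:
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    weights = sim[iu, ju]
    keep = (weights >= cutoff) & (weights > 0.0)
    for i, j, w in zip(iu[keep], ju[keep], weights[keep]):
        g.add_edge(make_node(ids[i]), make_node(ids[j]), weight=float(w), kind=kind)


def remove_interaction(hg: HetGraph, drug_id: str, target_id: str) -> HetGraph:
    """Return a copy of the graph with one drug-target edge removed.

    Raises ``KeyError`` if the edge is absent, so cross-validation loops
    cannot silently remove nothing.
    """
    if not hg.has_interaction(drug_id, target_id):
        raise KeyError(
            f"no interaction edge between drug {drug_id!r} and target {target_id!r}"
        )
    out = hg.copy()
    out.graph.remove_edge(drug_node(drug_id), target_node(target_id))
    return out


@contextmanager
def interactions_removed(
    hg: HetGraph, pairs: Iterable[tuple[str, str]]
) -> Iterator[HetGraph]:
    """Temporarily remove interaction edges in place, restoring them on exit.

    This is the patching primitive used by the cross-validation loops: one
    edge (or a drug's whole edge set) is removed for a round and put back
    afterwards, avoiding a full graph rebuild per round.
    """
    pairs = list(pairs)
    for d, t in pairs:
        if not hg.has_interaction(d, t):
            raise KeyError(f"no interaction edge between drug {d!r} and target {t!r}")
    try:
        for d, t in pairs:
            hg.graph.remove_edge(drug_node(d), target_node(t))
        yield hg
    finally:
        for d, t in pairs:
            hg.graph.add_edge(drug_node(d), target_node(t), weight=1.0, kind="dt")


def write_edge_list(hg: HetGraph, path: str | Path) -> None:
    """Export the graph as a tab-separated edge list for inspection."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\ttype\tweight\n")
        for u, v, data in sorted(hg.graph.edges(data=True)):
            fh.write(f"{u[1]}\t{v[1]}\t{data['kind']}\t{data['weight']:.10g}\n")
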