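"""High-confidence PPI filtering and first-neighbour subnetwork extraction.

A cluster-related subnetwork is built by locating a cluster's proteins
(the seeds) in the confidence-filtered interactome and taking them together
with their first direct neighbours; the subnetwork keeps every interactome
edge among the selected nodes (induced subgraph), so neighbour-neighbour
edges are retained — without them clique-based hub scoring would degenerate
to node degree on star-shaped neighbourhoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: STRING "high confidence" on the integer 0-1000 scale (0.7 * 1000).
MIN_COMBINED_SCORE: int = 700


def filter_high_confidence(
    net: nx.Graph,
    min_score: int = MIN_COMBINED_SCORE,
    keep_isolated: bool = False,
) -> nx.Graph:
    """Keep exactly the edges with ``combined_score >= min_score``.

    Nodes left without any retained edge are dropped unless
    ``keep_isolated`` is set.
    """
    out = nx.Graph()
    if keep_isolated:
        out.add_nodes_from(net.nodes)
    for u, v, d in net.edges(data=True):
        if d["combined_score"] >= min_score:
            out.add_edge(u, v, combined_score=d["combined_score"])
    return out


@dataclass(frozen=True)
class Subnetwork:
    """Seeds plus first neighbours, with the induced edge set.

    ``missing_seeds`` records requested seeds absent from the interactome
    (ID-mapping losses are reported, never silently dropped).
    """

    label: int | str
    seeds: frozenset[str]
    graph: nx.Graph = field(compare=False)
    missing_seeds: tuple[str, ...] = ()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __post_init__(self) -> None:
        if not self.seeds <= frozenset(self.graph.nodes):
            raise ValueError(f"subnetwork {self.label}: seeds must be nodes")


def extract_subnetwork(
    net: nx.Graph, seeds, label: int | str = ""
) -> Subnetwork:
    """Select seeds and their first neighbours; induce all edges among them.

    Raises ``ValueError`` when no seed is present in the network.
    """
    requested = sorted(set(seeds))
    present = [s for s in requested if s in net]
    missing = tuple(s for s in requested if s not in net)
    if not present:
        raise ValueError(
            f"subnetwork {label!r}: no seed present in the network "
            f"(missing: {list(missing)})"
        )
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(
        (u, v, d) for u, v, d in net.subgraph(nodes).edges(data=True)
    )
    return Subnetwork(
        label=label,
        seeds=frozenset(present),
        graph=sub,
        missing_seeds=missing,
    )


def subnetworks_from_clusters(
    net: nx.Graph,
    clustering,
    sector_assignment: dict,
) -> list[Subnetwork]:
    """One subnetwork per sector-peaking cluster with >= 1 seed in the net.

    Clusters whose centroid reaches the sector threshold in no condition, or
    whose proteins are all absent from the interactome, are skipped with a
    logged reason; per-cluster failures never abort the batch. Output order
    is stable by cluster label.
    """
    subnetworks: list[Subnetwork] = []
    for label in sorted(sector_assignment):
        if not sector_assignment[label]:
            logger.info("cluster %s: no condition at threshold, skipped", label)
            continue
        seeds = clustering.assignments.index[
            clustering.assignments == label
        ].tolist()
        try:
            subnetworks.append(extract_subnetwork(net, seeds, label=label))
        except ValueError as exc:
            logger.warning("cluster %s skipped: %s", label, exc)
    return subnetworks
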