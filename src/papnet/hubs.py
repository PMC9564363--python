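"""Maximal Clique Centrality (MCC) hub-gene ranking.

For a node v of a simple undirected graph, with S(v) the collection of
maximal cliques containing v,

    MCC(v) = sum over C in S(v) of (|C| - 1)!

When a node's neighbours share no edges, every incident edge is its own
maximal 2-clique and MCC reduces to the node degree; in a complete graph K_n
every node scores (n-1)!. Scores are exact integers (factorials overflow
fixed-width arithmetic quickly), and the top-ranked nodes per subnetwork are
reported as candidate hub genes together with whether they are mutually
connected (forming a triangle when k = 3).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import factorial

import networkx as nx


def _fingerprint(graph: nx.Graph) -> str:
    payload = ";".join(
        sorted(f"{min(u, v)}-{max(u, v)}" for u, v in graph.edges)
    ) + "|" + ";".join(sorted(map(str, graph.nodes)))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CliqueSet:
    """All maximal cliques of a graph, in a deterministic order."""

    cliques: tuple[frozenset[str], ...]
    fingerprint: str
    isolated: tuple[str, ...]  # nodes in no clique (degree 0)


def maximal_cliques(graph: nx.Graph) -> CliqueSet:
    """Enumerate maximal cliques (Bron-Kerbosch with pivoting).

    Cliques are ordered by size descending, then by their sorted member
    list; isolated nodes belong to no clique and are reported separately.
    """
    cliques = sorted(
        (frozenset(c) for c in nx.find_cliques(graph) if len(c) >= 2),
        key=lambda c: (-len(c), sorted(c)),
    )
    isolated = tuple(sorted(n for n in graph.nodes if graph.degree(n) == 0))
    return CliqueSet(
        cliques=tuple(cliques),
        fingerprint=_fingerprint(graph),
        isolated=isolated,
    )


def mcc_scores(
    graph: nx.Graph, cliques: CliqueSet | None = None
) -> dict[str, int]:
    """Exact-integer MCC for every node (0 for isolated nodes)."""
    if cliques is None:
        cliques = maximal_cliques(graph)
    elif cliques.fingerprint != _fingerprint(graph):
        raise ValueError("clique set was enumerated for a different graph")
    scores: dict[str, int] = {n: 0 for n in graph.nodes}
    for clique in cliques.cliques:
        weight = factorial(len(clique) - 1)
        for node in clique:
            scores[node] += weight
    return scores


@dataclass(frozen=True)
class HubRanking:
    scores: dict[str, int]
    top: tuple[str, ...]  # ordered by (MCC desc, degree desc, node ID asc)
    hub_clique: bool  # do the top-k induce a complete subgraph?
    tied_at_cutoff: tuple[str, ...]  # nodes sharing the k-th node's score
    short_list: bool  # fewer than k rankable nodes were available


def top_hubs(graph: nx.Graph, k: int = 3) -> HubRanking:
    """Rank nodes by MCC and return the top-k candidate hubs.

    Ties are broken by degree (descending) then node ID (ascending) for a
    deterministic ranking; isolated nodes never enter the list. If fewer
    than k non-isolated nodes exist, all of them are returned and the
    ranking is flagged short.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    scores = mcc_scores(graph)
    rankable = [n for n in graph.nodes if graph.degree(n) > 0]
    ordered = sorted(
        rankable, key=lambda n: (-scores[n], -graph.degree(n), str(n))
    )
    top = tuple(ordered[:k])
    short = len(ordered) < k
    hub_clique = bool(top) and all(
        graph.has_edge(a, b) for a, b in combinations(top, 2)
    )
    tied = ()
    if top and not short:
        cutoff_score = scores[top[-1]]
        tied = tuple(n for n in ordered if scores[n] == cutoff_score)
    return HubRanking(
        scores=scores,
        top=top,
        hub_clique=hub_clique,
        tied_at_cutoff=tied,
        short_list=short,
    )
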