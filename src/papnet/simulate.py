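"""Synthetic study generator with planted, recoverable structure.

Emulates the three inputs of the bent-root network pipeline so every
downstream stage has a ground-truth test surface without external downloads:

* a 66 x 6 abundance table whose normalized profiles are cluster centroids
  plus i.i.d. Gaussian log2 noise (defaults: the published six-cluster
  centroid matrix and sizes 12/4/11/3/16/20);
* a STRING-style PPI network: an Erdős–Rényi background scored below the
  confidence threshold plus, per cluster, maximal cliques scored above it
  that pairwise overlap only at one designated hub protein — so the hub's
  MCC is known in closed form as sum over its cliques of (size-1)!;
* a three-namespace GO DAG and annotation corpus in which one leaf term per
  (subnetwork, namespace) is over-represented among the subnetwork's genes.

A single integer seed drives three deterministically derived sub-streams
(abundance, graph, annotations), so regenerating one component never shifts
another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import datasets
from .io import AnnotationSet, GODag, OboTerm
from .network import MIN_COMBINED_SCORE, extract_subnetwork, filter_high_confidence
from .profiles import CONDITIONS

_BASE_DENSITY = 1000.0  # per-protein mean spot density of generated tables


def _default_centroids() -> tuple[tuple[float, ...], ...]:
    return tuple(
        tuple(row) for row in datasets.published_centroids().to_numpy()
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the published study design: 66 proteins in six
    clusters of sizes 12/4/11/3/16/20 around the published centroid matrix,
    with 0.2 log2 units of profile noise (the minimum pairwise centroid
    distance is ~2.3, so separation/noise stays >= 10 and planted clusters
    are recoverable); three planted cliques of five proteins per hub against
    a sparse sub-threshold background; and a 40-term-per-namespace GO DAG
    with a 0.9-vs-0.05 planted annotation contrast.
    """

    n_proteins: int = 66
    n_clusters: int = 6
    cluster_sizes: tuple[int, ...] = (12, 4, 11, 3, 16, 20)
    centroid_matrix: tuple[tuple[float, ...], ...] = field(
        default_factory=_default_centroids
    )
    noise_sd: float = 0.2
    n_background_nodes: int = 40
    background_edge_prob: float = 0.05
    planted_clique_sizes: tuple[tuple[int, ...], ...] = ((5, 5, 5),) * 6
    score_high_range: tuple[int, int] = (700, 1000)
    score_low_range: tuple[int, int] = (150, 699)
    confidence_threshold: int = MIN_COMBINED_SCORE
    n_terms_per_namespace: int = 40
    dag_depth: int = 4
    baseline_annotation_prob: float = 0.05
    enriched_annotation_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if sum(self.cluster_sizes) != self.n_proteins:
            raise ValueError("cluster_sizes must sum to n_proteins")
        if len(self.centroid_matrix) != self.n_clusters:
            raise ValueError("centroid_matrix needs one row per cluster")
        if any(len(row) != len(CONDITIONS) for row in self.centroid_matrix):
            raise ValueError(
                f"centroid rows must have {len(CONDITIONS)} conditions"
            )
        for p in (
            self.background_edge_prob,
            self.baseline_annotation_prob,
            self.enriched_annotation_prob,
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.enriched_annotation_prob <= self.baseline_annotation_prob:
            raise ValueError(
                "enriched_annotation_prob must exceed baseline_annotation_prob"
            )
        for lo, hi in (self.score_low_range, self.score_high_range):
            if not (0 <= lo <= hi <= 1000):
                raise ValueError(f"score range out of [0,1000]: {(lo, hi)}")
        if self.score_high_range[0] < self.confidence_threshold:
            raise ValueError("high score range must lie above the threshold")
        if self.score_low_range[1] >= self.confidence_threshold:
            raise ValueError("low score range must lie below the threshold")
        if len(self.planted_clique_sizes) != self.n_clusters:
            raise ValueError("planted_clique_sizes needs one tuple per cluster")
        if any(s < 2 for sizes in self.planted_clique_sizes for s in sizes):
            raise ValueError("planted clique sizes must be >= 2")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be >= 2")


def _substreams(config: SimulationConfig):
    """Three independent RNGs derived from the single config seed."""
    ab, gr, an = np.random.SeedSequence(config.seed).spawn(3)
    return (
        np.random.default_rng(ab),
        np.random.default_rng(gr),
        np.random.default_rng(an),
    )


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def generate_abundance_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series]:
    """Abundance table plus ground-truth cluster labels.

    Profiles are drawn in normalized log2 space (centroid + noise) and
    back-transformed around a per-protein base level of 1000 density units,
    rescaled so the per-protein mean is exactly the base level; abundances
    are therefore strictly positive and the log2(x/mean) normalization
    recovers the drawn profile up to its own row-centering constant.
    """
    rng, _, _ = _substreams(config)
    centroids = np.asarray(config.centroid_matrix, dtype=float)
    labels = np.repeat(np.arange(config.n_clusters), config.cluster_sizes)
    ids = [f"P{i + 1:03d}" for i in range(config.n_proteins)]

    rows = []
    for label in labels:
        for _ in range(10):  # bounded resampling against numeric blowups
            z = centroids[label] + rng.normal(0.0, config.noise_sd, len(CONDITIONS))
            lin = np.exp2(z)
            x = _BASE_DENSITY * lin / lin.mean()
            if np.isfinite(x).all() and (x > 0).all():
                rows.append(x)
                break
        else:
            raise ValueError(
                "could not generate positive abundances; centroid/noise "
                "combination out of numeric range"
            )
    table = pd.DataFrame(rows, index=ids, columns=list(CONDITIONS))
    return table, pd.Series(labels, index=ids, name="cluster")


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def generate_ppi_network(
    config: SimulationConfig,
    seed_assignments: dict[int | str, list[str]],
) -> tuple[nx.Graph, dict]:
    """Erdős–Rényi background plus planted cliques through per-cluster hubs.

    ``seed_assignments`` maps each cluster label to its (ordered) protein
    IDs; the first protein of each cluster is the designated hub. Cluster
    proteins beyond the planted cliques' capacity are attached to the hub by
    a single high-score edge. Background pairs (and background-to-planted
    pairs) appear with ``background_edge_prob`` at sub-threshold scores.

    Returns the graph and a ground-truth dict with hub identities, planted
    clique memberships, the planted (high-confidence) edge count and each
    hub's closed-form expected MCC.
    """
    _, rng, _ = _substreams(config)
    lo_l, hi_l = config.score_low_range
    lo_h, hi_h = config.score_high_range

    g = nx.Graph()
    labels = sorted(seed_assignments, key=str)
    if len(labels) != config.n_clusters:
        raise ValueError(
            f"expected {config.n_clusters} seed groups, got {len(labels)}"
        )
    all_seeds: list[str] = [s for lab in labels for s in seed_assignments[lab]]
    if len(set(all_seeds)) != len(all_seeds):
        raise ValueError("duplicate node identifiers in seed assignments")

    def high() -> int:
        return int(rng.integers(lo_h, hi_h + 1))

    def low() -> int:
        return int(rng.integers(lo_l, hi_l + 1))

    hubs: dict[str, str] = {}
    cliques: dict[str, list[list[str]]] = {}
    expected_mcc: dict[str, int] = {}
    planted_edges = 0
    for idx, label in enumerate(labels):
        seeds = list(seed_assignments[label])
        if not seeds:
            raise ValueError(f"cluster {label!r} has no seeds")
        hub, pool = seeds[0], seeds[1:]
        hubs[str(label)] = hub
        sizes = config.planted_clique_sizes[idx]
        members_used: set[str] = set()
        cluster_cliques = []
        filler = 0
        mcc = 0
        for q, size in enumerate(sizes):
            members = [hub]
            while len(members) < size:
                if pool:
                    members.append(pool.pop(0))
                else:
                    filler += 1
                    name = f"N{label}F{filler:03d}"
                    if name in set(all_seeds):
                        raise ValueError(f"duplicate node identifier {name!r}")
                    members.append(name)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if g.has_edge(a, b) or a in members_used and b in members_used:
                        raise ValueError("planted cliques may overlap only at hub")
                    g.add_edge(a, b, combined_score=high())
                    planted_edges += 1
            members_used.update(m for m in members if m != hub)
            cluster_cliques.append(sorted(members))
            mcc += math.factorial(size - 1)
        # leftover cluster proteins hang off the hub as 2-cliques
        for s in pool:
            g.add_edge(hub, s, combined_score=high())
            planted_edges += 1
            mcc += 1
        cliques[str(label)] = cluster_cliques
        expected_mcc[str(label)] = mcc

    background = [f"B{i:03d}" for i in range(config.n_background_nodes)]
    if set(background) & set(g.nodes):
        raise ValueError("duplicate node identifiers in background")
    planted_nodes = sorted(g.nodes)
    g.add_nodes_from(background)
    p = config.background_edge_prob
    if p > 0:
        for i, a in enumerate(background):
            for b in background[i + 1:]:
                if rng.random() < p:
                    g.add_edge(a, b, combined_score=low())
            for b in planted_nodes:
                if rng.random() < p:
                    g.add_edge(a, b, combined_score=low())

    truth = {
        "hubs": hubs,
        "cliques": cliques,
        "planted_edge_count": planted_edges,
        "expected_hub_mcc": expected_mcc,
    }
    return g, truth


# ---------------------------------------------------------------------------
# GO resources
# ---------------------------------------------------------------------------

def generate_go_resources(
    config: SimulationConfig,
    subnetwork_gene_sets: dict[int | str, frozenset[str] | set[str]],
    universe: frozenset[str] | set[str] | None = None,
) -> tuple[GODag, AnnotationSet, dict[str, dict[str, str]]]:
    """Three-namespace is_a DAG plus an annotation corpus with planted signal.

    Each namespace gets one root and ``n_terms_per_namespace - 1`` further
    terms arranged in ``dag_depth`` levels; every term has one parent in the
    level above and, with probability 0.3, a second (producing diamonds).
    Genes are annotated to leaf terms at ``baseline_annotation_prob`` except
    for one designated leaf per (subnetwork, namespace), annotated among that
    subnetwork's genes at ``enriched_annotation_prob``.

    Returns the DAG, the direct annotations and the planted term map
    ``{subnetwork label: {namespace: term}}``.
    """
    from .io import GO_NAMESPACES

    _, _, rng = _substreams(config)
    labels = sorted(subnetwork_gene_sets, key=str)
    gene_sets = {str(k): frozenset(subnetwork_gene_sets[k]) for k in labels}
    genes = sorted(
        frozenset(universe)
        if universe is not None
        else frozenset().union(*gene_sets.values())
    )
    missing = frozenset().union(*gene_sets.values()) - set(genes)
    if missing:
        raise ValueError(f"subnetwork genes outside the universe: {sorted(missing)}")

    counter = 0
    terms: list[OboTerm] = []
    ns_leaves: dict[str, list[str]] = {}
    for namespace in GO_NAMESPACES:
        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"GO:{counter:07d}"

        root = next_id()
        terms.append(OboTerm(root, f"synthetic {namespace} root", namespace))
        n_rest = config.n_terms_per_namespace - 1
        n_levels = config.dag_depth - 1
        per_level = [
            n_rest // n_levels + (1 if lvl < n_rest % n_levels else 0)
            for lvl in range(n_levels)
        ]
        levels: list[list[str]] = [[root]]
        has_child: set[str] = set()
        for lvl, n_here in enumerate(per_level, start=1):
            level_ids = []
            for _ in range(n_here):
                tid = next_id()
                prev = levels[lvl - 1]
                parents = {prev[rng.integers(len(prev))]}
                if len(prev) > 1 and rng.random() < 0.3:
                    parents.add(prev[rng.integers(len(prev))])
                terms.append(
                    OboTerm(
                        tid,
                        f"synthetic {namespace} term {tid[3:]}",
                        namespace,
                        parents=tuple(sorted(parents)),
                    )
                )
                has_child.update(parents)
                level_ids.append(tid)
            levels.append(level_ids)
        ns_leaves[namespace] = sorted(
            t.id
            for t in terms
            if t.namespace == namespace and t.id not in has_child and t.parents
        )

    dag = GODag(terms)

    planted: dict[str, dict[str, str]] = {str(lab): {} for lab in labels}
    pairs: set[tuple[str, str]] = set()
    for namespace in GO_NAMESPACES:
        leaves = list(ns_leaves[namespace])
        if len(leaves) < len(labels):
            raise ValueError(
                f"namespace {namespace}: {len(leaves)} leaves cannot host "
                f"{len(labels)} planted terms"
            )
        chosen = rng.choice(len(leaves), size=len(labels), replace=False)
        planted_for = {leaves[j]: str(lab) for j, lab in zip(chosen, labels)}
        for gene in genes:
            for leaf in leaves:
                owner = planted_for.get(leaf)
                prob = (
                    config.enriched_annotation_prob
                    if owner is not None and gene in gene_sets[owner]
                    else config.baseline_annotation_prob
                )
                if rng.random() < prob:
                    pairs.add((gene, leaf))
        for leaf, owner in planted_for.items():
            planted[owner][namespace] = leaf

    return dag, AnnotationSet(direct=frozenset(pairs)), planted


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedStudy:
    config: SimulationConfig
    abundance: pd.DataFrame
    labels: pd.Series  # ground-truth cluster of each protein
    ppi: nx.Graph
    ppi_truth: dict
    dag: GODag
    annotations: AnnotationSet
    planted_terms: dict[str, dict[str, str]]


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate all three pipeline inputs with consistent ground truth.

    The GO corpus is planted on the true subnetworks (each cluster's seeds
    plus first neighbours in the confidence-filtered planted network), with
    the full node set as the annotation universe.
    """
    config = config or SimulationConfig()
    abundance, labels = generate_abundance_table(config)
    seed_assignments = {
        int(c): labels.index[labels == c].tolist()
        for c in range(config.n_clusters)
    }
    ppi, truth = generate_ppi_network(config, seed_assignments)
    filtered = filter_high_confidence(ppi, config.confidence_threshold)
    gene_sets = {
        label: extract_subnetwork(filtered, seeds, label=label).nodes
        for label, seeds in seed_assignments.items()
    }
    dag, annotations, planted = generate_go_resources(
        config, gene_sets, universe=frozenset(ppi.nodes)
    )
    return SimulatedStudy(
        config=config,
        abundance=abundance,
        labels=labels,
        ppi=ppi,
        ppi_truth=truth,
        dag=dag,
        annotations=annotations,
        planted_terms=planted,
    )
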