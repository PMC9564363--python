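"""Readers and writers for the pipeline's external formats.

Formats: abundance CSV (proteins x six conditions), STRING-style edge TSV
(``protein1  protein2  combined_score`` on the integer 0-1000 scale), OBO 1.2
ontologies (``is_a`` relationships only), flat annotation TSV
(``gene  term  namespace``) and JSON for ground truth / manifests.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .profiles import CONDITIONS

logger = logging.getLogger(__name__)

GO_NAMESPACES: tuple[str, ...] = (
    "biological_process",
    "molecular_function",
    "cellular_component",
)

_GO_ID = re.compile(r"^GO:\d{7}$")
SCORE_MIN, SCORE_MAX = 0, 1000


# ---------------------------------------------------------------------------
# ontology containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OboTerm:
    """One non-obsolete ontology term with its direct ``is_a`` parents."""

    id: str
    name: str
    namespace: str
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not _GO_ID.match(self.id):
            raise ValueError(f"malformed GO identifier: {self.id!r}")
        if self.namespace not in GO_NAMESPACES:
            raise ValueError(
                f"term {self.id}: unknown namespace {self.namespace!r}"
            )


class GODag:
    """A Gene Ontology DAG over ``is_a`` edges, one root per namespace.

    Validates acyclicity, resolvable parents, parent/child namespace
    agreement, and that every namespace present has exactly one root.
    """

    def __init__(self, terms: list[OboTerm] | tuple[OboTerm, ...]):
        self.terms: dict[str, OboTerm] = {}
        for t in terms:
            if t.id in self.terms:
                raise ValueError(f"duplicate term {t.id}")
            self.terms[t.id] = t

        for t in self.terms.values():
            for p in t.parents:
                parent = self.terms.get(p)
                if parent is None:
                    raise ValueError(f"term {t.id}: unknown parent {p}")
                if parent.namespace != t.namespace:
                    raise ValueError(
                        f"term {t.id}: is_a parent {p} crosses namespaces"
                    )

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (t.id, p) for t in self.terms.values() for p in t.parents
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"is_a cycle detected: {cycle}")
        self._graph = g

        self.roots: dict[str, str] = {}
        for t in self.terms.values():
            if not t.parents:
                if t.namespace in self.roots:
                    raise ValueError(
                        f"namespace {t.namespace} has multiple roots: "
                        f"{self.roots[t.namespace]}, {t.id}"
                    )
                self.roots[t.namespace] = t.id
        namespaces = {t.namespace for t in self.terms.values()}
        missing = namespaces - set(self.roots)
        if missing:
            raise ValueError(f"namespaces without a root: {sorted(missing)}")

        self._ancestors = lru_cache(maxsize=None)(self._ancestors_uncached)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def _ancestors_uncached(self, term_id: str) -> frozenset[str]:
        out: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.terms[p].parents)
        return frozenset(out)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a ancestors of a term, excluding the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        return self._ancestors(term_id)

    def children(self, term_id: str) -> frozenset[str]:
        return frozenset(self._graph.predecessors(term_id))

    def leaves(self, namespace: str | None = None) -> frozenset[str]:
        """Terms with no children (optionally restricted to one namespace)."""
        out = {
            t for t in self.terms
            if self._graph.in_degree(t) == 0
            and (namespace is None or self.terms[t].namespace == namespace)
        }
        return frozenset(out)


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> GO term assignments, before/after ancestor propagation.

    ``direct`` holds the pairs as annotated; ``propagated`` additionally
    contains every implied (gene, ancestor) pair under the true-path rule,
    or is ``None`` until :func:`papnet.enrichment.propagate_annotations`
    has been applied.
    """

    direct: frozenset[tuple[str, str]]
    propagated: frozenset[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.propagated is not None and not self.direct <= self.propagated:
            raise ValueError("direct annotations must be a subset of propagated")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.direct)


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a proteins x six-conditions abundance CSV.

    The header must name all six conditions; columns are returned in the
    canonical order. Values must be strictly positive numbers (the log2
    normalization is undefined otherwise).
    """
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in CONDITIONS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing condition column(s) {missing}")
    df = df[list(CONDITIONS)]
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate protein ID {dup!r}")
    for protein, row in df.iterrows():
        for cond, value in row.items():
            v = pd.to_numeric(value, errors="coerce")
            if pd.isna(v) or v <= 0:
                raise ValueError(
                    f"{path}: invalid abundance for protein {protein!r}, "
                    f"condition {cond!r}: {value!r}"
                )
    return df.astype(float)


def write_abundance(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="protein")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

def read_ppi_tsv(path: str | Path) -> nx.Graph:
    """Read a STRING-style edge TSV into an undirected simple graph.

    Duplicate undirected pairs collapse to the maximum score (conservative
    toward the downstream high-confidence filter); self-loops are dropped
    with a warning. Edge scores live in the ``combined_score`` attribute.
    """
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["protein1", "protein2", "combined_score"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            a, b, raw = parts
            try:
                score = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer score {raw!r}"
                ) from None
            if not SCORE_MIN <= score <= SCORE_MAX:
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            if g.has_edge(a, b):
                g[a][b]["combined_score"] = max(g[a][b]["combined_score"], score)
            else:
                g.add_edge(a, b, combined_score=score)
    return g


def write_ppi_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, score in sorted(
            (tuple(sorted((u, v))) + (d["combined_score"],))
            for u, v, d in graph.edges(data=True)
        ):
            fh.write(f"{a}\t{b}\t{score}\n")


# ---------------------------------------------------------------------------
# OBO ontologies and annotations
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> GODag:
    """Parse an OBO 1.2 file into a validated :class:`GODag`.

    Obsolete terms are excluded. Only ``is_a`` is honoured; ``relationship:``
    lines (``part_of`` etc.) are ignored and counted in a log message.
    Unknown parents, cycles and missing namespaces are errors.
    """
    graph = obonet.read_obo(path)  # skips obsolete terms by default
    terms = []
    n_other_relations = 0
    for node, data in graph.nodes(data=True):
        if "name" not in data or "namespace" not in data:
            # obonet materialises dangling is_a targets as bare nodes
            referrers = sorted(graph.predecessors(node))
            raise ValueError(
                f"{path}: term {node} is referenced by {referrers} but has "
                "no [Term] stanza or lacks a namespace"
            )
        n_other_relations += len(data.get("relationship", []))
        terms.append(
            OboTerm(
                id=node,
                name=data["name"],
                namespace=data["namespace"],
                parents=tuple(sorted(data.get("is_a", []))),
            )
        )
    if n_other_relations:
        logger.info(
            "%s: ignored %d non-is_a relationship line(s)", path, n_other_relations
        )
    return GODag(terms)


def write_obo(dag: GODag, path: str | Path) -> None:
    """Write a minimal OBO 1.2 rendering of the DAG (is_a only)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: papnet-synthetic\n")
        for tid in sorted(dag.terms):
            t = dag.terms[tid]
            fh.write(f"\n[Term]\nid: {t.id}\nname: {t.name}\n")
            fh.write(f"namespace: {t.namespace}\n")
            for p in t.parents:
                fh.write(f"is_a: {p} ! {dag.terms[p].name}\n")


def read_annotations(path: str | Path, dag: GODag) -> AnnotationSet:
    """Read a ``gene<TAB>term<TAB>namespace`` TSV against a loaded DAG.

    Pairs referencing terms absent from the DAG are dropped (logged with a
    count); duplicates collapse to one pair.
    """
    pairs: set[tuple[str, str]] = set()
    dropped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene", "term"]:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            gene, term = parts[0], parts[1]
            if term not in dag:
                dropped += 1
                continue
            pairs.add((gene, term))
    if dropped:
        logger.warning("%s: dropped %d annotation(s) to unknown terms", path, dropped)
    annotations = AnnotationSet(direct=frozenset(pairs))
    # counter rides along without participating in equality of the frozen type
    object.__setattr__(annotations, "dropped_unknown_terms", dropped)
    return annotations


def write_annotations(annotations: AnnotationSet, dag: GODag, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\tnamespace\n")
        for gene, term in sorted(annotations.direct):
            fh.write(f"{gene}\t{term}\t{dag.namespace(term)}\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for ground truth and manifests."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
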