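"""GO over-representation analysis with Bonferroni family-wise control.

Annotations are first closed over ``is_a`` ancestors (true-path rule). For a
study set of n genes drawn from a background universe of N annotated genes,
a term annotating K background genes and k study genes gets the
hypergeometric upper-tail probability

    p_raw = sum_{i=k..min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

Each (subnetwork, namespace) pair is one test family: with m tested terms
(those with k >= 1), p_adj = min(1, m * p_raw) and a term is significant when
p_adj < alpha (0.05 by default).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace

from scipy.stats import hypergeom

from .io import AnnotationSet, GODag

DEFAULT_ALPHA: float = 0.05


def propagate_annotations(dag: GODag, annotations: AnnotationSet) -> AnnotationSet:
    """Close direct annotations over is_a ancestors (true-path rule)."""
    for _, term in annotations.direct:
        if term not in dag:
            raise ValueError(f"annotation term {term} absent from DAG")
    propagated = set(annotations.direct)
    for gene, term in annotations.direct:
        propagated.update((gene, anc) for anc in dag.ancestors(term))
    return AnnotationSet(direct=annotations.direct, propagated=frozenset(propagated))


def genes_by_term(
    annotations: AnnotationSet, dag: GODag, namespace: str
) -> dict[str, frozenset[str]]:
    """Propagated term -> gene-set map restricted to one namespace."""
    if annotations.propagated is None:
        raise ValueError("annotations must be propagated first")
    acc: dict[str, set[str]] = defaultdict(set)
    for gene, term in annotations.propagated:
        if dag.namespace(term) == namespace:
            acc[term].add(gene)
    return {t: frozenset(gs) for t, gs in acc.items()}


def annotated_universe(
    annotations: AnnotationSet, dag: GODag, namespace: str
) -> frozenset[str]:
    """Genes with >= 1 propagated annotation in the namespace."""
    if annotations.propagated is None:
        raise ValueError("annotations must be propagated first")
    return frozenset(
        g for g, t in annotations.propagated if dag.namespace(t) == namespace
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    namespace: str
    study_count: int  # k
    study_size: int  # n
    background_count: int  # K
    background_size: int  # N
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_raw <= 1:
            raise ValueError(f"{self.term}: p_raw out of (0, 1]: {self.p_raw}")
        if self.study_count > min(self.study_size, self.background_count):
            raise ValueError(f"{self.term}: impossible counts")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study,
    annotations: AnnotationSet,
    dag: GODag,
    namespace: str,
    universe=None,
) -> list[EnrichmentResult]:
    """Test every term represented in the study set (k >= 1).

    The background universe defaults to all genes carrying at least one
    propagated annotation in the namespace; pass ``universe`` to widen it
    (e.g. to the full network node set). Namespace roots are excluded (they
    always annotate the whole universe). Results are sorted by raw p then
    term ID.
    """
    study = frozenset(study)
    if not study:
        raise ValueError("empty study set")
    if universe is None:
        universe = annotated_universe(annotations, dag, namespace)
    else:
        universe = frozenset(universe)
    outside = study - universe
    if outside:
        raise ValueError(f"study genes outside the universe: {sorted(outside)}")

    term_genes = genes_by_term(annotations, dag, namespace)
    root = dag.roots.get(namespace)
    N, n = len(universe), len(study)
    results = []
    for term, genes in term_genes.items():
        if term == root:
            continue
        genes = genes & universe
        k = len(genes & study)
        if k < 1:
            continue
        K = len(genes)
        results.append(
            EnrichmentResult(
                term=term,
                namespace=namespace,
                study_count=k,
                study_size=n,
                background_count=K,
                background_size=N,
                p_raw=hypergeom_upper_tail(k, N, K, n),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def adjust_bonferroni(
    results: list[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Bonferroni-adjust one (subnetwork, namespace) family.

    m is the number of tested terms in the family (terms with k >= 1), so
    the correction is reproducible from the result list alone.
    """
    m = len(results)
    return [
        replace(
            r,
            p_adj=(p_adj := min(1.0, m * r.p_raw)),
            significant=p_adj < alpha,
        )
        for r in results
    ]
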