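"""Semantic redundancy reduction of significant GO terms (REVIGO-style).

Term specificity is measured by information content, IC(t) = -ln p(t), where
p(t) is the fraction of the namespace's annotated genes carrying the term
after ancestor propagation (the namespace root has p = 1, IC = 0). Pairwise
relatedness uses Lin similarity,

    sim(t1, t2) = 2 IC(MICA) / (IC(t1) + IC(t2)),

with MICA the common is_a ancestor (terms included as their own ancestors
here) of maximal IC. Reduction is greedy: while any remaining pair is more
similar than the cutoff (0.5 by default, a stringent grouping), the
less-significant member of the most similar pair is merged into the other.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .enrichment import EnrichmentResult, genes_by_term
from .io import AnnotationSet, GODag

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF: float = 0.5


@dataclass(frozen=True)
class TermIC:
    term: str
    p: float  # propagated annotation frequency in (0, 1]
    ic: float  # -ln p, nats

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"{self.term}: frequency out of (0, 1]: {self.p}")


def information_content(dag: GODag, annotations: AnnotationSet) -> dict[str, TermIC]:
    """Per-term IC over the artifact's own propagated annotation corpus.

    Terms with zero propagated annotations are excluded (IC undefined there)
    with a warning.
    """
    ic: dict[str, TermIC] = {}
    for namespace in dag.roots:
        term_genes = genes_by_term(annotations, dag, namespace)
        total = len(
            {g for genes in term_genes.values() for g in genes}
        )
        if total == 0:
            continue
        for term in dag.terms:
            if dag.namespace(term) != namespace:
                continue
            count = len(term_genes.get(term, ()))
            if count == 0:
                logger.warning("term %s has no propagated annotations; skipped", term)
                continue
            p = count / total
            ic[term] = TermIC(term=term, p=p, ic=-math.log(p))
    return ic


def lin_similarity(
    t1: str, t2: str, dag: GODag, ic: dict[str, TermIC]
) -> float:
    """Lin similarity in [0, 1]; 0 when both terms are maximally general."""
    if dag.namespace(t1) != dag.namespace(t2):
        raise ValueError(
            f"cross-namespace pair: {t1} ({dag.namespace(t1)}) vs "
            f"{t2} ({dag.namespace(t2)})"
        )
    # common subsumers: each term counts as its own ancestor
    common = (dag.ancestors(t1) | {t1}) & (dag.ancestors(t2) | {t2})
    common = {t for t in common if t in ic}
    if not common:
        return 0.0
    mica_ic = max(ic[t].ic for t in common)
    denom = ic[t1].ic + ic[t2].ic
    if denom == 0:
        return 0.0
    return 2 * mica_ic / denom


@dataclass(frozen=True)
class ReducedTermSet:
    """Surviving representatives and the merge map of discarded terms."""

    representatives: tuple[str, ...]
    merged: dict[str, str]  # discarded term -> final representative
    cutoff: float

    def __post_init__(self) -> None:
        overlap = set(self.representatives) & set(self.merged)
        if overlap:
            raise ValueError(f"terms both kept and merged: {sorted(overlap)}")


def reduce_terms(
    results: list[EnrichmentResult],
    dag: GODag,
    ic: dict[str, TermIC],
    cutoff: float = DEFAULT_CUTOFF,
) -> ReducedTermSet:
    """Greedy redundancy reduction of one namespace's significant terms.

    Repeatedly take the most similar remaining pair with similarity > cutoff
    (ties: lexicographically smallest pair) and discard the member with the
    larger adjusted p (ties: larger annotation frequency, then
    lexicographically larger term ID), recording it as merged into the
    survivor. Terms lacking an IC entry are kept unconditionally (their
    similarity is undefined). Fully deterministic.
    """
    namespaces = {r.namespace for r in results}
    if len(namespaces) > 1:
        raise ValueError(f"results span multiple namespaces: {sorted(namespaces)}")
    p_adj = {r.term: (r.p_adj if r.p_adj is not None else r.p_raw) for r in results}
    alive = sorted(p_adj)

    sims: dict[tuple[str, str], float] = {}
    for i, a in enumerate(alive):
        for b in alive[i + 1:]:
            if a in ic and b in ic:
                sims[(a, b)] = lin_similarity(a, b, dag, ic)

    merged: dict[str, str] = {}
    alive_set = set(alive)
    while True:
        best: tuple[str, str] | None = None
        best_sim = cutoff
        for pair in sorted(sims):
            a, b = pair
            if a in alive_set and b in alive_set and sims[pair] > best_sim:
                best_sim = sims[pair]
                best = pair
        if best is None:
            break
        a, b = best

        def _discard_key(t: str):
            return (p_adj[t], ic[t].p if t in ic else 0.0, t)

        loser = max(a, b, key=_discard_key)
        winner = a if loser == b else b
        merged[loser] = winner
        alive_set.discard(loser)

    # resolve chains so every discarded term maps to a surviving representative
    def _resolve(t: str) -> str:
        while t in merged:
            t = merged[t]
        return t

    merged = {t: _resolve(rep) for t, rep in merged.items()}
    return ReducedTermSet(
        representatives=tuple(sorted(alive_set)),
        merged=merged,
        cutoff=cutoff,
    )
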