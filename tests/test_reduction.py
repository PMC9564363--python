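import math

import numpy as np
import pytest

from papnet import (
    GODag,
    OboTerm,
    information_content,
    lin_similarity,
    propagate_annotations,
    reduce_terms,
)
from papnet.enrichment import EnrichmentResult
from papnet.io import AnnotationSet


def _result(term, p_adj, ns="biological_process"):
    return EnrichmentResult(
        term=term, namespace=ns, study_count=1, study_size=5,
        background_count=2, background_size=20, p_raw=min(p_adj, 1.0),
        p_adj=p_adj, significant=True,
    )


class TestInformationContent:
    def test_chain_frequencies_and_ic(self, chain_dag):
        dag, ann = chain_dag
        ic = information_content(dag, propagate_annotations(dag, ann))
        assert ic["GO:0000001"].p == 1.0 and ic["GO:0000001"].ic == 0.0
        assert ic["GO:0000002"].p == 0.5
        assert ic["GO:0000002"].ic == pytest.approx(math.log(2))
        assert ic["GO:0000003"].p == 0.25

    def test_unannotated_term_excluded_with_warning(self, caplog):
        dag = GODag(
            [
                OboTerm("GO:0000001", "root", "biological_process"),
                OboTerm("GO:0000002", "t", "biological_process", ("GO:0000001",)),
            ]
        )
        ann = propagate_annotations(
            dag, AnnotationSet(direct=frozenset({("g", "GO:0000001")}))
        )
        with caplog.at_level("WARNING"):
            ic = information_content(dag, ann)
        assert "GO:0000002" not in ic
        assert any("no propagated annotations" in r.message for r in caplog.records)

    def test_counting_oracle_on_synthetic_corpus(self, study, propagated):
        ic = information_content(study.dag, propagated)
        for namespace in study.dag.roots:
            genes_in_ns = {
                g for g, t in propagated.propagated
                if study.dag.namespace(t) == namespace
            }
            for term, entry in ic.items():
                if study.dag.namespace(term) != namespace:
                    continue
                count = sum(
                    1 for g in genes_in_ns if (g, term) in propagated.propagated
                )
                assert entry.p == pytest.approx(count / len(genes_in_ns))
                assert entry.ic == pytest.approx(-math.log(entry.p))


class TestLinSimilarity:
    def test_self_similarity_is_one(self, chain_dag):
        dag, ann = chain_dag
        ic = information_content(dag, propagate_annotations(dag, ann))
        assert lin_similarity("GO:0000002", "GO:0000002", dag, ic) == 1.0

    def test_chain_value_two_thirds(self, chain_dag):
        # p = (1, 1/2, 1/4): sim(a, b) = 2 ln2 / (ln2 + ln4) = 2/3
        dag, ann = chain_dag
        ic = information_content(dag, propagate_annotations(dag, ann))
        assert lin_similarity("GO:0000002", "GO:0000003", dag, ic) == pytest.approx(2 / 3)

    def test_disjoint_branches_share_only_zero_ic_root(self):
        dag = GODag(
            [
                OboTerm("GO:0000001", "root", "biological_process"),
                OboTerm("GO:0000002", "a", "biological_process", ("GO:0000001",)),
                OboTerm("GO:0000003", "b", "biological_process", ("GO:0000001",)),
            ]
        )
        direct = frozenset({("g1", "GO:0000002"), ("g2", "GO:0000003")})
        ic = information_content(
            dag, propagate_annotations(dag, AnnotationSet(direct=direct))
        )
        assert lin_similarity("GO:0000002", "GO:0000003", dag, ic) == 0.0

    def test_cross_namespace_pair_rejected(self, study, propagated):
        ic = information_content(study.dag, propagated)
        bp = study.dag.roots["biological_process"]
        mf = study.dag.roots["molecular_function"]
        with pytest.raises(ValueError, match="cross-namespace"):
            lin_similarity(bp, mf, study.dag, ic)


class TestReduce:
    def test_dissimilar_terms_all_survive(self):
        dag = GODag(
            [
                OboTerm("GO:0000001", "root", "biological_process"),
                OboTerm("GO:0000002", "a", "biological_process", ("GO:0000001",)),
                OboTerm("GO:0000003", "b", "biological_process", ("GO:0000001",)),
            ]
        )
        direct = frozenset({("g1", "GO:0000002"), ("g2", "GO:0000003")})
        ic = information_content(
            dag, propagate_annotations(dag, AnnotationSet(direct=direct))
        )
        reduced = reduce_terms(
            [_result("GO:0000002", 0.01), _result("GO:0000003", 0.02)], dag, ic
        )
        assert reduced.representatives == ("GO:0000002", "GO:0000003")
        assert reduced.merged == {}

    def test_near_identical_terms_merge_toward_smaller_p(self, chain_dag):
        dag, ann = chain_dag
        ic = information_content(dag, propagate_annotations(dag, ann))
        # sim(a, b) = 2/3 > 0.5: the 0.01 term merges into the 0.001 term
        reduced = reduce_terms(
            [_result("GO:0000002", 0.001), _result("GO:0000003", 0.01)], dag, ic
        )
        assert reduced.representatives == ("GO:0000002",)
        assert reduced.merged == {"GO:0000003": "GO:0000002"}

    def test_mixed_namespaces_rejected(self):
        results = [
            _result("GO:0000002", 0.01),
            _result("GO:0000003", 0.01, ns="molecular_function"),
        ]
        with pytest.raises(ValueError, match="namespaces"):
            reduce_terms(results, None, {})

    def test_survivor_pairs_stay_at_or_below_cutoff(self, study, propagated):
        ic = information_content(study.dag, propagated)
        rng = np.random.default_rng(0)
        for namespace in study.dag.roots:
            terms = sorted(t for t in ic if study.dag.namespace(t) == namespace)
            results = [
                _result(t, float(rng.uniform(0.0001, 0.04)), ns=namespace)
                for t in terms
            ]
            reduced = reduce_terms(results, study.dag, ic, cutoff=0.5)
            reps = reduced.representatives
            for i, a in enumerate(reps):
                for b in reps[i + 1:]:
                    assert lin_similarity(a, b, study.dag, ic) <= 0.5

    def test_greedy_order_matches_rule_replay_oracle(self, study, propagated):
        ic = information_content(study.dag, propagated)
        rng = np.random.default_rng(1)
        namespace = "biological_process"
        terms = sorted(t for t in ic if study.dag.namespace(t) == namespace)
        p_adj = {t: float(rng.uniform(0.0001, 0.04)) for t in terms}
        results = [_result(t, p_adj[t], ns=namespace) for t in terms]
        reduced = reduce_terms(results, study.dag, ic, cutoff=0.5)

        # independent replay of the stated rules
        alive = set(terms)
        merged = {}
        while True:
            candidates = []
            for a in sorted(alive):
                for b in sorted(alive):
                    if a < b:
                        s = lin_similarity(a, b, study.dag, ic)
                        if s > 0.5:
                            candidates.append((s, a, b))
            if not candidates:
                break
            # most similar pair; ties by lexicographically smallest pair
            best_s = max(c[0] for c in candidates)
            tied = sorted((a2, b2) for s2, a2, b2 in candidates if s2 == best_s)
            a, b = tied[0]
            loser = max(a, b, key=lambda t: (p_adj[t], ic[t].p, t))
            winner = a if loser == b else b
            merged[loser] = winner
            alive.remove(loser)
        assert set(reduced.representatives) == alive
        resolved = {}
        for t, rep in merged.items():
            while rep in merged:
                rep = merged[rep]
            resolved[t] = rep
        assert reduced.merged == resolved

    def test_deterministic(self, study, propagated):
        ic = information_content(study.dag, propagated)
        terms = sorted(
            t for t in ic if study.dag.namespace(t) == "molecular_function"
        )[:15]
        results = [
            _result(t, 0.01, ns="molecular_function") for t in terms
        ]
        r1 = reduce_terms(results, study.dag, ic)
        r2 = reduce_terms(list(reversed(results)), study.dag, ic)
        assert r1.representatives == r2.representatives
        assert r1.merged == r2.merged
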