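"""End-to-end orchestration: simulate/read -> cluster -> subnetworks ->
enrichment -> reduction -> overlap partition -> hub ranking.

Every stage writes its artifacts under the run's output directory and the
run ends with a manifest (config echo, seed, per-stage entity counts, sha256
checksums of every written file). Identical config + seed reproduce
byte-identical artifacts, hence identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as pio
from .enrichment import (
    adjust_bonferroni,
    annotated_universe,
    enrich,
    propagate_annotations,
)
from .hubs import maximal_cliques, top_hubs
from .network import filter_high_confidence, subnetworks_from_clusters
from .overlaps import intersection_cells, partition_terms, summarize_partition
from .profiles import assign_sectors, kmeans_cluster, normalize_abundance
from .reduction import information_content, reduce_terms
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run.

    Either a simulation block or the four input paths must be given. The
    defaults are the study's printed parameters: k = 6 clusters, sector
    threshold 0.3 (log2 units), STRING combined score >= 700, Bonferroni
    alpha 0.05, semantic-reduction cutoff 0.5, top 3 hub genes.
    """

    outdir: str = "papnet_run"
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    abundance_path: str | None = None
    ppi_path: str | None = None
    obo_path: str | None = None
    annotations_path: str | None = None
    k: int = 6
    sector_threshold: float = 0.3
    min_score: int = 700
    alpha: float = 0.05
    reduction_cutoff: float = 0.5
    top_k: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 1000:
            raise ValueError("min_score must be in [0, 1000]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.reduction_cutoff <= 1:
            raise ValueError("reduction cutoff must be in (0, 1]")
        if self.k < 1 or self.top_k < 1:
            raise ValueError("k and top_k must be positive")
        paths = (
            self.abundance_path,
            self.ppi_path,
            self.obo_path,
            self.annotations_path,
        )
        if self.simulation is None and any(p is None for p in paths):
            raise ValueError(
                "either a simulation block or all four input paths required"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_clusters_tsv(profiles, clustering, path: Path) -> None:
    out = profiles.copy()
    out.insert(0, "cluster", clustering.assignments)
    out.to_csv(path, sep="\t", index_label="protein")


def _write_enrichment_tsv(results, path: Path) -> None:
    rows = [
        {
            "term": r.term,
            "namespace": r.namespace,
            "study_count": r.study_count,
            "study_size": r.study_size,
            "background_count": r.background_count,
            "background_size": r.background_size,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "term", "namespace", "study_count", "study_size",
            "background_count", "background_size", "p_raw", "p_adj",
            "significant",
        ],
    ).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict[str, object] = {}

    def _mark(path: Path) -> Path:
        written.append(path)
        return path

    stage = "inputs"
    try:
        inputs_dir = outdir / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            study = simulate_study(sim)
            abundance, ppi = study.abundance, study.ppi
            dag, annotations = study.dag, study.annotations
            pio.write_abundance(abundance, _mark(inputs_dir / "abundance.csv"))
            pio.write_ppi_tsv(ppi, _mark(inputs_dir / "ppi.tsv"))
            pio.write_obo(dag, _mark(inputs_dir / "ontology.obo"))
            pio.write_annotations(
                annotations, dag, _mark(inputs_dir / "annotations.tsv")
            )
            pio.write_json(
                {
                    "labels": study.labels.to_dict(),
                    "ppi": study.ppi_truth,
                    "planted_terms": study.planted_terms,
                },
                _mark(inputs_dir / "ground_truth.json"),
            )
        else:
            abundance = pio.read_abundance(config.abundance_path)
            ppi = pio.read_ppi_tsv(config.ppi_path)
            dag = pio.read_obo(config.obo_path)
            annotations = pio.read_annotations(config.annotations_path, dag)
        counts["proteins"] = len(abundance)
        counts["ppi_nodes"] = ppi.number_of_nodes()
        counts["ppi_edges"] = ppi.number_of_edges()
        counts["ontology_terms"] = len(dag)
        counts["direct_annotations"] = len(annotations.direct)

        stage = "cluster"
        profiles = normalize_abundance(abundance)
        clustering = kmeans_cluster(profiles, k=config.k, seed=config.seed)
        sectors = assign_sectors(clustering, threshold=config.sector_threshold)
        assert int(clustering.sizes.sum()) == len(abundance), (
            "cluster sizes must conserve the protein count"
        )
        _write_clusters_tsv(profiles, clustering, _mark(outdir / "clusters.tsv"))
        clustering.centroids.to_csv(
            _mark(outdir / "centroids.tsv"), sep="\t", index_label="cluster"
        )
        pio.write_json(
            {str(k): list(v) for k, v in sectors.items()},
            _mark(outdir / "sectors.json"),
        )
        counts["clusters"] = clustering.k
        counts["cluster_sizes"] = [int(s) for s in clustering.sizes]
        counts["sector_peaking_clusters"] = sum(bool(v) for v in sectors.values())

        stage = "subnetworks"
        filtered = filter_high_confidence(ppi, config.min_score)
        subnets = subnetworks_from_clusters(filtered, clustering, sectors)
        sub_dir = outdir / "subnetworks"
        sub_dir.mkdir(exist_ok=True)
        sub_manifest = {}
        for sn in subnets:
            pio.write_ppi_tsv(sn.graph, _mark(sub_dir / f"subnetwork_{sn.label}.tsv"))
            sub_manifest[str(sn.label)] = {
                "seeds": sorted(sn.seeds),
                "missing_seeds": list(sn.missing_seeds),
                "n_nodes": len(sn.nodes),
                "n_edges": sn.n_edges,
            }
        pio.write_json(sub_manifest, _mark(sub_dir / "manifest.json"))
        counts["high_confidence_edges"] = filtered.number_of_edges()
        counts["subnetworks"] = len(subnets)
        logger.info("%d cluster-related subnetworks were obtained", len(subnets))

        stage = "enrichment"
        annotations = propagate_annotations(dag, annotations)
        enr_dir = outdir / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        by_subnet_ns: dict[tuple[str, str], list] = {}
        n_significant = 0
        for sn in subnets:
            for namespace in sorted(dag.roots):
                universe = annotated_universe(annotations, dag, namespace)
                study = sn.nodes & universe
                if not study:
                    logger.info(
                        "subnetwork %s / %s: no annotated study gene, skipped",
                        sn.label, namespace,
                    )
                    continue
                results = adjust_bonferroni(
                    enrich(study, annotations, dag, namespace),
                    alpha=config.alpha,
                )
                by_subnet_ns[(str(sn.label), namespace)] = results
                n_significant += sum(r.significant for r in results)
                _write_enrichment_tsv(
                    results,
                    _mark(enr_dir / f"subnetwork_{sn.label}_{namespace}.tsv"),
                )
        counts["tested_families"] = len(by_subnet_ns)
        counts["significant_terms"] = n_significant

        stage = "reduction"
        ic = information_content(dag, annotations)
        red_dir = outdir / "reduction"
        red_dir.mkdir(exist_ok=True)
        reduced_sets: dict[str, dict[str, frozenset[str]]] = {}
        for (label, namespace), results in by_subnet_ns.items():
            significant = [r for r in results if r.significant]
            if not significant:
                continue
            reduced = reduce_terms(
                significant, dag, ic, cutoff=config.reduction_cutoff
            )
            reduced_sets.setdefault(namespace, {})[label] = frozenset(
                reduced.representatives
            )
            p_adj = {r.term: r.p_adj for r in significant}
            rows = [
                {
                    "term": t,
                    "representative": reduced.merged.get(t, t),
                    "kept": t in reduced.representatives,
                    "p_adj": p_adj[t],
                    "ic": ic[t].ic if t in ic else float("nan"),
                }
                for t in sorted(p_adj)
            ]
            pd.DataFrame(
                rows, columns=["term", "representative", "kept", "p_adj", "ic"]
            ).to_csv(
                _mark(red_dir / f"subnetwork_{label}_{namespace}.tsv"),
                sep="\t",
                index=False,
            )
        counts["reduced_term_sets"] = {
            ns: {lab: len(s) for lab, s in sorted(d.items())}
            for ns, d in sorted(reduced_sets.items())
        }

        stage = "partition"
        part_dir = outdir / "partition"
        part_dir.mkdir(exist_ok=True)
        partition_summary = {}
        for namespace, named_sets in sorted(reduced_sets.items()):
            if len(named_sets) < 2:
                logger.info(
                    "namespace %s: fewer than two subnetwork term sets, "
                    "partition skipped", namespace,
                )
                continue
            part = partition_terms(named_sets)
            summary = summarize_partition(part)
            partition_summary[namespace] = summary
            pio.write_json(
                {
                    "summary": summary,
                    "shared": sorted(part.shared),
                    "specific": {
                        lab: sorted(s) for lab, s in sorted(part.specific.items())
                    },
                    "cells": intersection_cells(named_sets),
                },
                _mark(part_dir / f"partition_{namespace}.json"),
            )
        counts["partition"] = partition_summary

        stage = "hubs"
        hub_dir = outdir / "hubs"
        hub_dir.mkdir(exist_ok=True)
        hub_summary = {}
        for sn in subnets:
            ranking = top_hubs(sn.graph, k=config.top_k)
            cliques = maximal_cliques(sn.graph)
            rows = sorted(
                (
                    {
                        "node": n,
                        "mcc": ranking.scores[n],
                        "degree": sn.graph.degree(n),
                    }
                    for n in sn.graph.nodes
                ),
                key=lambda r: (-r["mcc"], -r["degree"], str(r["node"])),
            )
            for rank, row in enumerate(rows, start=1):
                row["rank"] = rank
            pd.DataFrame(
                rows, columns=["node", "mcc", "degree", "rank"]
            ).to_csv(
                _mark(hub_dir / f"subnetwork_{sn.label}.tsv"), sep="\t", index=False
            )
            hub_summary[str(sn.label)] = {
                "top": list(ranking.top),
                "hub_clique": ranking.hub_clique,
                "n_maximal_cliques": len(cliques.cliques),
            }
        pio.write_json(hub_summary, _mark(hub_dir / "summary.json"))
        counts["hubs"] = hub_summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": _config_echo(config),
        "seed": config.seed,
        "counts": counts,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(written)
        },
    }
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    if config.simulation is not None:
        echo["simulation"] = dataclasses.asdict(config.simulation)
    return echo
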