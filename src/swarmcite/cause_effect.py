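"""The two-round cause-effect analysis.

Round 1 clusters the swarm axis of the probe x swarm co-citation matrix
(UPGMA on cosine), cuts at the CCSV threshold, and keeps the clusters
that contain at least one swarm holding a *seed* protein (a receptor of
interest).  The union of proteins across the kept clusters' swarms is
the seed-receptor *interactome*.

Round 2 restricts counting to the interactome's swarms, re-clusters, and
cuts the probe axis at the disease-group threshold, yielding groups of
probes with similar cause-effect profiles plus the doubly-ordered matrix
(heatmap source).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clustering import (
    Dendrogram,
    SwarmCluster,
    cut_at_ccsv,
    similarity_matrix,
    upgma,
    write_newick,
)
from .cocitation import CocitationMatrix, HitRule, count_matrix
from .config import PipelineConfig, emit_manifest
from .datamodel import Corpus, PPINetwork, TissueProteome, Table1Fixture, normalize_symbol
from .errors import ConfigurationError
from .swarms import SwarmCollection, build_swarms, swarms_containing, write_swarms
from .synthetic import SyntheticTruth, generate_study

logger = logging.getLogger(__name__)


@dataclass
class Interactome:
    """Union of proteins in seed-containing swarm clusters."""

    seed_proteins: set[str]
    clusters: list[SwarmCluster] = field(default_factory=list)
    proteins: set[str] = field(default_factory=set)

    @property
    def swarm_ids(self) -> set[int]:
        ids: set[int] = set()
        for c in self.clusters:
            ids |= set(c.member_ids)
        return ids

    def __bool__(self) -> bool:
        return bool(self.clusters)


def select_seed_clusters(
    clusters: list[SwarmCluster],
    swarms: SwarmCollection,
    seeds: set[str],
    threshold: float,
) -> Interactome:
    """Keep clusters with CCSV above ``threshold`` that contain at least
    one swarm intersecting ``seeds``; aggregate the member proteins."""
    seeds = {normalize_symbol(s) for s in seeds}
    seed_swarms = swarms_containing(swarms, seeds)
    kept = [
        c
        for c in clusters
        if c.ccsv > threshold and set(c.member_ids) & seed_swarms
    ]
    proteins: set[str] = set()
    for c in kept:
        for sid in c.member_ids:
            proteins |= swarms.by_id(sid).members
    if not kept:
        logger.warning("no swarm cluster qualifies at CCSV > %.3g with the given seeds", threshold)
    return Interactome(seed_proteins=seeds, clusters=kept, proteins=proteins)


def aggregate_interactome(source: Table1Fixture | list[SwarmCluster] | Interactome,
                          swarms: SwarmCollection | None = None) -> set[str]:
    """Normalized union of proteins across cluster columns / member swarms."""
    if isinstance(source, Table1Fixture):
        out: set[str] = set()
        for label in source.cluster_labels:
            out.update(normalize_symbol(p) for p in source.columns[label])
        return out
    if isinstance(source, Interactome):
        return set(source.proteins)
    out = set()
    for cluster in source:
        if swarms is None:
            raise ConfigurationError("aggregating swarm clusters requires the swarm collection")
        for sid in cluster.member_ids:
            out |= swarms.by_id(sid).members
    return out


@dataclass
class DiseaseGrouping:
    """Probe groups from the second-round cut, plus the ordered matrix."""

    groups: list[SwarmCluster]
    ordered_matrix: pd.DataFrame
    probe_tree: Dendrogram
    swarm_tree: Dendrogram
    swarm_clusters: list[SwarmCluster]
    dropped_probes: list[str] = field(default_factory=list)

    def labels_for(self, probes: list[str]) -> list[int]:
        """Group index per probe (grouped probes only; -1 if dropped)."""
        assignment = {}
        for g, cluster in enumerate(self.groups):
            for p in cluster.member_ids:
                assignment[p] = g
        return [assignment.get(p, -1) for p in probes]


def second_round(
    corpus: Corpus,
    probes: list[str],
    interactome: Interactome,
    swarms: SwarmCollection,
    disease_threshold: float = 0.76,
    swarm_axis_threshold: float = 0.69,
    rule: HitRule = HitRule(),
) -> DiseaseGrouping:
    """Re-count against the interactome's swarms and group the probes."""
    if not interactome:
        raise ConfigurationError("interactome is empty; nothing to re-cluster")
    selected = swarms.subset(interactome.swarm_ids)
    counts = count_matrix(corpus, probes, selected, rule)
    probe_sim = similarity_matrix(counts, axis="rows")
    probe_tree = upgma(probe_sim)
    groups = cut_at_ccsv(probe_tree, disease_threshold)
    swarm_sim = similarity_matrix(counts, axis="columns")
    swarm_tree = upgma(swarm_sim)
    swarm_clusters = cut_at_ccsv(swarm_tree, swarm_axis_threshold)
    row_order = [probe_tree.leaves[i] for i in probe_tree.leaf_order]
    col_order = [swarm_tree.leaves[i] for i in swarm_tree.leaf_order]
    ordered = counts.counts.loc[row_order, col_order]
    return DiseaseGrouping(
        groups=groups,
        ordered_matrix=ordered,
        probe_tree=probe_tree,
        swarm_tree=swarm_tree,
        swarm_clusters=swarm_clusters,
        dropped_probes=list(probe_sim.dropped),
    )


# ------------------------------------------------------------- full pipeline


@dataclass
class PipelineResult:
    """All artifacts of one end-to-end run."""

    config: PipelineConfig
    seed: int
    network: PPINetwork
    proteomes: list[TissueProteome]
    corpus: Corpus
    truth: SyntheticTruth | None
    swarms: SwarmCollection
    counts: CocitationMatrix
    swarm_tree: Dendrogram
    round1_clusters: list[SwarmCluster]
    interactome: Interactome
    grouping: DiseaseGrouping
    manifest: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> PipelineResult:
    """Execute simulate/ingest -> swarms -> co-citation -> round-1 cluster
    and seed selection -> round-2 disease grouping, writing every stage
    artifact plus a checksum manifest under ``config.output_dir``."""
    from . import io as sio

    seed = config.seeds[0] if seed is None else seed
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_files: dict[str, dict[str, Path]] = {}

    def _stage(name):
        stage_files[name] = {}
        return stage_files[name]

    # ---- inputs -----------------------------------------------------------
    files = _stage("inputs")
    truth = None
    if config.simulate is not None:
        study = generate_study(seed=seed, **config.simulate)
        network, proteomes, corpus, truth = (
            study.network,
            study.proteomes,
            study.corpus,
            study.truth,
        )
        files["ppi"] = out / "ppi.tsv"
        sio.write_ppi_edgelist(network, files["ppi"])
        files["proteomes"] = out / "proteomes.tsv"
        sio.write_proteomes(proteomes, files["proteomes"])
        files["corpus"] = out / "corpus.jsonl"
        sio.write_corpus(corpus, files["corpus"])
        files["truth"] = out / "truth.yaml"
        _write_truth(truth, files["truth"])
    else:
        network = sio.read_ppi_edgelist(config.inputs["ppi"])
        proteomes = sio.read_proteomes(config.inputs["proteomes"])
        probes_reg = (
            sio.read_probes(config.inputs["probes"]) if "probes" in config.inputs else None
        )
        corpus = sio.read_corpus(config.inputs["corpus"], probes=probes_reg)

    probes = sorted(corpus.probe_registry)
    rule = HitRule(mode=config.hit_rule["mode"], k=config.hit_rule["k"])

    if config.seed_proteins == "pathway-receptors":
        if truth is None:
            raise ConfigurationError(
                "seed_proteins: 'pathway-receptors' requires a simulate block"
            )
        seeds_set = truth.pathway_receptors()
    else:
        seeds_set = {normalize_symbol(s) for s in config.seed_proteins}

    # ---- swarms -----------------------------------------------------------
    files = _stage("swarms")
    collection = build_swarms(proteomes, network, max_size=config.max_swarm_size)
    files["swarms"] = out / "swarms.tsv"
    write_swarms(collection, files["swarms"])
    logger.info("swarm collection: %d swarms", len(collection))

    # ---- co-citation ------------------------------------------------------
    files = _stage("cocitation")
    counts = count_matrix(corpus, probes, collection, rule)
    files["counts"] = out / "counts.tsv"
    sio.write_matrix(counts.counts, files["counts"])

    # ---- round 1: swarm-axis clustering and seed selection ----------------
    files = _stage("round1")
    swarm_sim = similarity_matrix(counts, axis="columns")
    swarm_tree = upgma(swarm_sim)
    round1_clusters = cut_at_ccsv(swarm_tree, config.ccsv_threshold_round1)
    interactome = select_seed_clusters(
        round1_clusters, collection, seeds_set, config.ccsv_threshold_round1
    )
    files["round1_newick"] = out / "round1_swarms.newick"
    write_newick(swarm_tree, files["round1_newick"])
    files["round1_clusters"] = out / "round1_clusters.tsv"
    _write_clusters(round1_clusters, files["round1_clusters"])
    files["interactome"] = out / "interactome.txt"
    with open(files["interactome"], "w", encoding="utf-8") as fh:
        for p in sorted(interactome.proteins):
            fh.write(p + "\n")
    logger.info(
        "round 1: %d clusters, %d selected, interactome of %d proteins",
        len(round1_clusters),
        len(interactome.clusters),
        len(interactome.proteins),
    )

    # ---- round 2: disease grouping ---------------------------------------
    files = _stage("round2")
    grouping = second_round(
        corpus,
        probes,
        interactome,
        collection,
        disease_threshold=config.disease_threshold,
        swarm_axis_threshold=config.swarm_axis_threshold,
        rule=rule,
    )
    files["groups"] = out / "disease_groups.tsv"
    _write_clusters(grouping.groups, files["groups"])
    files["ordered_matrix"] = out / "round2_ordered_matrix.tsv"
    sio.write_matrix(grouping.ordered_matrix, files["ordered_matrix"])
    files["round2_probe_newick"] = out / "round2_probes.newick"
    write_newick(grouping.probe_tree, files["round2_probe_newick"])
    files["round2_swarm_newick"] = out / "round2_swarms.newick"
    write_newick(grouping.swarm_tree, files["round2_swarm_newick"])
    logger.info("round 2: %d disease groups", len(grouping.groups))

    # ---- manifest ---------------------------------------------------------
    parameters = {
        "simulate": config.simulate,
        "inputs": {k: str(v) for k, v in config.inputs.items()} if config.inputs else None,
        "hit_rule": config.hit_rule,
        "ccsv_threshold_round1": config.ccsv_threshold_round1,
        "swarm_axis_threshold": config.swarm_axis_threshold,
        "disease_threshold": config.disease_threshold,
        "max_swarm_size": config.max_swarm_size,
        "seed_proteins": sorted(seeds_set),
    }
    manifest = emit_manifest(out / "manifest.json", parameters, seed, stage_files)

    return PipelineResult(
        config=config,
        seed=seed,
        network=network,
        proteomes=proteomes,
        corpus=corpus,
        truth=truth,
        swarms=collection,
        counts=counts,
        swarm_tree=swarm_tree,
        round1_clusters=round1_clusters,
        interactome=interactome,
        grouping=grouping,
        manifest=manifest,
        output_dir=out,
    )


def _write_clusters(clusters: list[SwarmCluster], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tccsv\tmembers\n")
        for c in clusters:
            members = ";".join(str(m) for m in sorted(c.member_ids, key=str))
            fh.write(f"{c.label}\t{c.ccsv:.6f}\t{members}\n")


def _write_truth(truth: SyntheticTruth, path: Path) -> None:
    import yaml

    payload = {
        "params": truth.params,
        "pathway_assignment": dict(sorted(truth.pathway_assignment.items())),
        "probe_pathways": {
            p: sorted(ks) for p, ks in sorted(truth.probe_pathways.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
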