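"""Synthetic study generator with planted probe-pathway structure.

The generator emulates the statistical skeleton of literature co-citation
mining over tissue-protein networks: proteins belong to pathways (a
planted partition), the PPI network is dense within pathways and sparse
between them, tissues express random protein subsets, and each document
mentions one probe plus proteins drawn with an elevated rate ``p_assoc``
from the probe's pathway(s) and a background rate ``p_bg`` elsewhere.
Because the pathway assignment and the probe-pathway map are recorded as
ground truth, downstream clustering can be scored against the planted
blocks (adjusted Rand index).

Determinism contract: every operation draws from its own pseudo-random
stream derived from ``(seed, operation name)``, so each stage can be
regenerated independently and identical ``(params, seed)`` always yield
byte-identical serialized outputs.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import Corpus, Document, PPINetwork, Probe, TissueProteome
from .errors import ConfigurationError


def _rng(seed: int, operation: str) -> np.random.Generator:
    """Independent stream per (seed, operation name)."""
    tag = int.from_bytes(hashlib.sha256(operation.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def protein_symbol(i: int) -> str:
    return f"P{i:04d}"


def probe_id(i: int) -> str:
    return f"D{i:03d}"


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study.

    ``pathway_assignment`` maps each protein to exactly one pathway index;
    ``probe_pathways`` maps each probe to the pathway indices whose
    proteins it is preferentially co-mentioned with.
    """

    pathway_assignment: dict[str, int] = field(default_factory=dict)
    probe_pathways: dict[str, set[int]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def pathway_members(self, pathway: int) -> set[str]:
        return {p for p, k in self.pathway_assignment.items() if k == pathway}

    def pathway_receptors(self) -> set[str]:
        """One designated 'receptor' per pathway: its smallest member symbol.

        These play the role seed receptors play in cluster selection — a
        known protein per planted module used to pull in its swarm clusters.
        """
        receptors = {}
        for protein, k in self.pathway_assignment.items():
            if k not in receptors or protein < receptors[k]:
                receptors[k] = protein
        return set(receptors.values())

    def probe_blocks(self) -> dict[str, tuple[int, ...]]:
        """Probe -> hashable block label (its sorted pathway set)."""
        return {p: tuple(sorted(ks)) for p, ks in self.probe_pathways.items()}


def generate_ppi(
    n_proteins: int,
    n_pathways: int,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[PPINetwork, SyntheticTruth]:
    """Planted-partition PPI network.

    Proteins are split round-robin into ``n_pathways`` pathways; each
    within-pathway pair is an edge with probability ``p_in`` and each
    cross-pathway pair with probability ``p_out``.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ConfigurationError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if n_pathways < 1 or n_pathways > n_proteins:
        raise ConfigurationError("need 1 <= n_pathways <= n_proteins")
    rng = _rng(seed, "generate_ppi")
    proteins = [protein_symbol(i) for i in range(n_proteins)]
    assignment = {p: i % n_pathways for i, p in enumerate(proteins)}
    net = PPINetwork()
    for p in proteins:
        net.add_node(p)
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            prob = p_in if assignment[proteins[i]] == assignment[proteins[j]] else p_out
            if prob > 0 and rng.random() < prob:
                net.add_edge(proteins[i], proteins[j])
    truth = SyntheticTruth(
        pathway_assignment=assignment,
        params={
            "n_proteins": n_proteins,
            "n_pathways": n_pathways,
            "p_in": p_in,
            "p_out": p_out,
            "seed": int(seed),
        },
    )
    return net, truth


def generate_tissue_proteomes(
    network: PPINetwork,
    n_tissues: int,
    coverage: float,
    seed: int,
) -> list[TissueProteome]:
    """Each tissue samples ``ceil(coverage * |nodes|)`` proteins without
    replacement, deterministically per seed."""
    if not (0 < coverage <= 1):
        raise ConfigurationError(f"coverage must be in (0, 1], got {coverage}")
    if n_tissues < 1:
        raise ConfigurationError("n_tissues must be >= 1")
    rng = _rng(seed, "generate_tissue_proteomes")
    nodes = sorted(network.nodes)
    size = math.ceil(coverage * len(nodes))
    proteomes = []
    for t in range(n_tissues):
        chosen = rng.choice(len(nodes), size=size, replace=False)
        proteomes.append(
            TissueProteome(
                tissue_id=f"T{t:02d}",
                proteins=frozenset(nodes[i] for i in chosen),
            )
        )
    return proteomes


def assign_probe_pathways(
    truth: SyntheticTruth,
    n_probes: int,
    pathways_per_probe: int = 1,
) -> SyntheticTruth:
    """Assign pathways to probes round-robin (deterministic blocks).

    With one pathway per probe, probes assigned the same pathway form the
    planted blocks a perfect recovery should reproduce.
    """
    n_pathways = truth.params["n_pathways"]
    if not (1 <= pathways_per_probe <= n_pathways):
        raise ConfigurationError("need 1 <= pathways_per_probe <= n_pathways")
    for i in range(n_probes):
        ks = {(i + j) % n_pathways for j in range(pathways_per_probe)} if pathways_per_probe > 1 else {i % n_pathways}
        truth.probe_pathways[probe_id(i)] = ks
    truth.params["n_probes"] = n_probes
    return truth


def generate_corpus(
    truth: SyntheticTruth,
    n_docs: int,
    p_assoc: float,
    p_bg: float,
    seed: int,
) -> Corpus:
    """Documents with planted co-mention structure.

    Each document picks one probe uniformly, mentions it, and mentions
    each protein of the probe's pathway(s) independently with probability
    ``p_assoc`` and every other protein with probability ``p_bg``.
    """
    if n_docs <= 0:
        raise ConfigurationError("n_docs must be positive")
    if not (0 <= p_bg <= p_assoc <= 1) or p_assoc == 0:
        raise ConfigurationError(f"need 0 <= p_bg <= p_assoc <= 1 (p_assoc > 0), got {p_assoc}, {p_bg}")
    if not truth.probe_pathways:
        raise ConfigurationError("truth has no probe-pathway assignment")
    rng = _rng(seed, "generate_corpus")
    proteins = sorted(truth.pathway_assignment)
    pathway_of = np.array([truth.pathway_assignment[p] for p in proteins])
    probe_ids = sorted(truth.probe_pathways)
    registry = {pid: Probe(probe_id=pid, name=pid, probe_class="disease") for pid in probe_ids}
    # per-probe boolean mask of associated proteins
    assoc_mask = np.stack(
        [np.isin(pathway_of, sorted(truth.probe_pathways[pid])) for pid in probe_ids]
    )
    which = rng.integers(0, len(probe_ids), size=n_docs)
    u = rng.random((n_docs, len(proteins)))
    prob = np.where(assoc_mask[which], p_assoc, p_bg)
    mentioned = u < prob
    docs = []
    proteins_arr = np.array(proteins)
    for d in range(n_docs):
        docs.append(
            Document(
                doc_id=f"doc{d:06d}",
                probe_mentions=frozenset({probe_ids[which[d]]}),
                protein_mentions=frozenset(proteins_arr[mentioned[d]].tolist()),
            )
        )
    truth.params.update(
        {"n_docs": int(n_docs), "p_assoc": float(p_assoc), "p_bg": float(p_bg)}
    )
    return Corpus(documents=docs, probe_registry=registry)


@dataclass
class SyntheticStudy:
    """All inputs of one synthetic study plus its ground truth."""

    network: PPINetwork
    proteomes: list[TissueProteome]
    corpus: Corpus
    truth: SyntheticTruth


def generate_study(
    n_proteins: int = 120,
    n_pathways: int = 6,
    n_probes: int = 40,
    n_docs: int = 5000,
    n_tissues: int = 5,
    coverage: float = 0.8,
    p_in: float = 0.5,
    p_out: float = 0.02,
    p_assoc: float = 0.6,
    p_bg: float = 0.02,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a complete desk-scale study (network, proteomes, corpus).

    Defaults are the package's reference study conditions: 40 probes over
    6 pathways of 120 proteins, 5,000 documents, association rate 0.6
    against background 0.02.
    """
    network, truth = generate_ppi(n_proteins, n_pathways, p_in, p_out, seed)
    proteomes = generate_tissue_proteomes(network, n_tissues, coverage, seed)
    truth = assign_probe_pathways(truth, n_probes)
    corpus = generate_corpus(truth, n_docs, p_assoc, p_bg, seed)
    truth.params.update({"n_tissues": n_tissues, "coverage": coverage})
    return SyntheticStudy(network=network, proteomes=proteomes, corpus=corpus, truth=truth)
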