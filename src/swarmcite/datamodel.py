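"""Core domain types.

The pipeline's vocabulary: *probes* (diseases or drugs) are the entities
whose literature profiles are clustered; *tissue proteomes* list the
proteins expressed per tissue; the *PPI network* provides the physical
interaction scaffold from which *protein swarms* (small connected
fragments, built in :mod:`swarmcite.swarms`) are derived; *documents*
carry pre-extracted probe and protein mentions; *function gene sets* are
curated protein sets used in the overlap stage.

Protein symbols are normalized once, on entry: uppercased and stripped of
surrounding whitespace.  Hyphens and other internal punctuation are kept
(mitochondrial symbols such as ``MT-CYB`` are legitimate), but internal
whitespace is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .errors import InputFormatError, UnknownProteinError

logger = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    """Normalize a protein symbol: strip, uppercase, reject whitespace.

    >>> normalize_symbol(" nedd4l ")
    'NEDD4L'
    """
    s = symbol.strip().upper()
    if not s:
        raise InputFormatError("empty protein symbol")
    if any(c.isspace() for c in s):
        raise InputFormatError(f"protein symbol contains whitespace: {symbol!r}")
    return s


@dataclass(frozen=True)
class Probe:
    """A disease or drug whose co-citation profile is analyzed."""

    probe_id: str
    name: str = ""
    probe_class: str = "disease"

    def __post_init__(self):
        if self.probe_class not in ("disease", "drug"):
            raise InputFormatError(
                f"probe_class must be 'disease' or 'drug', got {self.probe_class!r}"
            )


@dataclass(frozen=True)
class TissueProteome:
    """The set of proteins expressed in one tissue."""

    tissue_id: str
    proteins: frozenset[str]

    def __post_init__(self):
        if not self.proteins:
            raise InputFormatError(f"tissue {self.tissue_id!r} has an empty proteome")


class PPINetwork:
    """An undirected protein-protein interaction network.

    Thin wrapper over :class:`networkx.Graph` that enforces symbol
    normalization, symmetric edges, no self-loops, and optional weights
    in [0, 1].  Duplicate edges collapse keeping the maximum weight.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def add_node(self, symbol: str) -> str:
        s = normalize_symbol(symbol)
        self.graph.add_node(s)
        return s

    def add_edge(self, a: str, b: str, weight: float | None = None) -> bool:
        """Add an undirected edge; returns False for a dropped self-loop."""
        a, b = normalize_symbol(a), normalize_symbol(b)
        if weight is not None and not (0.0 <= weight <= 1.0):
            raise InputFormatError(f"edge weight {weight} outside [0, 1]")
        if a == b:
            self.graph.add_node(a)
            logger.warning("dropping self-loop on %s", a)
            return False
        if self.graph.has_edge(a, b):
            old = self.graph.edges[a, b].get("weight")
            if weight is not None and (old is None or weight > old):
                self.graph.edges[a, b]["weight"] = weight
        else:
            if weight is None:
                self.graph.add_edge(a, b)
            else:
                self.graph.add_edge(a, b, weight=weight)
        return True

    def neighbors(self, protein: str) -> set[str]:
        p = normalize_symbol(protein)
        if p not in self.graph:
            raise UnknownProteinError(p)
        return set(self.graph.neighbors(p))

    def __contains__(self, protein: str) -> bool:
        return normalize_symbol(protein) in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass(frozen=True)
class Document:
    """One literature record with pre-extracted mentions."""

    doc_id: str
    probe_mentions: frozenset[str]
    protein_mentions: frozenset[str]


@dataclass
class Corpus:
    """An ordered collection of documents plus the probe registry.

    Every probe id mentioned in a document must exist in the registry.
    """

    documents: list[Document] = field(default_factory=list)
    probe_registry: dict[str, Probe] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for d in self.documents:
            if d.doc_id in seen:
                raise InputFormatError(f"duplicate doc_id {d.doc_id!r}")
            seen.add(d.doc_id)
            unknown = d.probe_mentions - self.probe_registry.keys()
            if unknown:
                raise InputFormatError(
                    f"document {d.doc_id!r} mentions unregistered probes {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.documents)


@dataclass(frozen=True)
class FunctionGeneSet:
    """A named curated set of proteins (one GMT line)."""

    name: str
    proteins: frozenset[str]
    description: str = ""

    def __post_init__(self):
        if not self.proteins:
            raise InputFormatError(f"gene set {self.name!r} is empty")


@dataclass
class Table1Fixture:
    """A machine-readable swarm-cluster table: one protein column per cluster.

    Cluster labels are opaque strings (the printed leaf-range labels are
    typographically inconsistent, so they are never parsed as numbers);
    per-column entries preserve repetitions — deduplication happens only
    at aggregation.
    """

    cluster_labels: list[str]
    columns: dict[str, list[str]]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)
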