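"""Protein swarms: connected network fragments of at most five proteins.

A swarm is the descriptor unit of the whole analysis: a small connected
fragment of the PPI network observed in a tissue proteome.  Counting how
often a probe is co-mentioned with any member of a swarm turns the
literature into a probe x swarm profile matrix.

Fragmenting rule (deterministic, hub-centered): within each connected
component of the tissue-induced subgraph, repeatedly pick the unassigned
node with the highest remaining degree (ties: lexicographically smallest
symbol) and grow a breadth-first fragment from it, adding unassigned
neighbors in lexicographic order, until ``max_size`` members or
exhaustion.  Identical member sets arising in different tissues merge
into one swarm whose ``source_tissues`` accumulate.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .datamodel import PPINetwork, TissueProteome
from .errors import ConfigurationError, InputFormatError

logger = logging.getLogger(__name__)

MAX_SWARM_SIZE = 5


@dataclass
class ProteinSwarm:
    """A connected fragment of 1-5 proteins used as a co-citation descriptor."""

    swarm_id: int
    members: frozenset[str]
    source_tissues: set[str] = field(default_factory=set)


@dataclass
class SwarmCollection:
    """Globally deduplicated, consecutively indexed swarms (ids from 1)."""

    swarms: list[ProteinSwarm] = field(default_factory=list)
    _by_members: dict[frozenset[str], ProteinSwarm] = field(default_factory=dict, repr=False)

    def add(self, members: frozenset[str], tissue: str) -> ProteinSwarm:
        sw = self._by_members.get(members)
        if sw is None:
            sw = ProteinSwarm(swarm_id=len(self.swarms) + 1, members=members)
            self.swarms.append(sw)
            self._by_members[members] = sw
        sw.source_tissues.add(tissue)
        return sw

    def __len__(self) -> int:
        return len(self.swarms)

    def __iter__(self):
        return iter(self.swarms)

    def by_id(self, swarm_id: int) -> ProteinSwarm:
        return self.swarms[swarm_id - 1]

    def subset(self, swarm_ids: set[int]) -> "SwarmCollection":
        """Restriction keeping the original ids (no re-indexing).

        Used by the second analysis round, where the selected swarms keep
        their first-round identities.  The consecutive-id invariant holds
        only for collections built by :func:`build_swarms`.
        """
        sub = SwarmCollection()
        for sw in self.swarms:
            if sw.swarm_id in swarm_ids:
                sub.swarms.append(sw)
                sub._by_members[sw.members] = sw
        return sub

    def protein_index(self) -> dict[str, list[int]]:
        """Inverted index protein -> swarm ids containing it."""
        index: dict[str, list[int]] = {}
        for sw in self.swarms:
            for p in sw.members:
                index.setdefault(p, []).append(sw.swarm_id)
        return index


def _fragment_component(sub: nx.Graph, max_size: int) -> list[frozenset[str]]:
    """Partition one connected component into BFS fragments of <= max_size."""
    unassigned = set(sub.nodes)
    fragments: list[frozenset[str]] = []
    while unassigned:
        remaining = sub.subgraph(unassigned)
        seed = min(remaining.nodes, key=lambda v: (-remaining.degree(v), v))
        frag = {seed}
        queue = deque([seed])
        while queue and len(frag) < max_size:
            v = queue.popleft()
            for w in sorted(remaining.neighbors(v)):
                if w not in frag:
                    frag.add(w)
                    queue.append(w)
                    if len(frag) >= max_size:
                        break
        fragments.append(frozenset(frag))
        unassigned -= frag
    return fragments


def build_swarms(
    proteomes: list[TissueProteome],
    network: PPINetwork,
    max_size: int = MAX_SWARM_SIZE,
) -> SwarmCollection:
    """Build the global swarm collection from tissue proteomes.

    Per tissue: take the network subgraph induced by the proteome,
    fragment each connected component (components visited in order of
    their smallest member symbol), and register each fragment.  Proteome
    proteins absent from the network become singleton swarms with a
    logged warning.  Ids are assigned by first appearance.
    """
    if max_size < 1:
        raise ConfigurationError("max_size must be >= 1")
    collection = SwarmCollection()
    for tp in proteomes:
        present = tp.proteins & network.nodes
        missing = tp.proteins - network.nodes
        sub = network.graph.subgraph(present)
        components = sorted(nx.connected_components(sub), key=min)
        for comp in components:
            for frag in _fragment_component(sub.subgraph(comp), max_size):
                collection.add(frag, tp.tissue_id)
        for p in sorted(missing):
            logger.warning(
                "tissue %s: protein %s absent from network; kept as singleton swarm",
                tp.tissue_id,
                p,
            )
            collection.add(frozenset({p}), tp.tissue_id)
    return collection


def swarms_containing(collection: SwarmCollection, proteins: set[str]) -> set[int]:
    """Ids of swarms whose member set intersects ``proteins``."""
    proteins = set(proteins)
    return {sw.swarm_id for sw in collection if sw.members & proteins}


# ----------------------------------------------------------------------- IO


def write_swarms(collection: SwarmCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("swarm_id\tmembers\tsource_tissues\n")
        for sw in collection:
            fh.write(
                f"{sw.swarm_id}\t{';'.join(sorted(sw.members))}\t"
                f"{';'.join(sorted(sw.source_tissues))}\n"
            )


def read_swarms(path) -> SwarmCollection:
    collection = SwarmCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or (lineno == 1 and line.startswith("swarm_id\t")):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise InputFormatError("expected 3 fields", line=lineno)
            swarm_id = int(fields[0])
            if swarm_id != len(collection.swarms) + 1:
                raise InputFormatError(
                    f"swarm ids must be consecutive from 1, got {swarm_id}", line=lineno
                )
            members = frozenset(fields[1].split(";"))
            sw = ProteinSwarm(swarm_id=swarm_id, members=members)
            sw.source_tissues = set(fields[2].split(";")) if fields[2] else set()
            if members in collection._by_members:
                raise InputFormatError("duplicate swarm member set", line=lineno)
            collection.swarms.append(sw)
            collection._by_members[members] = sw
    return collection
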