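"""Probe x swarm co-citation counting.

A document *hits* a swarm when it mentions at least one member (mode
``any``, the default) or at least ``k`` members (mode ``min_k``).  The
count matrix entry for (probe, swarm) is the number of documents that
mention the probe and hit the swarm — document-level counting, so each
document contributes at most one per pair.  Zero rows and columns are
retained here; the clustering stage drops zero profiles (a zero vector
has no cosine direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Corpus, Document
from .errors import ConfigurationError
from .swarms import MAX_SWARM_SIZE, ProteinSwarm, SwarmCollection


@dataclass(frozen=True)
class HitRule:
    """Criterion for a document hitting a swarm."""

    mode: str = "any"
    k: int = 1

    def __post_init__(self):
        if self.mode not in ("any", "min_k"):
            raise ConfigurationError(f"hit rule mode must be 'any' or 'min_k', got {self.mode!r}")
        if self.k < 1:
            raise ConfigurationError("hit rule k must be >= 1")
        if self.k > MAX_SWARM_SIZE:
            raise ConfigurationError(
                f"hit rule k={self.k} exceeds the maximum swarm size {MAX_SWARM_SIZE}"
            )

    @property
    def min_members(self) -> int:
        return 1 if self.mode == "any" else self.k


@dataclass
class CocitationMatrix:
    """Integer probe x swarm count grid with its provenance."""

    counts: pd.DataFrame  # rows: probe ids, columns: swarm ids (int)
    hit_rule: HitRule = field(default_factory=HitRule)
    n_docs: int = 0

    @property
    def row_labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def col_labels(self) -> list[int]:
        return list(self.counts.columns)

    def restrict_swarms(self, swarm_ids: set[int]) -> "CocitationMatrix":
        """Projection onto a swarm subset; retained counts are unchanged."""
        keep = [c for c in self.counts.columns if c in swarm_ids]
        return CocitationMatrix(
            counts=self.counts[keep].copy(), hit_rule=self.hit_rule, n_docs=self.n_docs
        )


def swarm_hit(document: Document, swarm: ProteinSwarm, rule: HitRule = HitRule()) -> bool:
    """True iff the document mentions enough swarm members under ``rule``."""
    return len(document.protein_mentions & swarm.members) >= rule.min_members


def count_matrix(
    corpus: Corpus,
    probes: list[str],
    swarms: SwarmCollection,
    rule: HitRule = HitRule(),
) -> CocitationMatrix:
    """Count, per (probe, swarm), the documents mentioning the probe for
    which the swarm is hit.  Probes never mentioned keep their zero rows.
    """
    if not probes:
        raise ConfigurationError("probe list is empty")
    if len(swarms) == 0:
        raise ConfigurationError("swarm collection is empty")
    probe_pos = {p: i for i, p in enumerate(probes)}
    swarm_ids = [sw.swarm_id for sw in swarms]
    swarm_pos = {s: j for j, s in enumerate(swarm_ids)}
    index = swarms.protein_index()
    counts = np.zeros((len(probes), len(swarm_ids)), dtype=np.int64)
    need = rule.min_members
    for doc in corpus.documents:
        rows = [probe_pos[p] for p in doc.probe_mentions if p in probe_pos]
        if not rows:
            continue
        if need == 1:
            hit_ids = set()
            for protein in doc.protein_mentions:
                hit_ids.update(index.get(protein, ()))
        else:
            tally: dict[int, int] = {}
            for protein in doc.protein_mentions:
                for s in index.get(protein, ()):
                    tally[s] = tally.get(s, 0) + 1
            hit_ids = {s for s, c in tally.items() if c >= need}
        cols = [swarm_pos[s] for s in hit_ids if s in swarm_pos]
        if cols:
            for r in rows:
                counts[r, cols] += 1
    df = pd.DataFrame(counts, index=pd.Index(probes, name="probe"), columns=swarm_ids)
    return CocitationMatrix(counts=df, hit_rule=rule, n_docs=len(corpus))
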