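"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
- PPI network: TSV edge list ``protein_a  protein_b  [weight]``
- corpus: JSONL, one document per line (``doc_id``, ``probe_mentions``,
  ``protein_mentions``) with an optional leading probe-registry record
- probes: TSV ``probe_id  name  probe_class``
- tissue proteomes: long TSV ``tissue_id  protein``
- gene sets: GMT (``name  description  member...``)
- labeled matrices: TSV with a header row and a label column
- swarm-cluster tables (machine-readable printed tables): TSV with one
  ragged protein column per cluster label
- overlap grids: TSV ``protein`` column plus one mark column per function

All parsers are total on their formats: malformed input raises
:class:`~swarmcite.errors.InputFormatError` naming the offending line.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    Corpus,
    Document,
    FunctionGeneSet,
    PPINetwork,
    Probe,
    Table1Fixture,
    TissueProteome,
    normalize_symbol,
)
from .errors import InputFormatError

logger = logging.getLogger(__name__)


def packaged_data(name: str) -> Path:
    """Path to a fixture packaged with the library (e.g. ``table1.tsv``)."""
    return Path(resources.files("swarmcite").joinpath("data", name))


# ---------------------------------------------------------------- PPI network


def read_ppi_edgelist(path: str | Path) -> PPINetwork:
    """Read a TSV edge list into a :class:`PPINetwork`.

    Duplicate edges collapse (max weight kept); self-loops are dropped with
    a logged warning; a malformed row (wrong column count, weight outside
    [0, 1]) raises :class:`InputFormatError` naming the line.
    """
    net = PPINetwork()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("protein_a", "source", "node_a"):
                continue
            if len(fields) not in (2, 3):
                raise InputFormatError(
                    f"expected 2 or 3 tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            weight = None
            if len(fields) == 3 and fields[2].strip():
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise InputFormatError(
                        f"non-numeric weight {fields[2]!r}", line=lineno
                    ) from exc
            try:
                net.add_edge(fields[0], fields[1], weight=weight)
            except InputFormatError as exc:
                raise InputFormatError(str(exc), line=lineno) from exc
    return net


def write_ppi_edgelist(net: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            w = net.graph.edges[a, b].get("weight")
            fh.write(f"{a}\t{b}\t{'' if w is None else w}\n")
        # isolated nodes survive a round-trip as degenerate rows
        isolated = sorted(n for n in net.nodes if net.graph.degree(n) == 0)
        for n in isolated:
            fh.write(f"{n}\t{n}\t\n")


# -------------------------------------------------------------------- corpus


def read_corpus(path: str | Path, probes: dict[str, Probe] | None = None) -> Corpus:
    """Read a JSONL corpus; symbols normalized, duplicate doc_id rejected.

    If ``probes`` is omitted, the registry is built from the mentioned
    probe ids (opaque registry entries).
    """
    corpus = Corpus(probe_registry=dict(probes) if probes else {})
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise InputFormatError(f"invalid JSON: {exc}", line=lineno) from exc
            for key in ("doc_id", "probe_mentions", "protein_mentions"):
                if key not in rec:
                    raise InputFormatError(f"missing field {key!r}", line=lineno)
            doc_id = str(rec["doc_id"])
            if doc_id in seen:
                raise InputFormatError(f"duplicate doc_id {doc_id!r}", line=lineno)
            seen.add(doc_id)
            try:
                proteins = frozenset(
                    normalize_symbol(s) for s in rec["protein_mentions"]
                )
            except InputFormatError as exc:
                raise InputFormatError(str(exc), line=lineno) from exc
            probe_ids = frozenset(str(p) for p in rec["probe_mentions"])
            corpus.documents.append(
                Document(doc_id=doc_id, probe_mentions=probe_ids, protein_mentions=proteins)
            )
            if probes is None:
                for pid in probe_ids:
                    corpus.probe_registry.setdefault(pid, Probe(probe_id=pid))
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus deterministically (sorted keys, sorted mentions)."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(
                json.dumps(
                    {
                        "doc_id": d.doc_id,
                        "probe_mentions": sorted(d.probe_mentions),
                        "protein_mentions": sorted(d.protein_mentions),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_probes(path: str | Path) -> dict[str, Probe]:
    probes: dict[str, Probe] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "probe_id":
                continue
            if len(fields) != 3:
                raise InputFormatError("expected 3 fields", line=lineno)
            pid, name, cls = fields
            if pid in probes:
                raise InputFormatError(f"duplicate probe_id {pid!r}", line=lineno)
            probes[pid] = Probe(probe_id=pid, name=name, probe_class=cls)
    return probes


def write_probes(probes: dict[str, Probe], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\tname\tprobe_class\n")
        for pid in probes:
            p = probes[pid]
            fh.write(f"{p.probe_id}\t{p.name}\t{p.probe_class}\n")


# ----------------------------------------------------------------- proteomes


def read_proteomes(path: str | Path) -> list[TissueProteome]:
    """Read long-format ``tissue_id  protein`` TSV into proteomes."""
    per_tissue: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "tissue_id":
                continue
            if len(fields) != 2:
                raise InputFormatError("expected 2 fields", line=lineno)
            tid = fields[0]
            if tid not in per_tissue:
                per_tissue[tid] = set()
                order.append(tid)
            try:
                per_tissue[tid].add(normalize_symbol(fields[1]))
            except InputFormatError as exc:
                raise InputFormatError(str(exc), line=lineno) from exc
    return [TissueProteome(tissue_id=t, proteins=frozenset(per_tissue[t])) for t in order]


def write_proteomes(proteomes: list[TissueProteome], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tissue_id\tprotein\n")
        for tp in proteomes:
            for p in sorted(tp.proteins):
                fh.write(f"{tp.tissue_id}\t{p}\n")


# ----------------------------------------------------------------- gene sets


def read_gene_sets(path: str | Path) -> list[FunctionGeneSet]:
    """Read a GMT file: ``name <tab> description <tab> member...``."""
    sets: list[FunctionGeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputFormatError(
                    f"GMT line needs >= 3 fields, got {len(fields)}", line=lineno
                )
            try:
                members = frozenset(normalize_symbol(s) for s in fields[2:] if s.strip())
            except InputFormatError as exc:
                raise InputFormatError(str(exc), line=lineno) from exc
            if not members:
                raise InputFormatError("gene set has no members", line=lineno)
            sets.append(
                FunctionGeneSet(name=fields[0], description=fields[1], proteins=members)
            )
    return sets


# --------------------------------------------------- printed-table fixtures


def read_table1_fixture(path: str | Path) -> Table1Fixture:
    """Read a swarm-cluster table: one (ragged) protein column per cluster.

    Column order is preserved, empty cells skipped, repeated symbols within
    a column kept (deduplication is the aggregation step's job).  Duplicate
    cluster labels are an error.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    if not lines or not lines[0].strip():
        raise InputFormatError("missing header row", line=1)
    labels = [c.strip() for c in lines[0].split("\t")]
    if labels and labels[0].lower() == "cluster":
        labels = labels[1:]
        header_offset = 1
    else:
        header_offset = 0
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise InputFormatError(f"duplicate cluster label(s) {dupes}", line=1)
    columns: dict[str, list[str]] = {lab: [] for lab in labels}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if header_offset and len(cells) == len(labels) + 1:
            cells = cells[1:]
        cells = cells + [""] * (len(labels) - len(cells))
        for lab, cell in zip(labels, cells[: len(labels)]):
            if cell.strip():
                try:
                    columns[lab].append(normalize_symbol(cell))
                except InputFormatError as exc:
                    raise InputFormatError(str(exc), line=lineno) from exc
    empty = [lab for lab in labels if not columns[lab]]
    if empty:
        raise InputFormatError(f"cluster column(s) with no proteins: {empty}")
    return Table1Fixture(cluster_labels=labels, columns=columns)


def read_overlap_fixture(path: str | Path) -> pd.DataFrame:
    """Read a printed overlap grid: ``protein`` column + one mark column per
    function.  Any non-empty cell counts as membership.  Returns a boolean
    DataFrame indexed by protein symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "protein":
        raise InputFormatError("first column must be 'protein'", line=1)
    proteins = [normalize_symbol(p) for p in df["protein"]]
    if len(set(proteins)) != len(proteins):
        raise InputFormatError("duplicate protein rows in overlap grid")
    grid = df.iloc[:, 1:].map(lambda c: bool(str(c).strip()))
    grid.index = pd.Index(proteins, name="protein")
    return grid


# ------------------------------------------------------------------ matrices


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled numeric table as TSV (12 significant digits)."""
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise InputFormatError("matrix labels must be unique")
    matrix.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise InputFormatError("matrix labels must be unique")
    if df.empty and df.columns.empty:
        return df
    # keep integer matrices integral after the round-trip
    values = df.to_numpy()
    if values.size and np.issubdtype(values.dtype, np.floating):
        if np.all(np.isfinite(values)) and np.all(values == np.round(values)):
            as_int = values.astype(np.int64)
            if np.array_equal(as_int.astype(values.dtype), values):
                df = df.astype(np.int64)
    return df
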