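"""Function-network overlap and hypergeometric enrichment.

Given a query protein set (e.g. an interactome or a swarm cluster's
proteins) and curated function gene sets, build the boolean membership
grid, extract core proteins shared by all selected functions, list
direct physical interactors, and test over-representation with the
one-sided (upper-tail) hypergeometric test plus Benjamini-Hochberg
control.

The hypergeometric tail is computed with exact integer arithmetic
(binomial coefficients via :func:`math.comb` accumulated as a rational
number) — at desk scale this is both exact and fast, and it doubles as
a reference the floating implementation in SciPy can be checked against.

The universe defaults to the union of all supplied gene sets and the
query; pass ``universe`` explicitly for a curated background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .datamodel import FunctionGeneSet, PPINetwork, normalize_symbol
from .errors import DegenerateInputError, InputFormatError


@dataclass
class OverlapTable:
    """Boolean protein x function membership grid."""

    membership: pd.DataFrame  # index: proteins (sorted), columns: function names

    @property
    def proteins(self) -> list[str]:
        return list(self.membership.index)

    @property
    def functions(self) -> list[str]:
        return list(self.membership.columns)


@dataclass
class EnrichmentResult:
    """One gene set's upper-tail hypergeometric enrichment."""

    name: str
    k: int  # overlap count
    K: int  # gene-set size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    q_value: float | None = None


def overlap_table(query: set[str], gene_sets: list[FunctionGeneSet]) -> OverlapTable:
    """Membership grid of the query proteins across the gene sets."""
    if not query:
        raise DegenerateInputError("query protein set is empty")
    proteins = sorted(normalize_symbol(p) for p in query)
    data = {
        gs.name: [p in gs.proteins for p in proteins] for gs in gene_sets
    }
    df = pd.DataFrame(data, index=pd.Index(proteins, name="protein"))
    df = df[[gs.name for gs in gene_sets]]
    return OverlapTable(membership=df)


def core_proteins(table: OverlapTable, functions: list[str] | set[str] | None = None) -> set[str]:
    """Proteins belonging to every selected function.

    With an empty selection the result is all proteins (vacuous truth).
    """
    if functions is None:
        functions = table.functions
    functions = list(functions)
    unknown = set(functions) - set(table.functions)
    if unknown:
        raise InputFormatError(f"unknown function(s) {sorted(unknown)}")
    if not functions:
        return set(table.proteins)
    mask = table.membership[functions].all(axis=1)
    return set(table.membership.index[mask])


def direct_interactors(network: PPINetwork, protein: str) -> set[str]:
    """Adjacent nodes of ``protein`` (the protein itself excluded)."""
    return network.neighbors(protein) - {normalize_symbol(protein)}


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P[X >= k], X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return float(Fraction(acc, total))


def hypergeom_enrichment(
    query: set[str],
    gene_set: FunctionGeneSet | set[str],
    universe: set[str],
    name: str | None = None,
) -> EnrichmentResult:
    """Upper-tail enrichment of the query in one gene set.

    ``p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n)`` with
    ``k = |query ∩ set|``, ``K = |set|``, ``n = |query|``, ``N = |universe|``.
    """
    members = gene_set.proteins if isinstance(gene_set, FunctionGeneSet) else frozenset(gene_set)
    if name is None:
        name = gene_set.name if isinstance(gene_set, FunctionGeneSet) else ""
    query = {normalize_symbol(p) for p in query}
    members = {normalize_symbol(p) for p in members}
    universe = {normalize_symbol(p) for p in universe}
    if not members <= universe:
        raise InputFormatError(
            f"gene set {name!r} not contained in universe "
            f"(e.g. {sorted(members - universe)[:3]})"
        )
    if not query <= universe:
        raise InputFormatError(
            f"query not contained in universe (e.g. {sorted(query - universe)[:3]})"
        )
    k = len(query & members)
    K, n, N = len(members), len(query), len(universe)
    return EnrichmentResult(name=name, k=k, K=K, n=n, N=N, p_value=hypergeom_tail(k, K, n, N))


def default_universe(query: set[str], gene_sets: list[FunctionGeneSet]) -> set[str]:
    """Default background: all gene-set members plus the query."""
    universe = {normalize_symbol(p) for p in query}
    for gs in gene_sets:
        universe |= gs.proteins
    return universe


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    m = len(p_values)
    for p in p_values:
        if not (0.0 < p <= 1.0):
            raise InputFormatError(f"p-value {p} outside (0, 1]")
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * (m / rank))
        q[i] = running
    return q


def enrichment_table(
    query: set[str],
    gene_sets: list[FunctionGeneSet],
    universe: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Enrichment of the query across all gene sets, with BH q-values."""
    if universe is None:
        universe = default_universe(query, gene_sets)
    results = [hypergeom_enrichment(query, gs, universe) for gs in gene_sets]
    qs = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, qs):
        r.q_value = qv
    return results
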