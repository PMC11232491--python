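"""Independent brute-force references used to check the implementation.

These deliberately avoid the package's own algorithms: UPGMA recomputes
average dissimilarities from the original matrix at every step, cosine
is a double loop over the definition, counting is a document x probe x
swarm triple loop, and the hypergeometric tail enumerates draws.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_cosine_matrix(data: np.ndarray) -> np.ndarray:
    """All-pairs cosine of the rows of ``data`` by direct evaluation."""
    n = data.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = float(np.dot(data[i], data[j]))
            den = math.sqrt(float(np.dot(data[i], data[i]))) * math.sqrt(
                float(np.dot(data[j], data[j]))
            )
            out[i, j] = num / den
    return out


def naive_upgma_cophenetic(similarity: np.ndarray, labels: list[str]) -> np.ndarray:
    """Cophenetic matrix of UPGMA on d = 1 - s, recomputing every
    inter-cluster average from the original dissimilarities each step.

    Ties break on the lexicographically smallest pair of cluster labels,
    a cluster being labelled by its smallest member label.
    """
    n = len(labels)
    d = 1.0 - similarity
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            avg = float(
                np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            )
            la = min(labels[i] for i in clusters[a])
            lb = min(labels[i] for i in clusters[b])
            key = (avg, tuple(sorted((la, lb))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _), a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = avg
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


def naive_count_matrix(corpus, probes, swarms, min_members=1):
    """Document x probe x swarm triple loop."""
    counts = np.zeros((len(probes), len(swarms.swarms)), dtype=int)
    for doc in corpus.documents:
        for r, probe in enumerate(probes):
            if probe not in doc.probe_mentions:
                continue
            for c, sw in enumerate(swarms.swarms):
                if len(doc.protein_mentions & sw.members) >= min_members:
                    counts[r, c] += 1
    return counts


def enumerate_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by enumerating every n-subset of an N-element universe
    whose first K elements are the 'successes'.  Exponential — tiny N only."""
    universe = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total
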