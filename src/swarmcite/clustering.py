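"""Cosine similarity, UPGMA dendrograms, CCSV cuts, Newick export.

The count matrix is turned into an all-pairs cosine similarity matrix
(over rows or columns), agglomerated by UPGMA (average linkage) on the
dissimilarity ``d = 1 - s``, and cut into flat clusters by a CCSV
threshold.  CCSV — the cluster-quality score on [0, 1] — is defined here
as one minus the UPGMA merge dissimilarity at the cluster's root, i.e.
the average cosine similarity at which the cluster's members were last
joined; singletons score 1.  Cluster labels are 1-based leaf-order
position ranges ("first–last"), mirroring the leaf-range labels used for
swarm clusters.

UPGMA is implemented in-package with an explicit determinism contract:
at each step the minimal average dissimilarity pair merges, exact ties
broken by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest member).  Merge heights are checked
to be non-decreasing on every build.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, UndefinedSimilarityError

HEIGHT_TOL = 1e-10


def cosine_similarity(profile_a, profile_b) -> float:
    """Cosine of two nonnegative profiles, clamped to [0, 1].

    Raises :class:`UndefinedSimilarityError` on a zero vector — callers
    must drop zero profiles first.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine of a zero vector is undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


@dataclass
class SimilarityMatrix:
    """Square symmetric cosine matrix over labelled items."""

    labels: list
    values: np.ndarray
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        assert v.shape == (len(self.labels), len(self.labels))
        assert np.allclose(v, v.T, atol=1e-12)

    def __len__(self) -> int:
        return len(self.labels)


def similarity_matrix(matrix, axis: str = "columns") -> SimilarityMatrix:
    """All-pairs cosine over the rows or columns of a count matrix.

    ``matrix`` is a :class:`~swarmcite.cocitation.CocitationMatrix` or a
    pandas DataFrame.  Zero profiles are dropped and reported via
    ``dropped``; fewer than two nonzero profiles is a degenerate input.
    """
    df = getattr(matrix, "counts", matrix)
    if axis in ("columns", "cols"):
        data = df.to_numpy(dtype=float).T
        labels = list(df.columns)
    elif axis == "rows":
        data = df.to_numpy(dtype=float)
        labels = list(df.index)
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    norms = np.linalg.norm(data, axis=1)
    keep = norms > 0
    dropped = [lab for lab, k in zip(labels, keep) if not k]
    data, labels, norms = data[keep], [l for l, k in zip(labels, keep) if k], norms[keep]
    if len(labels) < 2:
        raise DegenerateInputError(
            f"need >= 2 nonzero profiles, have {len(labels)} (dropped {len(dropped)})"
        )
    unit = data / norms[:, None]
    sims = np.clip(unit @ unit.T, 0.0, 1.0)
    np.fill_diagonal(sims, 1.0)
    sims = (sims + sims.T) / 2.0
    return SimilarityMatrix(labels=labels, values=sims, dropped=dropped)


@dataclass
class Dendrogram:
    """A UPGMA tree in merge order.

    Nodes 0..n-1 are leaves (in ``leaves`` order); internal node ``n + k``
    is created by ``merges[k] = (left, right, height)`` where ``height``
    is the average dissimilarity of the merge.  ``leaf_order`` is the
    left-to-right permutation induced by the tree (children ordered by
    smallest descendant label).
    """

    leaves: list
    merges: list[tuple[int, int, float]]

    def __post_init__(self):
        assert len(self.merges) == len(self.leaves) - 1
        heights = [h for _, _, h in self.merges]
        assert all(
            heights[i + 1] >= heights[i] - HEIGHT_TOL for i in range(len(heights) - 1)
        ), "UPGMA merge heights must be non-decreasing"

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.merges[node - n][2]

    def children(self, node: int) -> tuple[int, int] | None:
        n = self.n_leaves
        return None if node < n else self.merges[node - n][:2]

    def leaf_indices(self, node: int) -> list[int]:
        """Leaves under ``node`` in tree (left-to-right) order."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            ch = self.children(v)
            if ch is None:
                out.append(v)
            else:
                stack.append(ch[1])
                stack.append(ch[0])
        return out

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    @property
    def leaf_order(self) -> list[int]:
        return self.leaf_indices(self.root)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style linkage matrix (for interoperability and plotting)."""
        n = self.n_leaves
        sizes = {}
        Z = np.zeros((n - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            sa = 1 if a < n else sizes[a]
            sb = 1 if b < n else sizes[b]
            sizes[n + k] = sa + sb
            Z[k] = [a, b, h, sa + sb]
        return Z


def upgma(similarity: SimilarityMatrix) -> Dendrogram:
    """Average-linkage agglomeration of ``d = 1 - s``.

    Distances between merged clusters follow the Lance-Williams UPGMA
    update (size-weighted average), so each inter-cluster distance equals
    the mean pairwise dissimilarity between the original items.
    """
    n = len(similarity)
    d = 1.0 - similarity.values.astype(float)
    np.fill_diagonal(d, np.inf)
    labels = [str(lab) for lab in similarity.labels]
    # active cluster bookkeeping: matrix row i <-> node ids / sizes / min labels
    node = list(range(n))
    size = [1] * n
    minlab = labels[:]
    active = list(range(n))
    D = d.copy()
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        sub = D[np.ix_(active, active)]
        best = np.min(sub)
        # exact ties -> lexicographically smallest (label, label) pair
        ii, jj = np.where(sub == best)
        cand = [
            (tuple(sorted((minlab[active[i]], minlab[active[j]]))), active[i], active[j])
            for i, j in zip(ii, jj)
            if i < j
        ]
        _, a, b = min(cand)
        new_node = n + step
        merges.append((node[a], node[b], float(best)))
        # Lance-Williams average-linkage update into row a
        na, nb = size[a], size[b]
        for c in active:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = (na * D[a, c] + nb * D[b, c]) / (na + nb)
        node[a] = new_node
        size[a] = na + nb
        minlab[a] = min(minlab[a], minlab[b])
        active.remove(b)
    # canonical child order: smaller minimum descendant label first
    def min_leaf_label(v: int, tree_min: dict[int, str]) -> str:
        return tree_min[v]
    tree_min: dict[int, str] = {i: labels[i] for i in range(n)}
    ordered: list[tuple[int, int, float]] = []
    for k, (a, b, h) in enumerate(merges):
        if tree_min[b] < tree_min[a]:
            a, b = b, a
        tree_min[n + k] = min(tree_min[a], tree_min[b])
        ordered.append((a, b, h))
    return Dendrogram(leaves=list(similarity.labels), merges=ordered)


@dataclass
class SwarmCluster:
    """A flat cluster from a CCSV cut: contiguous leaf range + score."""

    label: str
    member_ids: set
    ccsv: float
    positions: tuple[int, int]  # 1-based (first, last) in leaf order


def cut_at_ccsv(tree: Dendrogram, threshold: float) -> list[SwarmCluster]:
    """Maximal subtrees whose root merge similarity exceeds ``threshold``.

    A node qualifies when ``1 - merge_dissimilarity > threshold``; leaves
    always qualify (singleton CCSV is 1).  The result partitions the
    leaves into ranges contiguous in leaf order, labelled
    ``"first–last"`` from 1-based leaf positions.
    """
    position = {leaf: i + 1 for i, leaf in enumerate(tree.leaf_order)}
    clusters: list[SwarmCluster] = []

    def emit(node: int) -> None:
        idx = tree.leaf_indices(node)
        pos = sorted(position[i] for i in idx)
        ccsv = 1.0 if node < tree.n_leaves else 1.0 - tree.node_height(node)
        clusters.append(
            SwarmCluster(
                label=f"{pos[0]}–{pos[-1]}",
                member_ids={tree.leaves[i] for i in idx},
                ccsv=float(np.clip(ccsv, 0.0, 1.0)),
                positions=(pos[0], pos[-1]),
            )
        )

    def walk(node: int) -> None:
        if node < tree.n_leaves or 1.0 - tree.node_height(node) > threshold:
            emit(node)
            return
        left, right = tree.children(node)
        walk(left)
        walk(right)

    walk(tree.root)
    clusters.sort(key=lambda c: c.positions)
    return clusters


def cophenetic(tree: Dendrogram) -> np.ndarray:
    """Merge dissimilarity of the lowest common ancestor, per leaf pair."""
    n = tree.n_leaves
    C = np.zeros((n, n))
    for k, (a, b, h) in enumerate(tree.merges):
        left = tree.leaf_indices(a)
        right = tree.leaf_indices(b)
        for i in left:
            C[i, right] = h
        for j in right:
            C[j, left] = h
    return C


def write_newick(tree: Dendrogram, path) -> None:
    """Ultrametric Newick export: root-to-leaf depth = merge height / 2."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_newick(tree))


def to_newick(tree: Dendrogram) -> str:
    def render(node: int, parent_height: float) -> str:
        h = tree.node_height(node)
        branch = (parent_height - h) / 2.0
        ch = tree.children(node)
        if ch is None:
            name = str(tree.leaves[node]).replace(" ", "_")
            return f"{name}:{branch:.10g}"
        inner = ",".join(render(c, h) for c in ch)
        return f"({inner}):{branch:.10g}"

    root = tree.root
    h = tree.node_height(root)
    ch = tree.children(root)
    if ch is None:  # single leaf
        return f"{tree.leaves[root]};"
    inner = ",".join(render(c, h) for c in ch)
    return f"({inner});"
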