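"""Deterministic agglomerative clustering of sample-by-pathway scores.

Hand-rolled Lance-Williams agglomeration (rather than a library call) so
that merge order under distance ties is fully specified: among equal
minimum distances, the pair whose (lexicographically smallest leaf id of
each cluster) pair sorts first merges first. This makes dendrograms
invariant to input sample order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "complete", "ward", "single")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: ``left``/``right`` are node ids (leaf names
    or earlier merge indices as ints); height is the linkage distance."""

    left: object
    right: object
    height: float


@dataclass
class Dendrogram:
    """Binary merge tree over samples with per-merge heights."""

    leaves: tuple[str, ...]       # original leaf names (input order)
    merges: tuple[Merge, ...]     # n-1 merges; node ids: str=leaf, int=merge index
    leaf_order: tuple[str, ...]   # display order implied by the tree

    def __post_init__(self) -> None:
        if sorted(self.leaf_order) != sorted(self.leaves):
            raise ValueError("leaf_order must be a permutation of leaves")
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _members(self) -> list[set[str]]:
        """Leaf sets of each merge node."""
        out: list[set[str]] = []
        for m in self.merges:
            s: set[str] = set()
            for node in (m.left, m.right):
                s |= out[node] if isinstance(node, int) else {node}
            out.append(s)
        return out


def pairwise_distances(
    data: pd.DataFrame, metric: Literal["euclidean", "correlation"]
) -> pd.DataFrame:
    """Row-by-row distance matrix: euclidean or 1 - Pearson correlation."""
    X = data.to_numpy(dtype=float)
    if metric == "euclidean":
        sq = (X ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
        D = np.sqrt(np.clip(d2, 0.0, None))
    elif metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((Xc ** 2).sum(axis=1))
        if (norms == 0).any():
            raise ValueError("correlation distance undefined for constant rows")
        C = (Xc @ Xc.T) / np.outer(norms, norms)
        D = 1.0 - np.clip(C, -1.0, 1.0)
    else:
        raise ValueError(f"unknown distance {metric!r}")
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=data.index, columns=data.index)


def _lance_williams(linkage: str, d_ac: float, d_bc: float, d_ab: float,
                    na: int, nb: int, nc: int) -> float:
    if linkage == "average":
        return (na * d_ac + nb * d_bc) / (na + nb)
    if linkage == "complete":
        return max(d_ac, d_bc)
    if linkage == "single":
        return min(d_ac, d_bc)
    if linkage == "ward":
        n = na + nb + nc
        return math.sqrt(max(
            ((na + nc) * d_ac ** 2 + (nb + nc) * d_bc ** 2 - nc * d_ab ** 2) / n,
            0.0,
        ))
    raise ValueError(f"unknown linkage {linkage!r}")


def cluster_samples(
    scores,
    distance: Literal["euclidean", "correlation"] = "euclidean",
    linkage: Literal["average", "complete", "ward", "single"] = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples (rows of the score matrix).

    Accepts a ``PathwayScoreMatrix`` or a plain samples x features
    DataFrame. Ward linkage requires euclidean distances.
    """
    data = scores.values if hasattr(scores, "scheme") else scores
    if not isinstance(data, pd.DataFrame):
        raise TypeError("expected a PathwayScoreMatrix or DataFrame")
    if distance not in DISTANCES:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    n = len(data.index)
    if n < 2:
        raise ValueError("clustering requires at least 2 samples")
    if data.isna().to_numpy().any():
        raise ValueError("undefined scores in clustering input")

    names = [str(s) for s in data.index]
    D = pairwise_distances(data, distance).to_numpy()

    # active cluster state; node id is a leaf name (str) or merge index (int)
    node_ids: list[object] = list(names)
    sizes: list[int] = [1] * n
    minleaf: list[str] = list(names)          # lexicographic tie-break key
    leaflists: list[list[str]] = [[nm] for nm in names]
    active = list(range(n))
    merges: list[Merge] = []

    while len(active) > 1:
        best: Optional[tuple[str, str]] = None
        best_pair: Optional[tuple[int, int]] = None
        best_d = math.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                d = D[a, b]
                key = tuple(sorted((minleaf[a], minleaf[b])))
                if best is None or d < best_d or (d == best_d and key < best):
                    best_d = float(d)
                    best = key
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        # orient: the side carrying the smaller min leaf goes left
        if minleaf[b] < minleaf[a]:
            a, b = b, a
        merge_idx = len(merges)
        merges.append(Merge(left=node_ids[a], right=node_ids[b], height=float(best_d)))
        # update distances into slot a (Lance-Williams), retire slot b
        for c in active:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = _lance_williams(
                linkage, D[a, c], D[b, c], D[a, b], sizes[a], sizes[b], sizes[c]
            )
        node_ids[a] = merge_idx
        sizes[a] = sizes[a] + sizes[b]
        minleaf[a] = min(minleaf[a], minleaf[b])
        leaflists[a] = leaflists[a] + leaflists[b]
        active.remove(b)

    root = active[0]
    return Dendrogram(
        leaves=tuple(names), merges=tuple(merges), leaf_order=tuple(leaflists[root])
    )


def cut(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Partition into k clusters by undoing the k-1 highest merges.

    Labels are 1..k in order of first appearance along ``leaf_order``.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    # replay the first n-k merges (heights are non-decreasing, so the last
    # k-1 merges are the highest)
    parent: dict[object, object] = {}

    def find(x):
        while x in parent:
            x = parent[x]
        return x

    for idx, m in enumerate(dendrogram.merges[: n - k]):
        parent[find(m.left)] = idx
        parent[find(m.right)] = idx

    rep: dict[str, object] = {leaf: find(leaf) for leaf in dendrogram.leaves}
    labels: dict[object, int] = {}
    for leaf in dendrogram.leaf_order:
        r = rep[leaf]
        if r not in labels:
            labels[r] = len(labels) + 1
    return {leaf: labels[rep[leaf]] for leaf in dendrogram.leaves}


def cophenetic_distances(dendrogram: Dendrogram) -> pd.DataFrame:
    """Pairwise heights at which leaves first share a cluster."""
    n = dendrogram.n_leaves
    leaves = list(dendrogram.leaves)
    idx = {nm: i for i, nm in enumerate(leaves)}
    D = np.zeros((n, n))
    members: list[set[str]] = []
    for m in dendrogram.merges:
        left = members[m.left] if isinstance(m.left, int) else {m.left}
        right = members[m.right] if isinstance(m.right, int) else {m.right}
        for u in left:
            for v in right:
                D[idx[u], idx[v]] = D[idx[v], idx[u]] = m.height
        members.append(left | right)
    return pd.DataFrame(D, index=leaves, columns=leaves)


def pair_adjacency(
    dendrogram: Dendrogram, pairs: Sequence[tuple[str, str]]
) -> tuple[dict[tuple[str, str], bool], float]:
    """Fraction of pairs whose two members merge with each other first.

    A pair is adjacent iff some merge joins exactly its two singleton
    leaves (i.e. each member's first merge is with the other).
    """
    leafset = set(dendrogram.leaves)
    for u, v in pairs:
        if u not in leafset or v not in leafset:
            raise ValueError(f"pair member missing from tree: {(u, v)}")
    sibling_merges = {
        frozenset((m.left, m.right))
        for m in dendrogram.merges
        if isinstance(m.left, str) and isinstance(m.right, str)
    }
    flags = {(u, v): frozenset((u, v)) in sibling_merges for u, v in pairs}
    frac = sum(flags.values()) / len(flags) if flags else float("nan")
    return flags, frac


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths = parent height - child height."""
    heights: list[float] = [m.height for m in dendrogram.merges]

    def node_height(node) -> float:
        return heights[node] if isinstance(node, int) else 0.0

    def render(node, parent_height: float) -> str:
        bl = parent_height - node_height(node)
        if isinstance(node, int):
            m = dendrogram.merges[node]
            inner = f"({render(m.left, m.height)},{render(m.right, m.height)})"
            return f"{inner}:{bl:.10g}"
        return f"{_quote(node)}:{bl:.10g}"

    root = len(dendrogram.merges) - 1
    m = dendrogram.merges[root]
    return f"({render(m.left, m.height)},{render(m.right, m.height)});"


def _quote(name: str) -> str:
    if any(c in name for c in "(),:; \t"):
        return "'" + name.replace("'", "''") + "'"
    return name
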