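"""Phenotypic subtyping by complete-linkage clustering of deficit profiles.

Participants are clustered on their aggregate abnormality z-scores.
Pairwise distances are Euclidean over the columns both participants
share, rescaled by sqrt(total columns / shared columns) so that pairs
with missing cells are comparable in magnitude (this pairwise-complete
rescaling may violate the triangle inequality, which complete linkage
tolerates). Agglomeration merges the pair of clusters with the smallest
maximum inter-member distance; ties break deterministically toward the
clusters containing the smallest participant indices. The resulting
merge tree is reported scipy-style, together with a leaf order used to
lay out the profile report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "pairwise_distance",
    "complete_linkage",
    "cut_clusters",
    "profile_report",
]


@dataclass(frozen=True)
class DistanceMatrix:
    values: np.ndarray  # square, symmetric, zero diagonal
    labels: tuple[str, ...]
    policy: str

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree in scipy linkage convention.

    ``merges`` has one row (a, b, height, size) per agglomeration;
    cluster ids 0..n-1 are leaves, id n+k is the cluster created by merge
    k. Heights are nondecreasing for complete linkage. ``leaf_order`` is
    the left-to-right layout order of the original labels.
    """

    merges: np.ndarray  # (n-1, 4)
    labels: tuple[str, ...]
    leaf_order: tuple[str, ...]

    def to_scipy(self) -> np.ndarray:
        return np.asarray(self.merges, dtype=float)


def pairwise_distance(
    ztable: pd.DataFrame, columns: list[str] | None = None, policy: str = "pairwise_complete"
) -> DistanceMatrix:
    """Euclidean profile distances with pairwise-complete rescaling.

    For each pair, the distance uses the columns where both scores are
    present, scaled by sqrt(n_columns / n_shared). ``policy="complete"``
    requires fully observed rows instead. A pair with no shared column
    is an error.
    """
    cols = list(columns) if columns is not None else list(ztable.columns)
    Z = ztable[cols].to_numpy(dtype=float)
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least 2 participants to compute distances")
    if policy == "complete" and np.isnan(Z).any():
        raise ValueError("policy='complete' requires fully observed profiles")
    if policy not in ("pairwise_complete", "complete"):
        raise ValueError(f"unknown missing-data policy {policy!r}")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(np.isnan(Z[i]) | np.isnan(Z[j]))
            k = int(shared.sum())
            if k == 0:
                raise ValueError(
                    f"participants {ztable.index[i]!r} and {ztable.index[j]!r} share no observed column"
                )
            d = np.sqrt(np.sum((Z[i, shared] - Z[j, shared]) ** 2) * (m / k))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(values=D, labels=tuple(map(str, ztable.index)), policy=policy)


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage merge tree.

    Each merge joins the pair of active clusters with the smallest
    maximum pairwise member distance; exact ties are broken toward the
    pair whose clusters contain the smallest original indices, making
    the tree invariant to permutations of the input up to relabeling.
    """
    D = dist.values
    n = D.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 participants")
    # stable key: rank of the participant label, so tie-breaking and leaf
    # ordering are equivariant under permutations of the input rows
    label_rank = {i: rank for rank, i in enumerate(np.argsort(np.array(dist.labels)))}
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    active = set(range(n))
    cd = {}  # complete-linkage distance between active cluster ids
    for i in range(n):
        for j in range(i + 1, n):
            cd[(i, j)] = D[i, j]
    merges = []
    next_id = n
    while len(active) > 1:
        # pick the minimum-height pair; ties -> smallest original member indices
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                h = cd[(a, b) if a < b else (b, a)]
                ra = min(label_rank[i] for i in members[a])
                rb = min(label_rank[i] for i in members[b])
                key = (h, min(ra, rb), max(ra, rb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        h = cd[(a, b)]
        new = next_id
        next_id += 1
        members[new] = members[a] | members[b]
        active.discard(a)
        active.discard(b)
        for c in active:
            da = cd[(min(a, c), max(a, c))]
            db = cd[(min(b, c), max(b, c))]
            cd[(min(new, c), max(new, c))] = max(da, db)
        active.add(new)
        merges.append([a, b, h, len(members[new])])

    # leaf order: recursive traversal, child containing the smallest
    # participant label first
    children = {n + k: (int(m[0]), int(m[1])) for k, m in enumerate(merges)}

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        la, lb = leaves(a), leaves(b)
        if min(label_rank[i] for i in la) < min(label_rank[i] for i in lb):
            return la + lb
        return lb + la

    order = leaves(next_id - 1)
    return Dendrogram(
        merges=np.array(merges, dtype=float),
        labels=dist.labels,
        leaf_order=tuple(dist.labels[i] for i in order),
    )


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Labels from cutting the tree into ``k`` clusters.

    Applies the first n - k merges; cluster labels are integers 1..k in
    order of appearance along the leaf order.
    """
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _, _) in enumerate(dendrogram.merges[: n - k]):
        new = n + idx
        parent[find(int(a))] = new
        parent[find(int(b))] = new
    roots = {}
    raw = {lab: find(i) for i, lab in enumerate(dendrogram.labels)}
    labels = {}
    for lab in dendrogram.leaf_order:
        r = raw[lab]
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[lab] = roots[r]
    return pd.Series(labels, name="cluster").reindex(list(dendrogram.labels))


def profile_report(
    ztable: pd.DataFrame,
    deficits: pd.DataFrame,
    dendrogram: Dendrogram,
    aggregate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Ordered per-participant profile table (summary columns first).

    Rows follow the dendrogram leaf order; each test column carries the
    z-score and a companion ``<col>_deficit`` flag; missing scores stay
    NaN with flag False. Participants absent from the dendrogram (e.g.
    excluded for having no scores) are dropped with a warning.
    """
    missing_rows = [p for p in ztable.index if str(p) not in dendrogram.leaf_order]
    if missing_rows:
        warnings.warn(f"excluding participants without cluster position: {missing_rows}")
    extra = [p for p in dendrogram.leaf_order if p not in set(map(str, ztable.index))]
    if extra:
        raise ValueError(f"dendrogram references unknown participants: {extra}")
    flags = deficits.pivot(index="participant_id", columns="column", values="is_deficit")
    order = [p for p in dendrogram.leaf_order]
    agg = [c for c in (aggregate_columns or []) if c in ztable.columns]
    cols = agg + [c for c in ztable.columns if c not in agg]
    out = ztable.loc[order, cols].copy()
    for c in cols:
        if c in flags.columns:
            out[f"{c}_deficit"] = flags.reindex(order)[c].fillna(False).astype(bool)
        else:
            out[f"{c}_deficit"] = False
    return out[[x for c in cols for x in (c, f"{c}_deficit")]]
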