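"""Average-linkage agglomerative clustering in torsional space.

Side-chain conformations are clustered with unweighted average linkage
(UPGMA) under the periodic torsional metric, and the dendrogram is cut at a
fixed height (40 deg by default) to produce flat clusters, each corresponding
to one rotamer.  The agglomeration is implemented here rather than delegated
so that the tie-break rule (merge the lexicographically smallest pair of
cluster ids among equal-distance candidates) and the strict "< cutoff" cut
are explicit and deterministic; scipy's implementation serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .torsion import TorsionVector, periodic_angle_distance

__all__ = [
    "pairwise_torsion_distances",
    "Dendrogram",
    "ClusterAssignment",
    "average_linkage_cluster",
    "export_merge_table",
]


def export_merge_table(dendrogram: "Dendrogram", path) -> None:
    """Write the dendrogram merge list as a TSV for external plotting tools."""
    lines = ["cluster_a\tcluster_b\theight\tsize"]
    for a, b, height, size in dendrogram.merges:
        lines.append(f"{a}\t{b}\t{height!r}\t{size}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def pairwise_torsion_distances(vectors: Sequence) -> np.ndarray:
    """Condensed table of pairwise torsional distances.

    Returns the m(m-1)/2 upper-triangle entries in scipy's condensed order.
    All vectors must share the same chi dimension.
    """
    if len(vectors) == 0:
        raise ValueError("need at least one torsion vector")
    arrs = [
        v.as_array() if isinstance(v, TorsionVector) else np.atleast_1d(np.asarray(v, float))
        for v in vectors
    ]
    n = arrs[0].shape[0]
    for a in arrs:
        if a.shape[0] != n:
            raise ValueError("mixed torsion dimensions in distance table")
    mat = np.vstack(arrs)
    m = mat.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    diffs = periodic_angle_distance(mat[iu], mat[ju])
    diffs = np.atleast_2d(diffs)
    if diffs.shape[0] != iu.shape[0]:  # m == 2, n == 1 edge shape
        diffs = diffs.reshape(iu.shape[0], n)
    return np.sqrt(np.sum(np.square(diffs), axis=1))


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree of the agglomeration.

    ``merges`` holds one row per merge as (id_a, id_b, height, size) with
    scipy's id convention: leaves are 0..m-1, the cluster created by merge t
    gets id m+t.  Average linkage is reducible, so heights are
    non-decreasing.
    """

    merges: Tuple
    n_leaves: int

    def as_linkage(self) -> np.ndarray:
        """Merge table as an (m-1, 4) array (scipy linkage layout)."""
        return np.array([list(row) for row in self.merges], dtype=float).reshape(
            len(self.merges), 4
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat cluster labels, ids contiguous 0..k-1 in leaf-first-seen order."""

    labels: Tuple
    k: int


def _upgma(distances: np.ndarray, m: int):
    """Naive UPGMA with Lance-Williams updates and lexicographic tie-break."""
    # Square matrix indexed by creation order of active clusters.
    D = np.full((m, m), np.inf)
    iu, ju = np.triu_indices(m, k=1)
    D[iu, ju] = distances
    ids = list(range(m))  # cluster id per active slot, ascending
    sizes = [1] * m
    members: List[List[int]] = [[i] for i in range(m)]
    merges = []
    next_id = m
    while len(ids) > 1:
        flat = int(np.argmin(D))
        i, j = divmod(flat, D.shape[0])
        height = D[i, j]
        # Lance-Williams UPGMA update for the merged cluster vs the rest.
        si, sj = sizes[i], sizes[j]
        row_i = np.minimum(D[i, :], D[:, i])
        row_j = np.minimum(D[j, :], D[:, j])
        new_row = (si * row_i + sj * row_j) / (si + sj)
        merges.append((ids[i], ids[j], float(height), si + sj))
        new_members = members[i] + members[j]
        # Remove slots i and j (i < j), append the merged cluster at the end
        # so slot order stays ascending in cluster id.
        keep = [s for s in range(len(ids)) if s not in (i, j)]
        new_row = new_row[keep]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=np.inf)
        D[: len(keep), -1] = new_row
        D[-1, : len(keep)] = np.inf  # keep distances in the upper triangle
        np.fill_diagonal(D, np.inf)
        ids = [ids[s] for s in keep] + [next_id]
        sizes = [sizes[s] for s in keep] + [si + sj]
        members = [members[s] for s in keep] + [new_members]
        next_id += 1
    return merges


def average_linkage_cluster(
    distances: np.ndarray, cutoff: float = 40.0
) -> Tuple[Dendrogram, ClusterAssignment]:
    """Cluster a condensed distance table; cut the dendrogram at ``cutoff``.

    Two leaves share a flat cluster iff they are joined at a merge height
    strictly below the cutoff (merges at exactly the cutoff are split).
    Returns the full dendrogram and the flat assignment.
    """
    distances = np.asarray(distances, dtype=float)
    # m from m(m-1)/2 condensed entries
    m = int(round((1 + np.sqrt(1 + 8 * distances.size)) / 2))
    if distances.size == 0:
        m = 1
    if m * (m - 1) // 2 != distances.size:
        raise ValueError("condensed distance table has invalid length")
    if m == 1:
        dend = Dendrogram(merges=(), n_leaves=1)
        return dend, ClusterAssignment(labels=(0,), k=1)

    merges = _upgma(distances, m)
    dend = Dendrogram(merges=tuple(merges), n_leaves=m)

    # Flat cut: union leaves over merges with height < cutoff.
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    next_id = m
    rep = {i: i for i in range(m)}  # dendrogram id -> union-find leaf rep
    for a, b, height, _size in merges:
        if height < cutoff:
            ra, rb = find(rep[a]), find(rep[b])
            parent[rb] = ra
            rep[next_id] = ra
        else:
            rep[next_id] = find(rep[a])  # unused beyond bookkeeping
        next_id += 1
    roots = [find(i) for i in range(m)]
    label_of: dict = {}
    labels = []
    for r in roots:
        if r not in label_of:
            label_of[r] = len(label_of)
        labels.append(label_of[r])
    return dend, ClusterAssignment(labels=tuple(labels), k=len(label_of))
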