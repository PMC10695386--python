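"""Merging similar clusters by hierarchical clustering of their basis vectors.

Clusters produced in different chunks frequently describe the same
architecture; collation groups their basis vectors with agglomerative
clustering (Ward linkage on Euclidean distance by default, correlation
distance optionally) and unions the member sets of each group. The
dendrogram cut is ultimately a user decision; the automatic cut places
it at the largest gap in the dendrogram's merge heights, which also
allows the "no merging" outcome (e.g. for mutually orthogonal bases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import squareform

from .cluster_types import Cluster

logger = logging.getLogger(__name__)

__all__ = ["CollationPlan", "basis_distance_matrix", "collate_clusters", "apply_mapping"]

# near-zero distance below which a pair of bases counts as duplicate
_DUP_EPS = 1e-6


@dataclass
class CollationPlan:
    """How to collate: distance, linkage, and dendrogram cut."""

    distance: Literal["euclid", "corr"] = "euclid"
    linkage: str = "ward"
    cut: Literal["auto"] | int | float = "auto"  # int = n_groups, float = height

    def __post_init__(self) -> None:
        if self.distance not in ("euclid", "corr"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage == "ward" and self.distance == "corr":
            logger.warning(
                "Ward linkage with correlation distance is a non-metric "
                "combination; results are heuristic"
            )


def basis_distance_matrix(
    vectors: Sequence[np.ndarray], distance: str = "euclid"
) -> np.ndarray:
    """Symmetric pairwise distance matrix between basis vectors.

    ``euclid`` works on unit-max-scaled vectors (so amplitude differences
    between chunks do not dominate); ``corr`` is 1 - Pearson and is
    scale-free by construction.
    """
    M = np.asarray([np.asarray(v, dtype=float) for v in vectors])
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least two equal-length vectors")
    if distance == "euclid":
        scale = M.max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        Ms = M / scale
        diff = Ms[:, None, :] - Ms[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    elif distance == "corr":
        sd = M.std(axis=1)
        if (sd == 0).any():
            raise ValueError("correlation distance undefined for a constant vector")
        Z = (M - M.mean(axis=1, keepdims=True)) / sd[:, None]
        D = 1.0 - (Z @ Z.T) / M.shape[1]
        np.fill_diagonal(D, 0.0)
        D = np.clip(D, 0.0, None)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return (D + D.T) / 2.0


def _auto_groups(D: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Largest-gap cut of the dendrogram, allowing "no merging".

    Duplicated architectures from different chunks sit at small merge
    heights while genuinely different architectures join much higher, so
    the cut is placed at the largest jump in the sequence of merge
    heights. The jump from the leaf level (height 0) to the first merge
    is a candidate too: when it dominates, nothing is merged. Vectors at
    near-zero distance are always merged.
    """
    K = D.shape[0]
    heights = Z[:, 2]
    if heights[-1] < _DUP_EPS:  # everything is (near-)identical
        return np.ones(K, dtype=int)
    gaps = np.diff(np.concatenate([[0.0], heights]))
    if heights[0] < _DUP_EPS:
        gaps[0] = -1.0  # a leaf-level cut would split near-identical vectors
    i = int(np.argmax(gaps))
    if i == 0:
        return np.arange(1, K + 1)  # all separate
    # cut_tree guarantees exactly K - i groups even with tied merge heights
    return cut_tree(Z, n_clusters=K - i).ravel() + 1


def collate_clusters(
    clusters: Sequence[Cluster], plan: CollationPlan | None = None
) -> list[Cluster]:
    """Merge clusters whose basis vectors group together in the dendrogram.

    A merged cluster unions the member lists and carries the
    member-count-weighted mean of the constituent basis vectors; its
    lineage is inherited from the largest constituent. The result is a
    partition of exactly the input members.
    """
    plan = plan or CollationPlan()
    clusters = list(clusters)
    if len(clusters) == 0:
        raise ValueError("no clusters to collate")
    if len(clusters) == 1:
        return clusters
    D = basis_distance_matrix([c.basis for c in clusters], plan.distance)
    Z = linkage(squareform(D, checks=False), method=plan.linkage)
    if plan.cut == "auto":
        labels = _auto_groups(D, Z)
    elif isinstance(plan.cut, int):
        labels = cut_tree(Z, n_clusters=min(plan.cut, len(clusters))).ravel() + 1
    else:
        labels = fcluster(Z, t=float(plan.cut), criterion="distance")
    merged: list[Cluster] = []
    for g in np.unique(labels):
        group = [c for c, lab in zip(clusters, labels) if lab == g]
        members = [i for c in group for i in c.members]
        weights = np.array([len(c.members) for c in group], dtype=float)
        basis = np.average(
            np.asarray([c.basis for c in group]), axis=0, weights=weights
        )
        parent = max(group, key=lambda c: len(c.members))
        merged.append(Cluster(members=members, basis=basis, lineage=parent.lineage))
    merged.sort(key=lambda c: min(c.members))
    return merged


def apply_mapping(
    clusters: Sequence[Cluster], mapping: dict[int, int]
) -> list[Cluster]:
    """Mechanical curation: re-group clusters by a user map old -> new label.

    Cluster indices are 0-based positions in ``clusters``; clusters
    mapped to the same new label are merged (count-weighted mean basis).
    Unmapped clusters keep their own group.
    """
    groups: dict[int, list[Cluster]] = {}
    next_label = max(mapping.values(), default=-1) + 1
    for idx, c in enumerate(clusters):
        lab = mapping.get(idx)
        if lab is None:
            lab = next_label
            next_label += 1
        groups.setdefault(lab, []).append(c)
    out: list[Cluster] = []
    for lab in sorted(groups):
        group = groups[lab]
        members = [i for c in group for i in c.members]
        weights = np.array([len(c.members) for c in group], dtype=float)
        basis = np.average(
            np.asarray([c.basis for c in group]), axis=0, weights=weights
        )
        out.append(Cluster(members=members, basis=basis, lineage=group[0].lineage))
    return out
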