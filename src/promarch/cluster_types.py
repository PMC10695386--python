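"""Shared cluster containers and the run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = ["Lineage", "Cluster", "ClusterSolution", "RunConfig"]


@dataclass(frozen=True)
class Lineage:
    """Where a cluster came from: iteration, outer/inner chunk, local id."""

    iteration: int
    outer_chunk: int
    inner_chunk: int
    local_cluster: int


@dataclass
class Cluster:
    """A set of global sequence indices plus its architecture basis vector."""

    members: list[int]
    basis: np.ndarray
    lineage: Lineage

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        self.basis = np.asarray(self.basis, dtype=float)
        if (self.basis < 0).any():
            raise ValueError("basis vector must be non-negative")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterSolution:
    """A partition of sequence indices into clusters for one iteration."""

    clusters: list[Cluster]
    iteration: int

    def __post_init__(self) -> None:
        all_members = [i for c in self.clusters for i in c.members]
        if len(all_members) != len(set(all_members)):
            raise ValueError("clusters overlap: not a partition")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def member_set(self) -> set[int]:
        return {i for c in self.clusters for i in c.members}

    def labels(self, n: int | None = None) -> np.ndarray:
        """Per-sequence integer labels (cluster position in the list)."""
        idx = sorted(self.member_set())
        if n is None:
            n = len(idx)
        if set(idx) != set(range(n)):
            raise ValueError("solution does not cover indices 0..n-1")
        out = np.empty(n, dtype=int)
        for lab, c in enumerate(self.clusters):
            out[np.asarray(c.members)] = lab
        return out


@dataclass
class RunConfig:
    """All tunables of the chunked iterative clustering run.

    ``set_ocollation[t]`` says whether the clusters produced in iteration
    ``t`` are collated across chunks before seeding the next iteration;
    the final reporting collation is independent of these flags.
    """

    chunk_size: int = 500
    bound: float = 1e-6
    k_min: int = 2
    k_max: int = 8
    n_runs: int = 100
    mod_sel_type: Literal["stability", "bicv"] = "stability"
    cv_folds: int = 5
    total_itr: int = 1
    set_ocollation: list[bool] = field(default_factory=lambda: [True])
    result_dist: Literal["euclid", "corr"] = "euclid"
    result_aggl: str = "ward"
    seed: int = 0
    overfit_cv_threshold: float = 1.0
    min_cluster_size: int = 5
    shuffle_input: bool = False

    def __post_init__(self) -> None:
        if self.total_itr < 1:
            raise ValueError("total_itr must be >= 1")
        if len(self.set_ocollation) != self.total_itr:
            raise ValueError(
                "set_ocollation must have one flag per iteration "
                f"({self.total_itr}), got {len(self.set_ocollation)}"
            )
        if self.chunk_size < self.k_max:
            raise ValueError("chunk_size must be >= k_max")
        if self.mod_sel_type not in ("stability", "bicv"):
            raise ValueError(f"unknown mod_sel_type {self.mod_sel_type!r}")
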