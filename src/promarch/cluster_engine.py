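"""The chunked, iterative clustering driver.

The full collection of sequences is processed one *chunk* at a time: the
encoded columns of each chunk are factorised at a rank chosen by model
selection, sequences are assigned to the basis vector with their highest
coefficient, overfit clusters are re-merged into their parent, and
similar clusters from different chunks are optionally collated. Each
subsequent iteration treats the previous iteration's clusters as *outer
chunks* (re-chunked to ``chunk_size`` when larger) and repeats, so that
architectures mixed together in early chunks are progressively
disentangled. The last iteration's clusters are always collated once
more for final reporting, while the uncollated clusters are retained for
manual curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cluster_types import Cluster, ClusterSolution, Lineage, RunConfig
from .collation import CollationPlan, collate_clusters
from .io_encoding import EncodedMatrix
from .model_selection import select_k_bicv, select_k_stability
from .nmf_core import best_of_runs

logger = logging.getLogger(__name__)

__all__ = [
    "make_chunks",
    "assign_to_clusters",
    "detect_overfit",
    "remerge_overfit",
    "run_iteration",
    "run_clustering",
    "ClusteringResult",
]


def make_chunks(
    indices: list[int], chunk_size: int, min_remainder: int = 50
) -> list[list[int]]:
    """Split an ordered index list into contiguous chunks of ``chunk_size``.

    The trailing remainder keeps its own chunk unless it is smaller than
    ``min_remainder``, in which case it is merged into the previous chunk
    so every chunk is large enough for a well-posed factorisation.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if not indices:
        raise ValueError("cannot chunk an empty index list")
    chunks = [
        list(indices[i : i + chunk_size]) for i in range(0, len(indices), chunk_size)
    ]
    if len(chunks) > 1 and len(chunks[-1]) < min_remainder:
        chunks[-2].extend(chunks.pop())
    return chunks


def assign_to_clusters(H: np.ndarray) -> np.ndarray:
    """Assign each sequence (column of H) to its highest-coefficient basis.

    Ties break to the lowest basis index.
    """
    H = np.asarray(H)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    return H.argmax(axis=0)


def detect_overfit(
    winning_coeffs: np.ndarray,
    cv_threshold: float = 1.0,
    min_cluster_size: int = 5,
) -> bool:
    """Flag a cluster whose coefficient mass sits on very few sequences.

    An overfit basis vector models the idiosyncrasies of a handful of
    sequences: their coefficients dwarf the rest, so the coefficient of
    variation of the members' winning coefficients is large. Tiny
    clusters are flagged outright.
    """
    coeffs = np.asarray(winning_coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("cluster has no members")
    if coeffs.size < min_cluster_size:
        return True
    mean = coeffs.mean()
    if mean == 0:
        return True
    return bool(coeffs.std() / mean > cv_threshold)


def remerge_overfit(
    clusters: list[Cluster], flags: list[bool]
) -> list[Cluster]:
    """Merge flagged clusters into the first non-flagged (parent) cluster.

    If every cluster is flagged, the whole chunk collapses to a single
    cluster (with a warning): there is no parent to separate from.
    """
    if len(clusters) != len(flags):
        raise ValueError("one flag per cluster required")
    if not any(flags):
        return list(clusters)
    keep = [c for c, f in zip(clusters, flags) if not f]
    drop = [c for c, f in zip(clusters, flags) if f]
    if not keep:
        logger.warning("all clusters flagged as overfit; merging chunk into one")
        parent = clusters[0]
        extra = clusters[1:]
    else:
        parent = keep[0]
        extra = drop
        keep = keep[1:]
    merged_members = list(parent.members) + [i for c in extra for i in c.members]
    merged = Cluster(members=merged_members, basis=parent.basis, lineage=parent.lineage)
    return [merged] + keep


@dataclass
class ChunkRecord:
    """Bookkeeping for one processed inner chunk (for the run report)."""

    iteration: int
    outer_chunk: int
    inner_chunk: int
    size: int
    selected_k: int
    per_k: dict[int, float] = field(default_factory=dict)
    n_clusters: int = 0


def _derive_seed(config: RunConfig, iteration: int, outer: int, inner: int) -> int:
    return (config.seed + 100003 * iteration + 1009 * outer + 101 * inner) % (2**31 - 1)


def _process_inner_chunk(
    idx: list[int],
    V: EncodedMatrix,
    config: RunConfig,
    lineage_base: tuple[int, int, int],
) -> tuple[list[Cluster], ChunkRecord]:
    iteration, outer, inner = lineage_base
    seed = _derive_seed(config, iteration, outer, inner)
    Vc = V.columns(idx)
    k_max = min(config.k_max, len(idx) - 1, Vc.shape[0])
    record = ChunkRecord(
        iteration=iteration, outer_chunk=outer, inner_chunk=inner,
        size=len(idx), selected_k=1,
    )

    def single_cluster() -> list[Cluster]:
        basis = np.asarray(Vc.mean(axis=1)).ravel()
        lineage = Lineage(iteration, outer, inner, 0)
        return [Cluster(members=list(idx), basis=basis, lineage=lineage)]

    if k_max < config.k_min:
        record.n_clusters = 1
        return single_cluster(), record

    if config.mod_sel_type == "stability":
        rep = select_k_stability(
            Vc, k_min=config.k_min, k_max=k_max, bound=config.bound,
            n_runs=config.n_runs, seed=seed,
        )
        record.per_k = rep.per_k
    else:
        rep = select_k_bicv(
            Vc, k_min=config.k_min, k_max=k_max, folds=config.cv_folds,
            n_runs=config.n_runs, seed=seed,
        )
        record.per_k = {k: v[0] for k, v in rep.per_k.items()}
    k = rep.selected_k
    record.selected_k = k
    logger.info(
        "iter %d chunk (%d,%d) n=%d selected k=%d",
        iteration, outer, inner, len(idx), k,
    )
    if k == 1:
        record.n_clusters = 1
        return single_cluster(), record

    fit = best_of_runs(Vc, k, n_runs=config.n_runs, seed=seed)
    labels = assign_to_clusters(fit.H)
    clusters: list[Cluster] = []
    winning: list[np.ndarray] = []
    for local in range(k):
        mask = labels == local
        if not mask.any():
            logger.warning(
                "basis vector %d won no sequences in chunk (%d,%d); dropped",
                local, outer, inner,
            )
            continue
        members = [idx[j] for j in np.flatnonzero(mask)]
        clusters.append(
            Cluster(
                members=members,
                basis=fit.W[:, local],
                lineage=Lineage(iteration, outer, inner, local),
            )
        )
        winning.append(fit.H[local, mask])
    flags = [
        detect_overfit(w, config.overfit_cv_threshold, config.min_cluster_size)
        for w in winning
    ]
    clusters = remerge_overfit(clusters, flags)
    record.n_clusters = len(clusters)
    return clusters, record


def run_iteration(
    outer_chunks: list[list[int]],
    V: EncodedMatrix,
    config: RunConfig,
    iteration: int,
    records: list[ChunkRecord] | None = None,
) -> ClusterSolution:
    """One pass: process every outer chunk's inner chunks, then optionally
    collate the resulting clusters across chunks."""
    if not outer_chunks or not any(outer_chunks):
        raise ValueError("outer chunks are empty")
    min_rem = max(2 * config.k_min, 50)
    clusters: list[Cluster] = []
    for o, outer in enumerate(outer_chunks):
        inner_chunks = (
            make_chunks(outer, config.chunk_size, min_remainder=min_rem)
            if len(outer) > config.chunk_size
            else [list(outer)]
        )
        for i, idx in enumerate(inner_chunks):
            cl, rec = _process_inner_chunk(idx, V, config, (iteration, o, i))
            clusters.extend(cl)
            if records is not None:
                records.append(rec)
    if config.set_ocollation[iteration] and len(clusters) > 1:
        plan = CollationPlan(distance=config.result_dist, linkage=config.result_aggl)
        clusters = collate_clusters(clusters, plan)
    return ClusterSolution(clusters=clusters, iteration=iteration)


@dataclass
class ClusteringResult:
    """Everything a run produces: per-iteration solutions, the raw
    last-iteration clusters, the final collated solution, and a report."""

    iterations: list[ClusterSolution]
    final: ClusterSolution
    report: dict

    @property
    def last_uncollated(self) -> ClusterSolution:
        return self.iterations[-1]


def run_clustering(V: EncodedMatrix, config: RunConfig) -> ClusteringResult:
    """Run the full chunked, iterative clustering on an encoded matrix.

    Iteration 0 treats the whole input as one outer chunk; each later
    iteration's outer chunks are the previous iteration's clusters.
    After the last iteration the clusters are collated once more
    (independently of ``set_ocollation``) to give the reported final
    partition; the uncollated last-iteration solution is kept alongside
    for curation.
    """
    n = V.n
    if n == 0:
        raise ValueError("empty input")
    config_chunk = config.chunk_size
    if config_chunk > n:
        logger.warning("chunk_size %d > n=%d; using one chunk", config_chunk, n)
    indices = list(range(n))
    if config.shuffle_input:
        rng = np.random.default_rng(config.seed)
        indices = [int(i) for i in rng.permutation(n)]
    records: list[ChunkRecord] = []
    solutions: list[ClusterSolution] = []
    outer_chunks = [indices]
    for t in range(config.total_itr):
        sol = run_iteration(outer_chunks, V, config, t, records)
        if sol.member_set() != set(range(n)):
            raise AssertionError("iteration lost or duplicated sequences")
        solutions.append(sol)
        outer_chunks = [list(c.members) for c in sol.clusters]
    plan = CollationPlan(distance=config.result_dist, linkage=config.result_aggl)
    final_clusters = (
        collate_clusters(list(solutions[-1].clusters), plan)
        if solutions[-1].n_clusters > 1
        else list(solutions[-1].clusters)
    )
    final = ClusterSolution(clusters=final_clusters, iteration=config.total_itr)
    report = {
        "config": {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in vars(config).items()
        },
        "n_sequences": n,
        "chunks": [vars(r) for r in records],
        "iterations": [
            {
                "iteration": s.iteration,
                "n_clusters": s.n_clusters,
                "cluster_sizes": [len(c) for c in s.clusters],
            }
            for s in solutions
        ],
        "final_n_clusters": final.n_clusters,
        "final_cluster_sizes": [len(c) for c in final.clusters],
    }
    return ClusteringResult(iterations=solutions, final=final, report=report)
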