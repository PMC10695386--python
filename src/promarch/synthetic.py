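"""Simulated promoter-like data with planted, position-fixed motifs.

The generator emulates a benchmark of 1000 sequences of 100 nt drawn
uniformly over {A,C,G,T}, carrying four planted architectures:

====== ============================== ==================== ======
name   motifs                         1-based start        count
====== ============================== ==================== ======
A      AT dinucleotide repeat          10, 20, ..., 90      200
B      GATTACA and GAGAG               40 and 60            350
C      GAGAG                           60                   150
D      TCAT and GAGAG                  40 and 80            300
====== ============================== ==================== ======

Motifs in clusters B-D are planted under a mutation model: per motif
instance, ``positions`` distinct motif positions are chosen uniformly at
random and each chosen base is, with probability ``rate``, substituted
by a base drawn uniformly from the other three. Cluster A's repeat is
always planted verbatim. Clustering quality against the ground-truth
labels is measured with the adjusted Rand index (ARI).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster_types import RunConfig
from .io_encoding import DNA_ALPHABET, SequenceSet

__all__ = [
    "MotifPlacement",
    "ClusterSpec",
    "SyntheticSpec",
    "MutationModel",
    "four_cluster_spec",
    "disjoint_motif_spec",
    "plant_motif",
    "generate_dataset",
    "adjusted_rand_index",
    "enumerate_grid",
    "benchmark_grid",
    "write_fasta",
    "write_labels",
]


@dataclass(frozen=True)
class MotifPlacement:
    pattern: str
    start: int  # 1-based, inclusive


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    motifs: tuple[MotifPlacement, ...]
    count: int
    mutable: bool = True


@dataclass(frozen=True)
class SyntheticSpec:
    clusters: tuple[ClusterSpec, ...]
    L: int = 100
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        for c in self.clusters:
            if c.count < 1:
                raise ValueError(f"cluster {c.name}: count must be >= 1")
            for m in c.motifs:
                if m.start < 1 or m.start - 1 + len(m.pattern) > self.L:
                    raise ValueError(
                        f"motif {m.pattern} at {m.start} does not fit in L={self.L}"
                    )

    @property
    def total(self) -> int:
        return sum(c.count for c in self.clusters)


@dataclass(frozen=True)
class MutationModel:
    """Per-motif-instance mutation: ``positions`` candidate sites, each
    substituted with probability ``rate`` by one of the other three bases."""

    rate: float = 0.0
    positions: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.positions < 1:
            raise ValueError("positions must be >= 1")


def four_cluster_spec(repeat_end: int = 90) -> SyntheticSpec:
    """The standard four-architecture benchmark specification (see module
    docstring). ``repeat_end`` is the last 1-based start of cluster A's
    AT repeat."""
    a_starts = tuple(range(10, repeat_end + 1, 10))
    return SyntheticSpec(
        clusters=(
            ClusterSpec(
                "A", tuple(MotifPlacement("AT", s) for s in a_starts), 200,
                mutable=False,
            ),
            ClusterSpec(
                "B",
                (MotifPlacement("GATTACA", 40), MotifPlacement("GAGAG", 60)),
                350,
            ),
            ClusterSpec("C", (MotifPlacement("GAGAG", 60),), 150),
            ClusterSpec(
                "D",
                (MotifPlacement("TCAT", 40), MotifPlacement("GAGAG", 80)),
                300,
            ),
        ),
        L=100,
    )


def disjoint_motif_spec(n_per_cluster: int = 100, L: int = 60) -> SyntheticSpec:
    """Four architectures with disjoint motif supports (no shared motifs,
    non-overlapping positions) — the cleanest recoverable structure, used
    for exact-recovery sanity checks at mutation rate 0."""
    motifs = (
        ("TATAAATA", 11),
        ("CCGCCGCC", 25),
        ("GGAGGAGG", 41),
        ("TTGTTGTT", 51),
    )
    return SyntheticSpec(
        clusters=tuple(
            ClusterSpec(
                name=f"arch{i + 1}",
                motifs=(MotifPlacement(pat, start),),
                count=n_per_cluster,
            )
            for i, (pat, start) in enumerate(motifs)
        ),
        L=L,
    )


def plant_motif(
    seq: list[str],
    pattern: str,
    start: int,
    model: MutationModel,
    rng: np.random.Generator,
) -> None:
    """Overwrite ``seq`` in place with (a possibly mutated copy of) the motif.

    ``min(model.positions, len(pattern))`` distinct positions of the
    instance are sampled; each mutates with probability ``model.rate`` to
    a uniformly chosen *different* base, so the realised per-site
    mutation frequency equals the nominal rate.
    """
    if start < 1 or start - 1 + len(pattern) > len(seq):
        raise ValueError(f"motif {pattern} at {start} out of range")
    inst = list(pattern)
    if model.rate > 0:
        n_pos = min(model.positions, len(pattern))
        sites = rng.choice(len(pattern), size=n_pos, replace=False)
        for q in sites:
            if rng.random() < model.rate:
                others = [b for b in DNA_ALPHABET if b != inst[q]]
                inst[q] = others[rng.integers(3)]
    seq[start - 1 : start - 1 + len(pattern)] = inst


def generate_dataset(
    spec: SyntheticSpec, model: MutationModel, seed: int
) -> tuple[SequenceSet, list[str]]:
    """Draw the full dataset and its ground-truth labels.

    Background bases are i.i.d. from ``spec.background``; motifs are
    planted per cluster (clusters marked immutable use rate 0); the
    output order is a seeded uniform shuffle so cluster members are
    spread evenly across chunks. Labels align with the output order.
    """
    rng = np.random.default_rng(seed)
    bases = list(DNA_ALPHABET)
    seqs: list[str] = []
    labels: list[str] = []
    no_mut = MutationModel(rate=0.0, positions=model.positions)
    for cspec in spec.clusters:
        cmodel = model if cspec.mutable else no_mut
        for _ in range(cspec.count):
            s = list(rng.choice(bases, size=spec.L, p=list(spec.background)))
            for m in cspec.motifs:
                plant_motif(s, m.pattern, m.start, cmodel, rng)
            seqs.append("".join(s))
            labels.append(cspec.name)
    order = rng.permutation(len(seqs))
    width = len(str(len(seqs)))
    return (
        SequenceSet(
            ids=[f"seq{j:0{width}d}" for j in range(len(seqs))],
            seqs=[seqs[i] for i in order],
        ),
        [labels[i] for i in order],
    )


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two partitions (1 = identical up
    to relabeling, ~0 for independent partitions)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(list(labels_a), list(labels_b)))


def enumerate_grid(
    rates: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    positions: Sequence[int] = (1, 2, 3),
    chunk_sizes: Sequence[int] = (200, 500, 1000),
    repeats: int = 10,
) -> pd.DataFrame:
    """The benchmark grid as a table, one row per (rate, positions,
    chunk_size, repeat) cell, without running anything."""
    rows = [
        {"rate": r, "positions": p, "chunk_size": c, "repeat": rep}
        for r in rates
        for p in positions
        for c in chunk_sizes
        for rep in range(repeats)
    ]
    return pd.DataFrame(rows)


def benchmark_grid(
    spec: SyntheticSpec,
    rates: Sequence[float],
    positions: Sequence[int],
    chunk_sizes: Sequence[int],
    repeats: int,
    config: RunConfig,
    base_seed: int = 0,
    order: str = "di",
) -> pd.DataFrame:
    """Run the clustering over the full benchmark grid.

    Every cell generates a fresh dataset (seeded from ``base_seed`` and
    the cell coordinates), runs the chunked clustering, and records the
    final-partition ARI against the ground truth.
    """
    from .cluster_engine import run_clustering
    from .io_encoding import encode

    grid = enumerate_grid(rates, positions, chunk_sizes, repeats)
    results = []
    for row_i, row in grid.iterrows():
        cell_seed = (base_seed + 7919 * int(row_i)) % (2**31 - 1)
        model = MutationModel(rate=row["rate"], positions=int(row["positions"]))
        seqs, truth = generate_dataset(spec, model, seed=cell_seed)
        V = encode(seqs, order=order)
        cfg = replace(config, chunk_size=int(row["chunk_size"]), seed=cell_seed)
        result = run_clustering(V, cfg)
        ari = adjusted_rand_index(truth, result.final.labels(len(seqs)))
        results.append(
            {
                **row.to_dict(),
                "seed": cell_seed,
                "ari": ari,
                "n_final_clusters": result.final.n_clusters,
            }
        )
    return pd.DataFrame(results)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs:
            fh.write(f">{sid}\n{s}\n")


def write_labels(seqs: SequenceSet, labels: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sequence_id": seqs.ids, "cluster": list(labels)}).to_csv(
        path, sep="\t", index=False
    )
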