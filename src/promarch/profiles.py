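"""Per-cluster sequence profiles: PFMs, PWM-like matrices, logos, MEME export.

Two complementary views of an architecture are supported. A position
frequency matrix (PFM) counts the bases of a cluster's member sequences
at each position and is visualised as an information-content logo. The
NMF basis vector itself can also be rendered: it is reshaped to a
4 x L (mono) or 16 x L (di) matrix, the dinucleotide case collapsed to
4 x L by crediting each dinucleotide's weight to both constituent bases
(first base at its position, second at the next), and every column
normalised to sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_encoding import DNA_ALPHABET, SequenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "PFM",
    "PWMLike",
    "cluster_pfm",
    "info_content",
    "basis_to_pwm",
    "export_meme",
]


@dataclass
class PFM:
    """4 x L base counts (rows A, C, G, T); columns sum to the member count."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be non-negative")

    @property
    def L(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(DNA_ALPHABET),
            columns=range(1, self.L + 1),
        )


@dataclass
class PWMLike:
    """4 x L non-negative weights with unit column sums."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 4:
            raise ValueError("PWM must be 4 x L")
        if (self.weights < 0).any():
            raise ValueError("PWM weights must be non-negative")
        if not np.allclose(self.weights.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")

    @property
    def L(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=list(DNA_ALPHABET),
            columns=range(1, self.L + 1),
        )


def cluster_pfm(members: SequenceSet) -> PFM:
    """Base counts per position over a cluster's member sequences."""
    counts = np.zeros((4, members.L), dtype=np.int64)
    base_idx = {b: k for k, b in enumerate(DNA_ALPHABET)}
    for s in members.seqs:
        for i, b in enumerate(s):
            counts[base_idx[b], i] += 1
    return PFM(counts=counts)


def info_content(pfm: PFM, pseudocount: float = 1e-3) -> np.ndarray:
    """Per-base information heights (bits), a 4 x L matrix.

    Column frequencies are computed with a small pseudocount; the column
    information is ``2 + sum_b f_b log2 f_b`` (2 bits minus the entropy)
    and each base's height is its frequency times that information, so
    heights lie in [0, 2] and stacking them gives a sequence logo.
    """
    counts = pfm.counts.astype(float) + pseudocount
    freqs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1)), 0.0)
    col_info = 2.0 + plogp.sum(axis=0)
    return freqs * np.clip(col_info, 0.0, 2.0)


def basis_to_pwm(basis: np.ndarray, order: str, L: int) -> PWMLike:
    """Collapse an NMF basis vector into a column-normalised 4 x L matrix.

    Mono: reshape the 4L vector into position blocks. Di: each
    dinucleotide weight w(xy, i) credits base x at position i and base y
    at position i+1. Zero-weight columns become uniform (0.25 each) with
    a warning. Invariant to positive rescaling of the basis vector.
    """
    basis = np.asarray(basis, dtype=float)
    if (basis < 0).any():
        raise ValueError("basis vector must be non-negative")
    if order == "mono":
        if basis.size != 4 * L:
            raise ValueError(f"expected length {4 * L}, got {basis.size}")
        M = basis.reshape(L, 4).T.astype(float)
    elif order == "di":
        if basis.size != 16 * (L - 1):
            raise ValueError(f"expected length {16 * (L - 1)}, got {basis.size}")
        M = np.zeros((4, L))
        blocks = basis.reshape(L - 1, 16)
        for i in range(L - 1):
            W16 = blocks[i].reshape(4, 4)  # rows: first base x, cols: second y
            M[:, i] += W16.sum(axis=1)
            M[:, i + 1] += W16.sum(axis=0)
    else:
        raise ValueError(f"order must be 'mono' or 'di', got {order!r}")
    sums = M.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("%d zero-weight columns set to uniform", int(zero.sum()))
        M[:, zero] = 0.25
        sums[zero] = 1.0
    return PWMLike(weights=M / sums)


def export_meme(
    pwms: Sequence[PWMLike],
    names: Sequence[str],
    path: str | Path,
    nsites: Sequence[int] | None = None,
) -> None:
    """Write motifs in MEME minimal format (one motif per cluster).

    The file round-trips through standard MEME-format parsers
    (e.g. ``Bio.motifs`` with the ``minimal`` format). ``nsites`` is
    motif metadata; some parsers reconstruct counts as ``prob * nsites``,
    so the large default preserves probability resolution.
    """
    if len(pwms) != len(names):
        raise ValueError("one name per PWM required")
    if nsites is None:
        nsites = [1_000_000] * len(pwms)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
    ]
    for pwm, name, ns in zip(pwms, names, nsites):
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.L} "
            f"nsites= {ns} E= 0"
        )
        for col in pwm.weights.T:
            lines.append(" ".join(f"{x:.6f}" for x in col))
        lines.append("")
    Path(path).write_text("\n".join(lines))
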