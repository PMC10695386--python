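"""Reading TSS-aligned DNA sequences and one-hot encoding them as a feature matrix.

The clustering algorithm operates on a sparse (0,1) matrix ``V`` of shape
``p x n`` in which column ``j`` is the one-hot encoding of sequence ``j``.
In mononucleotide mode a length-``L`` sequence contributes ``p = 4L``
features (one block of four rows per position, rows ordered A, C, G, T
within the block); in dinucleotide mode the ``L - 1`` overlapping
dinucleotides contribute ``p = 16(L - 1)`` features (one block of sixteen
rows per dinucleotide start position, rows ordered AA, AC, ..., TT).
Dinucleotide profiles carry strictly more information (neighbour
dependencies such as the YR initiator) and are the recommended default.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO
from scipy import sparse
from scipy.io import mmwrite

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
DINUCLEOTIDES = tuple(a + b for a in DNA_ALPHABET for b in DNA_ALPHABET)

Order = Literal["mono", "di"]

__all__ = [
    "SequenceSet",
    "EncodedMatrix",
    "read_fasta",
    "encode",
    "decode_column",
    "write_matrix_market",
]


@dataclass
class SequenceSet:
    """A gapless alignment of equal-length DNA sequences over {A,C,G,T}.

    Sequences are assumed pre-aligned at a common reference position
    (e.g. the CAGE-derived dominant TSS); the container enforces the
    equal-length and alphabet invariants but is agnostic to the anchor.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if not self.seqs:
            raise ValueError("SequenceSet must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence identifiers must be unique")
        L = len(self.seqs[0])
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise ValueError(
                    f"length mismatch: record '{sid}' has length {len(s)}, "
                    f"expected {L}"
                )
            bad = set(s) - set(DNA_ALPHABET)
            if bad:
                raise ValueError(
                    f"record '{sid}' contains characters outside "
                    f"{{A,C,G,T}}: {sorted(bad)}"
                )
        if L < 2:
            raise ValueError("sequences must be at least 2 nt long")

    @property
    def L(self) -> int:
        """Common sequence length in nucleotides."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        return len(self.seqs)

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    def subset(self, indices: Sequence[int]) -> "SequenceSet":
        """Return a new SequenceSet restricted to ``indices`` (in order)."""
        return SequenceSet(
            ids=[self.ids[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
        )


@dataclass
class EncodedMatrix:
    """One-hot (0,1) feature matrix ``V`` (``p x n``) plus its row convention.

    ``values`` is a CSC sparse matrix so that column (sequence) slicing,
    as done by the chunked driver, is cheap. ``feature_index`` maps a
    ``(symbol, position)`` pair (position 0-based) to its row.
    """

    values: sparse.csc_matrix
    order: Order
    L: int
    feature_index: dict[tuple[str, int], int] = field(repr=False)

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def columns(self, indices: Sequence[int]) -> sparse.csc_matrix:
        """Sparse submatrix of the selected sequence columns."""
        return self.values[:, list(indices)]


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, drop_invalid: bool = False) -> SequenceSet:
    """Read a (plain or gzipped) FASTA file of equal-length DNA sequences.

    Parameters
    ----------
    path:
        FASTA file; records must share one length and use only A/C/G/T
        (case-insensitive).
    drop_invalid:
        If True, records with characters outside {A,C,G,T} (e.g. N) are
        skipped with a logged warning instead of raising. Length
        mismatches always raise: a ragged alignment has no valid anchor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids: list[str] = []
    seqs: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq).upper()
            if set(s) - set(DNA_ALPHABET):
                if drop_invalid:
                    logger.warning(
                        "dropping record '%s': non-ACGT characters", rec.id
                    )
                    continue
                raise ValueError(
                    f"record '{rec.id}' contains characters outside "
                    "{A,C,G,T}; use drop_invalid=True to skip such records"
                )
            ids.append(rec.id)
            seqs.append(s)
    if not seqs:
        raise ValueError(f"no usable sequences in {path}")
    return SequenceSet(ids=ids, seqs=seqs)


def _feature_index(order: Order, L: int) -> dict[tuple[str, int], int]:
    if order == "mono":
        return {(b, i): 4 * i + k for i in range(L) for k, b in enumerate(DNA_ALPHABET)}
    return {
        (d, i): 16 * i + k
        for i in range(L - 1)
        for k, d in enumerate(DINUCLEOTIDES)
    }


def encode(seqset: SequenceSet, order: Order = "di") -> EncodedMatrix:
    """One-hot encode a SequenceSet into the ``p x n`` feature matrix.

    Rows are grouped in position blocks; within the block for position
    ``i`` the rows follow alphabet order (A,C,G,T for mono; AA..TT for
    di). Every column has exactly one 1 per position block, so column
    sums are ``L`` (mono) or ``L - 1`` (di).
    """
    if order not in ("mono", "di"):
        raise ValueError(f"order must be 'mono' or 'di', got {order!r}")
    L, n = seqset.L, seqset.n
    base_idx = {b: k for k, b in enumerate(DNA_ALPHABET)}
    if order == "mono":
        p = 4 * L
        rows = np.empty(L * n, dtype=np.int64)
        for j, s in enumerate(seqset.seqs):
            for i, b in enumerate(s):
                rows[j * L + i] = 4 * i + base_idx[b]
        cols = np.repeat(np.arange(n), L)
    else:
        p = 16 * (L - 1)
        rows = np.empty((L - 1) * n, dtype=np.int64)
        for j, s in enumerate(seqset.seqs):
            for i in range(L - 1):
                rows[j * (L - 1) + i] = 16 * i + 4 * base_idx[s[i]] + base_idx[s[i + 1]]
        cols = np.repeat(np.arange(n), L - 1)
    data = np.ones(rows.shape[0], dtype=np.float64)
    values = sparse.csc_matrix((data, (rows, cols)), shape=(p, n))
    return EncodedMatrix(
        values=values, order=order, L=L, feature_index=_feature_index(order, L)
    )


def decode_column(matrix: EncodedMatrix, j: int) -> str:
    """Recover sequence ``j`` from its encoded column.

    Mono mode inverts exactly; di mode reads the first base of each
    dinucleotide and the second base of the final one.
    """
    col = np.asarray(matrix.values[:, j].todense()).ravel()
    if matrix.order == "mono":
        blocks = col.reshape(matrix.L, 4)
        return "".join(DNA_ALPHABET[k] for k in blocks.argmax(axis=1))
    blocks = col.reshape(matrix.L - 1, 16)
    dinucs = [DINUCLEOTIDES[k] for k in blocks.argmax(axis=1)]
    return "".join(d[0] for d in dinucs) + dinucs[-1][1]


def write_matrix_market(matrix: EncodedMatrix, path: str | Path) -> None:
    """Debug dump of the encoded matrix in MatrixMarket coordinate format."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mmwrite(str(path), matrix.values.tocoo())
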