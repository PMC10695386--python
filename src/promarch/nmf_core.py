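"""Non-negative matrix factorisation of the encoded sequence matrix.

``V (p x n) ~= W (p x k) @ H (k x n)`` with all entries non-negative:
columns of ``W`` are candidate sequence architectures (feature loadings),
columns of ``H`` hold each sequence's coefficients on those architectures.

Fits use the coordinate-descent solver with NNDSVD initialisation (which
encourages sparse factors). NNDSVD is deterministic, so run-to-run
variability — which the stability-based rank selection in
:mod:`promarch.model_selection` relies on — enters only through the
seeded shuffling of coordinate update order in the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .io_encoding import EncodedMatrix

__all__ = [
    "NMFDecomposition",
    "fit_nmf",
    "reconstruction_accuracy",
    "best_of_runs",
]

MAX_SEED = 2**31 - 1


@dataclass
class NMFDecomposition:
    """One NMF fit: basis matrix, coefficients, rank, accuracy, seed."""

    W: np.ndarray
    H: np.ndarray
    k: int
    accuracy: float
    seed: int

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.k or self.H.shape[0] != self.k:
            raise ValueError("W columns and H rows must both equal k")
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("W and H must be non-negative")


def _as_sparse(V) -> sparse.spmatrix:
    if isinstance(V, EncodedMatrix):
        return V.values
    if sparse.issparse(V):
        return V.tocsc()
    return sparse.csc_matrix(np.asarray(V, dtype=float))


def reconstruction_accuracy(V, W: np.ndarray, H: np.ndarray) -> float:
    """Relative-Frobenius reconstruction accuracy, clipped to [0, 1].

    Defined as ``1 - ||V - WH||_F / ||V||_F``: 1 for an exact
    reconstruction, 0 when the residual is as large as the data itself.
    """
    Vs = _as_sparse(V)
    if W.shape[0] != Vs.shape[0] or H.shape[1] != Vs.shape[1]:
        raise ValueError("incompatible shapes for V, W, H")
    v_norm = sparse.linalg.norm(Vs)
    if v_norm == 0:
        raise ValueError("reconstruction accuracy undefined for an all-zero V")
    resid = np.linalg.norm(Vs.toarray() - W @ H)
    return float(np.clip(1.0 - resid / v_norm, 0.0, 1.0))


def _unit_max_scale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Rescale each basis vector to unit max (inverse applied to H rows) so
    # that basis vectors are comparable across runs and chunks; the
    # factorisation WH is unchanged. All-zero basis vectors are left as is.
    scale = W.max(axis=0)
    nz = scale > 0
    W = W.copy()
    H = H.copy()
    W[:, nz] /= scale[nz]
    H[nz, :] *= scale[nz, None]
    return W, H


def fit_nmf(
    V,
    k: int,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> NMFDecomposition:
    """Fit a rank-``k`` NMF to ``V`` (EncodedMatrix, sparse or dense).

    Deterministic given ``(V, k, seed)``. Raises on ``k`` exceeding
    ``min(p, n)`` and on an all-zero input.
    """
    Vs = _as_sparse(V)
    p, n = Vs.shape
    if not 1 <= k <= min(p, n):
        raise ValueError(f"rank k={k} outside [1, min(p, n)={min(p, n)}]")
    if Vs.nnz == 0:
        raise ValueError("cannot factorise an all-zero matrix")
    model = NMF(
        n_components=k,
        init="nndsvd",
        solver="cd",
        tol=tol,
        max_iter=max_iter,
        shuffle=True,
        random_state=int(seed) % MAX_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(Vs)
    H = model.components_
    W, H = _unit_max_scale(W, H)
    acc = reconstruction_accuracy(Vs, W, H)
    return NMFDecomposition(W=W, H=H, k=k, accuracy=acc, seed=int(seed))


def best_of_runs(V, k: int, n_runs: int, seed: int) -> NMFDecomposition:
    """Best of ``n_runs`` seeded fits by reconstruction accuracy.

    Run ``r`` uses seed ``seed + r``; ties go to the lowest run index, so
    the result is reproducible from the master seed alone.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best: NMFDecomposition | None = None
    for r in range(n_runs):
        fit = fit_nmf(V, k, seed + r)
        if best is None or fit.accuracy > best.accuracy:
            best = fit
    assert best is not None
    return best
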