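"""Choosing the number of basis vectors (rank) per chunk.

Two criteria are provided:

* **Stability.** The set of basis vectors learned in one run is a
  *dictionary*. For two dictionaries R, R' with K vectors each, an
  Amari-type dissimilarity is computed from the K x K cross-correlation
  matrix C of their basis vectors::

      diss(R, R') = (2K - sum_j max_k C_kj - sum_k max_j C_kj) / (2K)

  which is 0 when R' is a (permuted) copy of R and 1 when no vectors
  correlate. The *instability* at rank k is the mean dissimilarity over
  all pairs of dictionaries from repeated seeded runs. Instability grows
  with k once the rank exceeds the structure in the data; the selected
  rank is the largest scanned k whose instability stays below a user
  bound (recommended 1e-6 .. 1e-8; default 1e-6, lenient). If even k=2
  violates the bound the chunk is declared homogeneous (k = 1).

* **Bi-cross-validation.** Gabriel-style holdout: rows and columns are
  each split into folds; the held-out block is predicted from the NMF fit
  of the retained block, and the rank is chosen by mean held-out
  reconstruction accuracy with the one-standard-error parsimony rule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .nmf_core import _as_sparse, fit_nmf, reconstruction_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "Dictionary",
    "StabilityReport",
    "BiCVReport",
    "amari_dissimilarity",
    "instability",
    "select_k_stability",
    "select_k_bicv",
    "select_from_instabilities",
    "select_one_se",
]


@dataclass
class Dictionary:
    """The basis vectors (columns of ``vectors``, p x K) from one NMF run."""

    vectors: np.ndarray
    run_seed: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise ValueError("vectors must be a p x K matrix with K >= 1")
        if not self.vectors.any(axis=0).all():
            raise ValueError("dictionary contains an all-zero basis vector")

    @property
    def K(self) -> int:
        return self.vectors.shape[1]


@dataclass
class StabilityReport:
    per_k: dict[int, float]
    bound: float
    selected_k: int


@dataclass
class BiCVReport:
    per_k: dict[int, tuple[float, float]]  # k -> (mean accuracy, std. error)
    selected_k: int


def amari_dissimilarity(R: Dictionary, R2: Dictionary) -> float:
    """Amari-type dissimilarity between two dictionaries, in [0, 1].

    C is the Pearson correlation between basis vectors, with negative
    correlations clipped to zero (an anti-correlated vector is no match).
    Symmetric; 0 for identical or permuted dictionaries; 1 when all
    correlations vanish.
    """
    A, B = R.vectors, R2.vectors
    if A.shape != B.shape:
        raise ValueError(
            f"dictionaries must match in shape, got {A.shape} vs {B.shape}"
        )
    K = R.K
    sa, sb = A.std(axis=0), B.std(axis=0)
    if (sa == 0).any() or (sb == 0).any():
        raise ValueError("correlation undefined for a zero-variance basis vector")
    Az = (A - A.mean(axis=0)) / sa
    Bz = (B - B.mean(axis=0)) / sb
    C = (Az.T @ Bz) / A.shape[0]
    C = np.clip(C, 0.0, None)
    diss = (2 * K - C.max(axis=0).sum() - C.max(axis=1).sum()) / (2 * K)
    return float(np.clip(diss, 0.0, 1.0))


def instability(dicts: list[Dictionary]) -> float:
    """Mean Amari-type dissimilarity over all unordered dictionary pairs."""
    if len(dicts) < 2:
        raise ValueError("instability requires at least two dictionaries")
    K = dicts[0].K
    if any(d.K != K for d in dicts):
        raise ValueError("all dictionaries must have the same K")
    pairs = list(itertools.combinations(dicts, 2))
    return float(np.mean([amari_dissimilarity(a, b) for a, b in pairs]))


def select_from_instabilities(per_k: dict[int, float], bound: float) -> int:
    """Apply the bounded-instability rule to a scanned ``k -> instability`` map.

    Returns the largest scanned k below the bound; 1 if none is.
    """
    under = [k for k, v in sorted(per_k.items()) if v < bound]
    return max(under) if under else 1


def select_k_stability(
    V,
    k_min: int = 2,
    k_max: int = 8,
    bound: float = 1e-6,
    n_runs: int = 100,
    seed: int = 0,
    scan_all: bool = False,
) -> StabilityReport:
    """Stability-based rank selection on the encoded matrix of one chunk.

    Scans k upward from ``k_min`` and selects the largest scanned k whose
    instability stays below the bound. Instability broadly grows with
    rank but can dip non-monotonically (a rank just below the true one is
    often ambiguous, hence unstable, while the true rank is stable
    again), so the scan stops only after two consecutive violations of
    the bound; ``scan_all=True`` evaluates every k in the range.
    """
    Vs = _as_sparse(V)
    if bound <= 0:
        raise ValueError("bound must be positive")
    if not 2 <= k_min <= k_max <= min(Vs.shape):
        raise ValueError(
            f"invalid rank range [{k_min}, {k_max}] for shape {Vs.shape}"
        )
    per_k: dict[int, float] = {}
    consecutive_violations = 0
    for k in range(k_min, k_max + 1):
        dicts = [
            Dictionary(fit_nmf(Vs, k, seed + 1000 * k + r).W, run_seed=seed + r)
            for r in range(n_runs)
        ]
        per_k[k] = instability(dicts)
        logger.debug("stability scan k=%d instability=%.3e", k, per_k[k])
        consecutive_violations = (
            consecutive_violations + 1 if per_k[k] >= bound else 0
        )
        if consecutive_violations >= 2 and not scan_all:
            break
    selected = select_from_instabilities(per_k, bound)
    return StabilityReport(per_k=per_k, bound=bound, selected_k=selected)


def select_one_se(per_k: dict[int, tuple[float, float]]) -> int:
    """One-standard-error rule on ``k -> (mean accuracy, SE)``.

    Selects the smallest k whose mean accuracy is within one standard
    error of the best k's mean.
    """
    best_mean, best_se = max(per_k.values(), key=lambda t: t[0])
    threshold = best_mean - best_se
    for k in sorted(per_k):
        if per_k[k][0] >= threshold:
            return k
    return min(per_k)  # unreachable; kept for safety


def _fold_slices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def select_k_bicv(
    V,
    k_min: int = 2,
    k_max: int = 8,
    folds: int = 5,
    n_runs: int = 5,
    seed: int = 0,
) -> BiCVReport:
    """Rank selection by r-fold bi-cross-validation (Gabriel holdout).

    Rows and columns are each partitioned into ``folds`` groups; fold f
    holds out the block V11 at (row-fold f, col-fold f), fits NMF on the
    retained block V22, and predicts ``V11 ~= V12 pinv(W22 H22) V21``.
    Per k, ``n_runs`` seeded repetitions are performed per fold and the
    mean held-out accuracy and its standard error over the folds x runs
    pool are recorded; the rank is chosen by the one-SE rule.
    """
    Vs = _as_sparse(V)
    p, n = Vs.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if p < 2 * folds or n < 2 * folds:
        raise ValueError("each fold needs at least 2 rows and 2 columns")
    if not 2 <= k_min <= k_max:
        raise ValueError("invalid rank range")
    rng = np.random.default_rng(seed)
    row_folds = _fold_slices(p, folds, rng)
    col_folds = _fold_slices(n, folds, rng)
    per_k: dict[int, tuple[float, float]] = {}
    for k in range(k_min, k_max + 1):
        scores: list[float] = []
        for f in range(folds):
            hold_r, hold_c = row_folds[f], col_folds[f]
            keep_r = np.setdiff1d(np.arange(p), hold_r)
            keep_c = np.setdiff1d(np.arange(n), hold_c)
            if min(len(keep_r), len(keep_c)) < k:
                raise ValueError("retained block too small for requested rank")
            V11 = Vs[np.ix_(hold_r, hold_c)].toarray()
            V12 = Vs[np.ix_(hold_r, keep_c)].toarray()
            V21 = Vs[np.ix_(keep_r, hold_c)].toarray()
            V22 = Vs[np.ix_(keep_r, keep_c)]
            for r in range(n_runs):
                fit = fit_nmf(V22, k, seed + 1000 * k + 10 * f + r)
                pred = V12 @ np.linalg.pinv(fit.W @ fit.H) @ V21
                v_norm = np.linalg.norm(V11)
                if v_norm == 0:
                    scores.append(0.0)
                    continue
                acc = 1.0 - np.linalg.norm(V11 - pred) / v_norm
                scores.append(float(np.clip(acc, 0.0, 1.0)))
        arr = np.asarray(scores)
        se = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        per_k[k] = (float(arr.mean()), float(se))
    return BiCVReport(per_k=per_k, selected_k=select_one_se(per_k))
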