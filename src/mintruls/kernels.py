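"""Pairwise similarity kernels over miRNAs and over target sites.

Eight base kernels are built -- per miRNA: free-energy, Gaussian
interaction-profile (GP), Needleman-Wunsch sequence, and SSR-profile
similarity; per site: free-energy, accessibility, AU-content and
SSR-profile similarity.  Each entity set's four kernels are integrated by
a weighted entrywise average into Sm (miRNAs) and St (sites), the two
factors of the Kronecker kernel used by the regularized least-squares
model.

All kernels are symmetric with unit diagonal and entries in [0, 1].  The
Gaussian kernels use the interaction-profile bandwidth rule: the width
parameter is a reference width (default 1) divided by the mean squared
norm (or mean squared value, for scalars) over the entity set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align

__all__ = [
    "SimilarityKernel",
    "gaussian_profile_kernel",
    "scalar_gaussian_kernel",
    "nw_similarity_kernel",
    "integrate_kernels",
    "nearest_psd",
]


@dataclass
class SimilarityKernel:
    """Square symmetric similarity matrix over one entity set."""

    entity_ids: list[str]
    M: np.ndarray
    kind: str = "integrated"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.entity_ids)
        if self.M.shape != (n, n):
            raise ValueError(f"kernel shape {self.M.shape} does not match {n} ids")

    def validate(self, atol: float = 1e-10, range_tol: float = 1e-8) -> None:
        asym = np.abs(self.M - self.M.T).max() if self.M.size else 0.0
        if asym >= atol:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        if not np.allclose(np.diag(self.M), 1.0, atol=1e-8):
            raise ValueError("kernel diagonal must be 1")
        if self.M.min() < -range_tol or self.M.max() > 1 + range_tol:
            raise ValueError(
                f"kernel entries outside [0, 1]: min {self.M.min():.3g}, "
                f"max {self.M.max():.3g}"
            )


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def gaussian_profile_kernel(vectors: np.ndarray, entity_ids: list[str] | None = None,
                            phi_prime: float = 1.0,
                            kind: str = "GP") -> SimilarityKernel:
    """Gaussian kernel on profile vectors with the mean-norm bandwidth rule.

    K[i, j] = exp(-phi * ||v_i - v_j||^2) with
    phi = phi_prime / mean_i ||v_i||^2.  Raises when every vector is zero
    (the bandwidth is undefined).
    """
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2:
        raise ValueError("vectors must form a 2-D array (one row per entity)")
    n = V.shape[0]
    ids = entity_ids if entity_ids is not None else [str(i) for i in range(n)]
    sq_norms = np.einsum("ij,ij->i", V, V)
    mean_sq = sq_norms.sum() / n
    if mean_sq == 0.0:
        raise ValueError("all profile vectors are zero: bandwidth undefined")
    phi = phi_prime / mean_sq
    G = V @ V.T
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * G
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-phi * d2)
    np.fill_diagonal(K, 1.0)
    return SimilarityKernel(list(ids), _symmetrize(K), kind)


def scalar_gaussian_kernel(values: np.ndarray, entity_ids: list[str] | None = None,
                           phi_prime: float = 1.0,
                           kind: str = "FE") -> SimilarityKernel:
    """Gaussian kernel on a scalar feature, same bandwidth rule as profiles.

    K[i, j] = exp(-gamma (x_i - x_j)^2) with gamma = phi_prime / mean(x^2).
    When every value is exactly 0 the bandwidth is undefined; the kernel
    falls back to gamma = 1 with a warning, which still yields the correct
    all-ones matrix because every pairwise distance is zero.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 entities")
    ids = entity_ids if entity_ids is not None else [str(i) for i in range(x.size)]
    mean_sq = float(np.mean(x**2))
    if mean_sq == 0.0:
        warnings.warn(
            "all feature values are 0; falling back to unit bandwidth "
            "(kernel is all-ones)", stacklevel=2,
        )
        gamma = 1.0
    else:
        gamma = phi_prime / mean_sq
    d2 = (x[:, None] - x[None, :]) ** 2
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return SimilarityKernel(list(ids), _symmetrize(K), kind)


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def nw_similarity_kernel(seqs: list[str], entity_ids: list[str] | None = None,
                         match: float = 1.0, mismatch: float = -1.0,
                         gap: float = -1.0) -> SimilarityKernel:
    """Needleman-Wunsch global-alignment similarity.

    Raw global alignment scores s(i, j) are normalized by the geometric
    mean of the self-scores, K[i, j] = max(0, s(i,j) / sqrt(s(i,i) s(j,j))),
    which keeps the kernel in [0, 1] with unit diagonal.
    """
    if any(len(s) == 0 for s in seqs):
        raise ValueError("zero-length sequence in NW kernel input")
    n = len(seqs)
    ids = entity_ids if entity_ids is not None else [str(i) for i in range(n)]
    aligner = _make_aligner(match, mismatch, gap)
    self_scores = np.array([match * len(s) for s in seqs], dtype=float)
    if (self_scores <= 0).any():
        raise ValueError("self-alignment scores must be positive for normalization")
    K = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = aligner.score(seqs[i], seqs[j])
            K[i, j] = K[j, i] = max(0.0, s / np.sqrt(self_scores[i] * self_scores[j]))
    return SimilarityKernel(list(ids), K, "NW")


def integrate_kernels(kernels: list[SimilarityKernel],
                      weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
                      kind: str = "integrated") -> SimilarityKernel:
    """Weighted entrywise average of kernels over the same entity set.

    The convex combination Sm = sum_i(w_i K_i) / sum_i(w_i) inherits
    symmetry, the unit diagonal and the [0, 1] range from its inputs.
    """
    if len(kernels) != len(weights):
        raise ValueError(f"{len(kernels)} kernels but {len(weights)} weights")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("at least one weight must be positive")
    ids = kernels[0].entity_ids
    for k in kernels[1:]:
        if k.entity_ids != ids:
            raise ValueError("kernels are over different entity lists")
    M = sum(wi * k.M for wi, k in zip(w, kernels)) / w.sum()
    return SimilarityKernel(list(ids), M, kind)


def nearest_psd(kernel: SimilarityKernel, floor: float = 0.0) -> SimilarityKernel:
    """Project a symmetric kernel onto the PSD cone, keeping a unit diagonal.

    Eigenvalues below ``floor`` are clipped, the matrix reconstructed, and
    the result rescaled to a unit diagonal.  Already-PSD input with a unit
    diagonal is a fixed point (up to floating-point roundoff).
    """
    M = _symmetrize(kernel.M)
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= floor:
        return SimilarityKernel(list(kernel.entity_ids), M, kernel.kind)
    vals = np.maximum(vals, floor)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(R), 1e-300, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return SimilarityKernel(list(kernel.entity_ids), _symmetrize(R), kernel.kind)
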