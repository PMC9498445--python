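"""Kronecker-product regularized least squares over a bipartite network.

Given an integrated miRNA kernel Sm (k x k), a site kernel St (l x l) and
the binary adjacency Y (k x l), the model minimizes

    J(f) = sum_i (y_i - f(x_i))^2 + lambda ||f||_K^2

over the pair kernel K = Sm (x) St, whose representer solution satisfies
(K + lambda I) alpha = y and predicts f = K alpha.  The kl x kl system is
never materialized: with eigendecompositions Sm = Qm Lm Qm^T and
St = Qt Lt Qt^T, the prediction matrix is

    F = Qm [ H o (Qm^T Y Qt) ] Qt^T,   H_ab = lm_a lt_b / (lm_a lt_b + lambda),

at O(k^3 + l^3 + kl(k+l)) cost.  The row-major vec convention
vec(A X B^T) = (A (x) B) vec(X) ties this eigen route to the dense system;
``direct_solve`` materializes K as a small-scale oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import InteractionMatrix
from .kernels import SimilarityKernel

__all__ = ["RLSModel", "ScoreMatrix", "fit", "direct_solve", "predict_scores"]

_DENSE_GUARD = 2000


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores for every miRNA x site pair."""

    mirna_ids: list[str]
    site_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.mirna_ids), len(self.site_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.isfinite(self.scores).all():
            raise ValueError("score matrix contains non-finite entries")


@dataclass
class RLSModel:
    """Fitted Kron-RLS model (eigenpairs of both kernels plus coefficients)."""

    mirna_ids: list[str]
    site_ids: list[str]
    Q_m: np.ndarray
    eigvals_m: np.ndarray
    Q_t: np.ndarray
    eigvals_t: np.ndarray
    lam: float
    C: np.ndarray  # filtered coefficient array in the eigenbasis
    score_matrix: np.ndarray = field(repr=False, default=None)

    def save(self, path) -> None:
        np.savez(
            path, format_version=1,
            mirna_ids=np.array(self.mirna_ids), site_ids=np.array(self.site_ids),
            Q_m=self.Q_m, eigvals_m=self.eigvals_m,
            Q_t=self.Q_t, eigvals_t=self.eigvals_t,
            lam=self.lam, C=self.C, score_matrix=self.score_matrix,
        )

    @classmethod
    def load(cls, path) -> "RLSModel":
        z = np.load(path, allow_pickle=False)
        if int(z["format_version"]) != 1:
            raise ValueError(f"unsupported model format version {z['format_version']}")
        return cls(
            list(z["mirna_ids"]), list(z["site_ids"]),
            z["Q_m"], z["eigvals_m"], z["Q_t"], z["eigvals_t"],
            float(z["lam"]), z["C"], z["score_matrix"],
        )


def _as_matrix(K: SimilarityKernel | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(K, SimilarityKernel):
        return K.M, list(K.entity_ids)
    return np.asarray(K, dtype=float), None


def fit(Sm: SimilarityKernel | np.ndarray, St: SimilarityKernel | np.ndarray,
        Y: InteractionMatrix | np.ndarray, lam: float = 35.0) -> RLSModel:
    """Fit Kron-RLS via the two small eigendecompositions.

    ``lam`` (lambda) trades data fit against smoothness in the pair-kernel
    norm; lam = 0 is permitted only when the Kronecker kernel is
    numerically nonsingular, in which case the fit interpolates Y exactly.
    """
    Km, mids = _as_matrix(Sm)
    Kt, tids = _as_matrix(St)
    if isinstance(Y, InteractionMatrix):
        Ymat = Y.A.astype(float)
        mids = mids or list(Y.mirna_ids)
        tids = tids or list(Y.site_ids)
    else:
        Ymat = np.asarray(Y, dtype=float)
    k, l = Km.shape[0], Kt.shape[0]
    if Ymat.shape != (k, l):
        raise ValueError(f"Y shape {Ymat.shape} does not match kernels ({k}, {l})")
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    lm, Qm = np.linalg.eigh(Km)
    lt, Qt = np.linalg.eigh(Kt)
    prod = np.outer(lm, lt)
    if lam == 0.0:
        scale = float(np.abs(prod).max()) or 1.0
        if np.abs(prod).min() <= 1e-12 * scale:
            cond = scale / max(np.abs(prod).min(), np.finfo(float).tiny)
            raise ValueError(
                "lambda = 0 with a numerically singular Kronecker kernel "
                f"(condition estimate {cond:.2e}); use lambda > 0"
            )
    H = prod / (prod + lam) if lam > 0 else np.ones_like(prod)
    C = H * (Qm.T @ Ymat @ Qt)
    F = Qm @ C @ Qt.T
    return RLSModel(
        mirna_ids=mids or [str(i) for i in range(k)],
        site_ids=tids or [str(j) for j in range(l)],
        Q_m=Qm, eigvals_m=lm, Q_t=Qt, eigvals_t=lt,
        lam=float(lam), C=C, score_matrix=F,
    )


def predict_scores(model: RLSModel) -> ScoreMatrix:
    """Score matrix of the fitted model (deterministic)."""
    if model.score_matrix is None:
        raise ValueError("model is not fitted")
    return ScoreMatrix(list(model.mirna_ids), list(model.site_ids),
                       model.score_matrix.copy())


def direct_solve(Sm: SimilarityKernel | np.ndarray, St: SimilarityKernel | np.ndarray,
                 Y: InteractionMatrix | np.ndarray, lam: float) -> ScoreMatrix:
    """Dense reference solver materializing K = Sm (x) St (tests only).

    Solves (K + lambda I) alpha = vec(Y) row-major and returns
    reshape(K alpha).  Guarded to kl <= 2000 to avoid memory blow-up.
    """
    Km, mids = _as_matrix(Sm)
    Kt, tids = _as_matrix(St)
    if isinstance(Y, InteractionMatrix):
        Ymat = Y.A.astype(float)
        mids = mids or list(Y.mirna_ids)
        tids = tids or list(Y.site_ids)
    else:
        Ymat = np.asarray(Y, dtype=float)
    k, l = Km.shape[0], Kt.shape[0]
    if k * l > _DENSE_GUARD:
        raise ValueError(
            f"problem size k*l = {k * l} exceeds the dense guard "
            f"({_DENSE_GUARD}); use fit() instead"
        )
    if Ymat.shape != (k, l):
        raise ValueError(f"Y shape {Ymat.shape} does not match kernels ({k}, {l})")
    K = np.kron(Km, Kt)
    y = Ymat.ravel()  # row-major vec matches the Kronecker factor order
    alpha = np.linalg.solve(K + lam * np.eye(k * l), y)
    scores = (K @ alpha).reshape(k, l)
    return ScoreMatrix(mids or [str(i) for i in range(k)],
                       tids or [str(j) for j in range(l)], scores)
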