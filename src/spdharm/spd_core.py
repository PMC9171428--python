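"""Core numerics on the manifold of symmetric positive-definite matrices.

Functional-connectivity matrices (full-rank correlation or covariance
matrices) live on the cone ``Sym_n^+`` of symmetric positive-definite (SPD)
matrices. This module provides the building blocks every downstream
operation relies on: validation, the symmetric matrix functions
(log, exp, square root), the affine-invariant Riemannian metric (AIRM)
tensor with its exponential/logarithmic maps, the AIRM and log-Euclidean
(LERM) geodesic distances, and the commutator diagnostic used to decide
when whitening and parallel transport coincide.

All matrix functions go through symmetric eigendecomposition
(``scipy.linalg.eigh``) and explicitly re-symmetrize their output so the
symmetry invariant survives floating-point round-off.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy import linalg

__all__ = [
    "MetricKind",
    "DEFAULT_SYM_TOL",
    "DEFAULT_PD_TOL",
    "validate_spd",
    "symmetrize",
    "is_spd",
    "matrix_log",
    "matrix_exp",
    "matrix_sqrt",
    "matrix_inv_sqrt",
    "airm_metric_tensor",
    "exp_map",
    "log_map",
    "airm_distance",
    "lerm_distance",
    "distance",
    "commutator",
    "commutator_norm",
]

#: Relative symmetry tolerance: max |M - M.T| may not exceed this fraction of
#: ||M||_F (absolute for matrices of norm < 1).
DEFAULT_SYM_TOL = 1e-8
#: Smallest eigenvalue must exceed this for a matrix to count as SPD.
DEFAULT_PD_TOL = 1e-10


class MetricKind(str, Enum):
    """The two Riemannian structures supported on ``Sym_n^+``.

    AIRM is the affine-invariant metric (distances invariant under congruence
    ``S -> C S C^T`` by any invertible ``C``); LERM is the log-Euclidean
    metric (Euclidean geometry of matrix logarithms).
    """

    AIRM = "airm"
    LERM = "lerm"


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Return the symmetric part ``(M + M.T) / 2``."""
    return (M + M.T) / 2.0


def validate_spd(
    M: np.ndarray,
    sym_tol: float = DEFAULT_SYM_TOL,
    pd_tol: float = DEFAULT_PD_TOL,
    eig_floor: float | None = None,
) -> np.ndarray:
    """Validate and canonicalize a candidate SPD matrix.

    Parameters
    ----------
    M
        Square real matrix.
    sym_tol
        Maximum allowed asymmetry ``max|M - M.T|``, relative to ``||M||_F``
        (absolute when the norm is below 1). Within tolerance the matrix is
        symmetrized; beyond it, a ``ValueError`` is raised.
    pd_tol
        Strict lower bound for the smallest eigenvalue.
    eig_floor
        If given, eigenvalues in ``(0, pd_tol]`` — e.g. from a rank-deficient
        correlation matrix estimated from too few time points — are clipped
        up to this floor instead of rejected. Eigenvalues ``<= 0`` are always
        rejected when ``eig_floor`` is None.

    Returns
    -------
    numpy.ndarray
        The symmetrized (and possibly eigenvalue-floored) SPD matrix.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    scale = max(1.0, float(np.linalg.norm(M)))
    asym = float(np.max(np.abs(M - M.T)))
    if asym > sym_tol * scale:
        raise ValueError(
            f"matrix is not symmetric: max asymmetry {asym:.3e} exceeds "
            f"tolerance {sym_tol * scale:.3e}"
        )
    S = symmetrize(M)
    w = linalg.eigvalsh(S)
    if w[0] <= pd_tol:
        if eig_floor is not None and w[0] > 0:
            w_f, U = linalg.eigh(S)
            w_f = np.maximum(w_f, eig_floor)
            return symmetrize((U * w_f) @ U.T)
        raise ValueError(
            f"matrix is not positive definite: smallest eigenvalue "
            f"{w[0]:.3e} <= {pd_tol:.3e}"
        )
    return S


def is_spd(M: np.ndarray, sym_tol: float = DEFAULT_SYM_TOL,
           pd_tol: float = DEFAULT_PD_TOL) -> bool:
    """True if ``M`` passes :func:`validate_spd` without regularization."""
    try:
        validate_spd(M, sym_tol=sym_tol, pd_tol=pd_tol)
    except ValueError:
        return False
    return True


def _eigh_fun(S: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, U = linalg.eigh(symmetrize(np.asarray(S, dtype=float)))
    return symmetrize((U * fun(w)) @ U.T)


def matrix_log(S: np.ndarray) -> np.ndarray:
    """Principal matrix logarithm of an SPD matrix: ``U log(D) U^T``.

    Maps the SPD cone diffeomorphically onto the vector space of symmetric
    matrices (the tangent space at any point, under LERM the global chart).
    """
    w, U = linalg.eigh(symmetrize(np.asarray(S, dtype=float)))
    if w[0] <= 0:
        raise ValueError(
            f"matrix logarithm requires positive eigenvalues; smallest is {w[0]:.3e}"
        )
    return symmetrize((U * np.log(w)) @ U.T)


def matrix_exp(V: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix: ``U exp(D) U^T`` (always SPD)."""
    return _eigh_fun(V, np.exp)


def matrix_sqrt(S: np.ndarray) -> np.ndarray:
    """Unique SPD square root ``S^{1/2} = Exp(Log(S)/2)``."""
    w, U = linalg.eigh(symmetrize(np.asarray(S, dtype=float)))
    if w[0] <= 0:
        raise ValueError("matrix square root requires an SPD input")
    return symmetrize((U * np.sqrt(w)) @ U.T)


def matrix_inv_sqrt(S: np.ndarray) -> np.ndarray:
    """Inverse SPD square root ``S^{-1/2}``."""
    w, U = linalg.eigh(symmetrize(np.asarray(S, dtype=float)))
    if w[0] <= 0:
        raise ValueError("matrix inverse square root requires an SPD input")
    return symmetrize((U / np.sqrt(w)) @ U.T)


def airm_metric_tensor(S: np.ndarray, X: np.ndarray, Y: np.ndarray) -> float:
    """AIRM inner product ``g_S(X, Y) = Tr(S^{-1} X S^{-1} Y)`` at base point S."""
    S = np.asarray(S, dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not (S.shape == X.shape == Y.shape):
        raise ValueError(
            f"dimension mismatch: {S.shape}, {X.shape}, {Y.shape}"
        )
    Sinv_X = linalg.solve(S, X, assume_a="sym")
    Sinv_Y = linalg.solve(S, Y, assume_a="sym")
    return float(np.trace(Sinv_X @ Sinv_Y))


def exp_map(S: np.ndarray, V: np.ndarray) -> np.ndarray:
    """AIRM exponential map: ``exp_S(V) = S^{1/2} Exp(S^{-1/2} V S^{-1/2}) S^{1/2}``.

    Shoots a geodesic from base point ``S`` along tangent vector ``V``.
    """
    h = matrix_sqrt(S)
    hinv = matrix_inv_sqrt(S)
    return symmetrize(h @ matrix_exp(hinv @ V @ hinv) @ h)


def log_map(S: np.ndarray, P: np.ndarray) -> np.ndarray:
    """AIRM logarithmic map: ``log_S(P) = S^{1/2} Log(S^{-1/2} P S^{-1/2}) S^{1/2}``.

    Inverse of :func:`exp_map`: the tangent vector at ``S`` pointing at ``P``.
    """
    h = matrix_sqrt(S)
    hinv = matrix_inv_sqrt(S)
    return symmetrize(h @ matrix_log(hinv @ P @ hinv) @ h)


def airm_distance(S: np.ndarray, P: np.ndarray) -> float:
    """AIRM geodesic distance ``||Log(S^{-1/2} P S^{-1/2})||_F``.

    Equals ``sqrt(sum log^2 lambda_i)`` over the generalized eigenvalues of
    the pencil ``(P, S)``; invariant under joint congruence by any
    invertible matrix.
    """
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    w = linalg.eigvalsh(symmetrize(P), symmetrize(S))
    if w[0] <= 0:
        raise ValueError("AIRM distance requires SPD arguments")
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def lerm_distance(S: np.ndarray, P: np.ndarray) -> float:
    """LERM geodesic distance ``||Log(S) - Log(P)||_F``."""
    return float(np.linalg.norm(matrix_log(S) - matrix_log(P)))


def distance(S: np.ndarray, P: np.ndarray, metric: MetricKind | str) -> float:
    """Geodesic distance under the requested metric."""
    metric = MetricKind(metric)
    if metric is MetricKind.AIRM:
        return airm_distance(S, P)
    return lerm_distance(S, P)


def commutator(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Matrix commutator ``[A, B] = AB - BA``.

    A vanishing commutator between the global mean and a site mean is the
    condition under which whitening and parallel transport harmonize
    identically; near-zero commutator norms explain why the two methods
    agree in practice on real cohorts.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    return A @ B - B @ A


def commutator_norm(A: np.ndarray, B: np.ndarray) -> float:
    """Frobenius norm of the commutator ``[A, B]``."""
    return float(np.linalg.norm(commutator(A, B)))
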