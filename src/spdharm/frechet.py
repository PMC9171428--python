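"""Fréchet means on the SPD manifold.

The Fréchet mean of matrices ``S_1..S_N`` minimizes the sum of squared
geodesic distances ``sum_i d^2(S, S_i)``. Under the log-Euclidean metric it
has the closed form ``Exp(mean of Log(S_i))``; under the affine-invariant
metric it is found by the classical fixed-point / gradient-descent
iteration ``S <- exp_S(mean_i log_S(S_i))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spd_core import (
    MetricKind,
    exp_map,
    log_map,
    matrix_exp,
    matrix_log,
    symmetrize,
)

__all__ = [
    "FrechetConfig",
    "FrechetResult",
    "lerm_frechet_mean",
    "airm_frechet_mean",
    "frechet_mean",
]


@dataclass
class FrechetConfig:
    """Convergence control for the iterative AIRM mean.

    ``tol`` bounds the Frobenius norm of the mean tangent update, which is
    exactly the Riemannian gradient direction of the Fréchet objective, so
    it is the natural residual. ``damping`` scales the update step
    (1.0 = the plain fixed-point iteration; < 1 can help badly conditioned
    sets).
    """

    metric: MetricKind = MetricKind.AIRM
    max_iter: int = 200
    tol: float = 1e-8
    init: str = "lerm_mean"  # lerm_mean | arithmetic_mean | first_element
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.init not in ("lerm_mean", "arithmetic_mean", "first_element"):
            raise ValueError(f"unknown init scheme {self.init!r}")


@dataclass
class FrechetResult:
    mean: np.ndarray
    n_iter: int
    final_update_norm: float
    converged: bool


def _check_stack(matrices: Sequence[np.ndarray]) -> np.ndarray:
    if len(matrices) == 0:
        raise ValueError("cannot average an empty collection of matrices")
    stack = np.asarray([np.asarray(M, dtype=float) for M in matrices])
    n = stack.shape[-1]
    if stack.ndim != 3 or stack.shape[-2] != n:
        raise ValueError("all matrices must be square and of equal dimension")
    return stack


def lerm_frechet_mean(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Closed-form log-Euclidean Fréchet mean ``Exp(1/N sum Log(S_i))``."""
    stack = _check_stack(matrices)
    logs = np.asarray([matrix_log(M) for M in stack])
    return matrix_exp(logs.mean(axis=0))


def airm_frechet_mean(
    matrices: Sequence[np.ndarray],
    config: FrechetConfig | None = None,
) -> FrechetResult:
    """Affine-invariant Fréchet mean by Riemannian gradient descent.

    Iterates ``S <- exp_S((damping/N) sum_i log_S(S_i))`` until the update
    norm drops below ``config.tol``. Non-convergence within ``max_iter`` is
    reported through ``converged=False`` rather than raised, so batteries
    of tests can log and continue.
    """
    if config is None:
        config = FrechetConfig()
    stack = _check_stack(matrices)
    if len(stack) == 1:
        return FrechetResult(mean=symmetrize(stack[0]), n_iter=0,
                             final_update_norm=0.0, converged=True)

    if config.init == "lerm_mean":
        current = lerm_frechet_mean(stack)
    elif config.init == "arithmetic_mean":
        current = symmetrize(stack.mean(axis=0))
    else:
        current = symmetrize(stack[0])

    update_norm = np.inf
    for it in range(1, config.max_iter + 1):
        tangent = np.mean([log_map(current, M) for M in stack], axis=0)
        update_norm = float(np.linalg.norm(tangent))
        if update_norm <= config.tol:
            return FrechetResult(mean=current, n_iter=it - 1,
                                 final_update_norm=update_norm, converged=True)
        current = exp_map(current, config.damping * tangent)
    # one last residual check after the final step
    tangent = np.mean([log_map(current, M) for M in stack], axis=0)
    update_norm = float(np.linalg.norm(tangent))
    return FrechetResult(mean=current, n_iter=config.max_iter,
                         final_update_norm=update_norm,
                         converged=update_norm <= config.tol)


def frechet_mean(
    matrices: Sequence[np.ndarray],
    metric: MetricKind | str = MetricKind.AIRM,
    config: FrechetConfig | None = None,
) -> np.ndarray:
    """Fréchet mean under the requested metric (dispatch helper)."""
    metric = MetricKind(metric)
    if metric is MetricKind.LERM:
        return lerm_frechet_mean(matrices)
    if config is None:
        config = FrechetConfig(metric=MetricKind.AIRM)
    return airm_frechet_mean(matrices, config).mean
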