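"""Site-harmonization transforms for multi-site SPD cohorts.

Multi-site functional-connectivity studies suffer two geometric batch
effects: site means are displaced from each other on the SPD manifold
(inter-site bias) and sites disperse differently around their means
(intra-site bias). Three congruence/translation transforms remove the
inter-site component while preserving intra-site geodesic distances:

* **Matrix whitening (MW)** — each site is congruence-transformed by the
  inverse square root of its own affine-invariant Fréchet mean, relocating
  every site mean to the identity.
* **Parallel transport (PT)** — each site is transported along the AIRM
  geodesic to a common reference (the Fréchet mean of site means) by the
  closed-form congruence ``C = (S0 Sbar_k^{-1})^{1/2}``, then the pooled
  result is whitened by that reference. When site means commute with the
  global mean this is provably identical to whitening.
* **Rigid log-Euclidean translation (RLET)** — matrix logarithms are
  rigidly translated so every site's log-mean coincides with a target
  (the global log-mean, or zero for the identity variant); an exact
  isometry of the log-Euclidean metric. The λ-rescaled variant
  additionally multiplies each site's centered logs by ``λ_k > 0``,
  rescaling intra-site distances to equalize dispersion across sites.

All transforms are condition-blind: one transform per site, never per
diagnostic group, so patient–control distances within a site are preserved
and the transforms can be applied to unlabeled data. Outputs are SPD by
construction (unlike entrywise location-scale adjustments, which do not
enforce positive definiteness). The unit diagonal of correlation-matrix
inputs is intentionally not restored: harmonized matrices are SPD but in
general not correlation matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import Cohort
from .frechet import FrechetConfig, airm_frechet_mean, lerm_frechet_mean
from .spd_core import (
    MetricKind,
    distance,
    matrix_exp,
    matrix_inv_sqrt,
    matrix_log,
    matrix_sqrt,
    symmetrize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationMethod",
    "HarmonizationReport",
    "site_means_lerm",
    "global_mean_lerm",
    "whiten",
    "transport_to_reference",
    "pt_harmonize",
    "rlet",
    "compute_lambda",
    "harmonize",
]


class HarmonizationMethod(str, Enum):
    MW = "mw"
    PT = "pt"
    RLET_GLOBAL = "rlet_global"
    RLET_IDENTITY = "rlet_identity"
    RLET_RESCALED = "rlet_rescaled"


@dataclass
class HarmonizationReport:
    """Post-hoc audit of a harmonization run.

    ``site_mean_to_target`` holds, per site, the geodesic distance (in the
    method's own metric) between the recomputed post-transform site mean
    and the target; ``max_intra_site_distortion`` is the largest absolute
    change in any within-site pairwise distance, which must vanish whenever
    all ``λ_k = 1``.
    """

    method: HarmonizationMethod
    metric: MetricKind
    target: np.ndarray
    pre_site_means: dict[str, np.ndarray]
    post_site_means: dict[str, np.ndarray]
    lambdas: dict[str, float]
    site_mean_to_target: dict[str, float]
    max_intra_site_distortion: float
    frechet_converged: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable summary (matrices reduced to norms)."""
        return {
            "method": self.method.value,
            "metric": self.metric.value,
            "lambdas": self.lambdas,
            "site_mean_to_target": self.site_mean_to_target,
            "max_intra_site_distortion": self.max_intra_site_distortion,
            "frechet_converged": self.frechet_converged,
        }


# ---------------------------------------------------------------------------
# means

def site_means_lerm(cohort: Cohort) -> dict[str, np.ndarray]:
    """Per-site log-Euclidean Fréchet mean ``Exp(mean of within-site logs)``."""
    out = {}
    for k, mats in cohort.site_partition().items():
        if not mats:
            raise ValueError(f"site {k!r} is empty")
        out[k] = lerm_frechet_mean(mats)
    return out


def global_mean_lerm(site_means: Mapping[str, np.ndarray]) -> np.ndarray:
    """Global mean: LERM mean of the *site means* (sites weighted equally,
    regardless of how many subjects each contributes)."""
    if not site_means:
        raise ValueError("no site means given")
    return lerm_frechet_mean(list(site_means.values()))


def _site_means_airm(cohort: Cohort, config: FrechetConfig | None = None,
                     ) -> tuple[dict[str, np.ndarray], dict[str, bool]]:
    means, converged = {}, {}
    for k, mats in cohort.site_partition().items():
        if not mats:
            raise ValueError(f"site {k!r} is empty")
        res = airm_frechet_mean(mats, config)
        if not res.converged:
            logger.warning("AIRM Fréchet mean for site %s did not converge "
                           "(residual %.3e)", k, res.final_update_norm)
        means[k], converged[k] = res.mean, res.converged
    return means, converged


# ---------------------------------------------------------------------------
# report helper

def _intra_site_distortion(pre: Cohort, post: Cohort,
                           metric: MetricKind) -> float:
    worst = 0.0
    for k in pre.sites:
        a = pre.matrices(site=k)
        b = post.matrices(site=k)
        for i in range(len(a)):
            for j in range(i + 1, len(a)):
                worst = max(worst, abs(distance(a[i], a[j], metric)
                                       - distance(b[i], b[j], metric)))
    return worst


def _build_report(method: HarmonizationMethod, metric: MetricKind,
                  target: np.ndarray, pre: Cohort, post: Cohort,
                  pre_means: dict[str, np.ndarray],
                  lambdas: dict[str, float],
                  converged: dict[str, bool],
                  compute_distortion: bool) -> HarmonizationReport:
    post_means: dict[str, np.ndarray] = {}
    dist_to_target: dict[str, float] = {}
    for k, mats in post.site_partition().items():
        if metric is MetricKind.AIRM:
            post_means[k] = airm_frechet_mean(mats).mean
        else:
            post_means[k] = lerm_frechet_mean(mats)
        dist_to_target[k] = distance(post_means[k], target, metric)
    distortion = (_intra_site_distortion(pre, post, metric)
                  if compute_distortion else float("nan"))
    return HarmonizationReport(
        method=method, metric=metric, target=target,
        pre_site_means=pre_means, post_site_means=post_means,
        lambdas=lambdas, site_mean_to_target=dist_to_target,
        max_intra_site_distortion=distortion, frechet_converged=converged)


# ---------------------------------------------------------------------------
# matrix whitening

def whiten(cohort: Cohort, frechet_config: FrechetConfig | None = None,
           compute_report: bool = True,
           ) -> tuple[Cohort, HarmonizationReport | None]:
    """Whitening at identity: ``S_i -> Sbar_k^{-1/2} S_i Sbar_k^{-1/2}``.

    ``Sbar_k`` is the site's AIRM Fréchet mean. By affine invariance all
    within-site AIRM distances are preserved, and by equivariance every
    site mean lands exactly on the identity.
    """
    pre_means, converged = _site_means_airm(cohort, frechet_config)
    inv_sqrts = {k: matrix_inv_sqrt(m) for k, m in pre_means.items()}
    new = [symmetrize(inv_sqrts[s.site] @ s.matrix @ inv_sqrts[s.site])
           for s in cohort.subjects]
    out = cohort.with_matrices(new)
    report = None
    if compute_report:
        target = np.eye(cohort.dim)
        lambdas = {k: 1.0 for k in pre_means}
        report = _build_report(HarmonizationMethod.MW, MetricKind.AIRM,
                               target, cohort, out, pre_means, lambdas,
                               converged, compute_distortion=True)
    return out, report


# ---------------------------------------------------------------------------
# parallel transport

def transport_to_reference(
    site_matrices: Sequence[np.ndarray],
    site_mean: np.ndarray,
    reference: np.ndarray,
    check_tol: float = 1e-8,
) -> list[np.ndarray]:
    """Transport a site's matrices to a reference point along the geodesic.

    Applies ``S_i -> C S_i C^T`` with ``C`` the principal square root of
    ``reference @ site_mean^{-1}``. That product is not symmetric, but it is
    similar to the SPD matrix ``A^{1/2} B^{-1} A^{1/2}`` (``A`` = reference,
    ``B`` = site mean), so the principal root is computed stably as
    ``C = A^{1/2} (A^{1/2} B^{-1} A^{1/2})^{1/2} A^{-1/2}``. The contract
    ``C B C^T = reference`` is verified post hoc.
    """
    A = np.asarray(reference, dtype=float)
    B = np.asarray(site_mean, dtype=float)
    A_half = matrix_sqrt(A)
    A_neg_half = matrix_inv_sqrt(A)
    B_inv = matrix_inv_sqrt(B) @ matrix_inv_sqrt(B)
    inner = matrix_sqrt(symmetrize(A_half @ B_inv @ A_half))
    C = A_half @ inner @ A_neg_half
    relocated = C @ B @ C.T
    err = float(np.linalg.norm(relocated - A))
    if err > check_tol * max(1.0, float(np.linalg.norm(A))):
        raise ArithmeticError(
            f"parallel transport postcondition failed: ||C B C^T - ref|| = {err:.3e}")
    return [symmetrize(C @ np.asarray(M, dtype=float) @ C.T)
            for M in site_matrices]


def pt_harmonize(cohort: Cohort, frechet_config: FrechetConfig | None = None,
                 compute_report: bool = True,
                 ) -> tuple[Cohort, HarmonizationReport | None]:
    """Composite parallel-transport harmonization.

    Every site is transported to the common reference ``S0 = Sbar`` (the
    AIRM Fréchet mean of the AIRM site means), then the pooled cohort is
    whitened by ``Sbar``. Each site's mean therefore ends at the identity,
    and within-site AIRM distances are untouched (both steps are
    congruences). For a single-site cohort the composite collapses
    algebraically to whitening that site.
    """
    pre_means, converged = _site_means_airm(cohort, frechet_config)
    global_res = airm_frechet_mean(list(pre_means.values()), frechet_config)
    Sbar = global_res.mean
    converged["__global__"] = global_res.converged
    Sbar_inv_half = matrix_inv_sqrt(Sbar)

    transported: dict[str, list[np.ndarray]] = {}
    for k in cohort.sites:
        transported[k] = transport_to_reference(
            cohort.matrices(site=k), pre_means[k], Sbar)
    new = []
    per_site_iter = {k: iter(v) for k, v in transported.items()}
    for s in cohort.subjects:
        T = next(per_site_iter[s.site])
        new.append(symmetrize(Sbar_inv_half @ T @ Sbar_inv_half))
    out = cohort.with_matrices(new)
    report = None
    if compute_report:
        target = np.eye(cohort.dim)
        lambdas = {k: 1.0 for k in pre_means}
        report = _build_report(HarmonizationMethod.PT, MetricKind.AIRM,
                               target, cohort, out, pre_means, lambdas,
                               converged, compute_distortion=True)
    return out, report


# ---------------------------------------------------------------------------
# rigid log-Euclidean translation

def rlet(
    cohort: Cohort,
    target: str = "global_mean",
    lambdas: Mapping[str, float] | None = None,
    compute_report: bool = True,
) -> tuple[Cohort, HarmonizationReport | None]:
    """Rigid log-Euclidean translation of a cohort.

    In log space every subject is mapped by
    ``L_i -> target_log + λ_k (L_i - Lbar_k)`` where ``Lbar_k`` is the
    site's log-mean and ``target_log`` is the global log-mean
    (``target="global_mean"``) or zero (``target="identity"``). With all
    ``λ_k = 1`` this is a rigid translation — an exact isometry of the
    log-Euclidean metric — and the two targets yield point sets with
    identical pairwise distances.
    """
    if target not in ("global_mean", "identity"):
        raise ValueError("target must be 'global_mean' or 'identity'")
    sites = cohort.sites
    if lambdas is None:
        lambdas = {k: 1.0 for k in sites}
    else:
        lambdas = dict(lambdas)
        missing = set(sites) - set(lambdas)
        if missing:
            raise ValueError(f"missing λ for sites {sorted(missing)}")
    if any(v <= 0 for v in lambdas.values()):
        raise ValueError("all λ must be positive")

    logs = {s.subject_id: matrix_log(s.matrix) for s in cohort.subjects}
    site_log_means = {}
    for k in sites:
        member_logs = [logs[s.subject_id] for s in cohort.subjects
                       if s.site == k]
        if not member_logs:
            raise ValueError(f"site {k!r} is empty")
        site_log_means[k] = np.mean(member_logs, axis=0)
    global_log_mean = np.mean(list(site_log_means.values()), axis=0)
    target_log = (global_log_mean if target == "global_mean"
                  else np.zeros_like(global_log_mean))

    new = [matrix_exp(target_log + lambdas[s.site]
                      * (logs[s.subject_id] - site_log_means[s.site]))
           for s in cohort.subjects]
    out = cohort.with_matrices(new)
    report = None
    if compute_report:
        rescaled = any(abs(v - 1.0) > 0 for v in lambdas.values())
        method = (HarmonizationMethod.RLET_RESCALED if rescaled
                  else HarmonizationMethod.RLET_GLOBAL
                  if target == "global_mean"
                  else HarmonizationMethod.RLET_IDENTITY)
        pre_means = {k: matrix_exp(m) for k, m in site_log_means.items()}
        report = _build_report(method, MetricKind.LERM,
                               matrix_exp(target_log), cohort, out,
                               pre_means, dict(lambdas),
                               {k: True for k in sites},
                               compute_distortion=not rescaled)
    return out, report


def compute_lambda(cohort: Cohort,
                   metric: MetricKind | str = MetricKind.LERM,
                   ) -> dict[str, float]:
    """Site rescaling factors that equalize mean intra-site dispersion.

    ``λ_k`` is the ratio between the across-site average of mean intra-site
    pairwise distances and site ``k``'s own mean intra-site pairwise
    distance (means over unordered within-site pairs). Applying
    λ-rescaled RLET with these factors makes every site's mean intra-site
    distance equal to the across-site average.
    """
    metric = MetricKind(metric)
    site_mean_dist: dict[str, float] = {}
    for k, mats in cohort.site_partition().items():
        if len(mats) < 2:
            raise ValueError(
                f"site {k!r} has fewer than 2 subjects; mean intra-site "
                "distance is undefined")
        dists = [distance(mats[i], mats[j], metric)
                 for i in range(len(mats)) for j in range(i + 1, len(mats))]
        site_mean_dist[k] = float(np.mean(dists))
    grand = float(np.mean(list(site_mean_dist.values())))
    return {k: grand / m for k, m in site_mean_dist.items()}


# ---------------------------------------------------------------------------
# dispatch

def harmonize(
    cohort: Cohort,
    method: HarmonizationMethod | str,
    lambdas: Mapping[str, float] | str | None = None,
    frechet_config: FrechetConfig | None = None,
    compute_report: bool = True,
) -> tuple[Cohort, HarmonizationReport | None]:
    """Run one harmonization method by name.

    ``lambdas="auto"`` (RLET_RESCALED only) computes the dispersion-
    equalizing factors from the cohort itself.
    """
    method = HarmonizationMethod(method)
    if method is HarmonizationMethod.MW:
        return whiten(cohort, frechet_config, compute_report)
    if method is HarmonizationMethod.PT:
        return pt_harmonize(cohort, frechet_config, compute_report)
    if method is HarmonizationMethod.RLET_GLOBAL:
        return rlet(cohort, "global_mean", None, compute_report)
    if method is HarmonizationMethod.RLET_IDENTITY:
        return rlet(cohort, "identity", None, compute_report)
    # RLET_RESCALED
    if lambdas == "auto" or lambdas is None:
        lambdas = compute_lambda(cohort)
    return rlet(cohort, "global_mean", lambdas, compute_report)
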