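"""Cohort container, readers/writers, pairwise distances and 2-D embedding.

A *cohort* is an ordered collection of subjects, each carrying an SPD
functional-connectivity matrix, a site label (which scanner / acquisition
center produced it) and a condition label (patient ``plus`` vs control
``minus``, or ``unknown``). On disk a cohort is a TSV manifest
(``subject_id  site  condition  path``) pointing at one delimited-text
matrix file per subject; a single stacked ``.npz`` container is supported
as an alternative for large cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spd_core import (
    MetricKind,
    matrix_inv_sqrt,
    matrix_log,
    symmetrize,
    validate_spd,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Subject",
    "Cohort",
    "load_cohort",
    "save_cohort",
    "load_cohort_npz",
    "save_cohort_npz",
    "pairwise_distances",
    "block_summary",
    "log_vectorize",
    "embed_2d",
]

CONDITIONS = ("plus", "minus", "unknown")
_COND_RANK = {c: i for i, c in enumerate(CONDITIONS)}


@dataclass(frozen=True)
class Subject:
    subject_id: str
    site: str
    condition: str  # plus | minus | unknown
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class Cohort:
    """Ordered multi-site collection of subjects with SPD matrices."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        if self.subjects:
            n = self.dim
            for s in self.subjects:
                if s.matrix.shape != (n, n):
                    raise ValueError(
                        f"subject {s.subject_id!r}: matrix shape "
                        f"{s.matrix.shape} != ({n}, {n})"
                    )
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def dim(self) -> int:
        return self.subjects[0].matrix.shape[0]

    @property
    def sites(self) -> list[str]:
        """Site labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s.site, None)
        return list(seen)

    def matrices(self, site: str | None = None,
                 condition: str | None = None) -> list[np.ndarray]:
        return [s.matrix for s in self.subjects
                if (site is None or s.site == site)
                and (condition is None or s.condition == condition)]

    def site_partition(self) -> dict[str, list[np.ndarray]]:
        return {k: self.matrices(site=k) for k in self.sites}

    def condition_partition(self) -> dict[str, list[np.ndarray]]:
        return {c: self.matrices(condition=c) for c in ("plus", "minus")}

    def with_matrices(self, new_matrices: Sequence[np.ndarray]) -> "Cohort":
        """Copy of the cohort with matrices replaced, labels kept."""
        if len(new_matrices) != len(self.subjects):
            raise ValueError("matrix count must match subject count")
        return Cohort([replace(s, matrix=np.asarray(M, dtype=float))
                       for s, M in zip(self.subjects, new_matrices)])

    def sorted_for_distances(self) -> "Cohort":
        """Deterministic ordering: site block, condition, original order."""
        site_rank = {k: i for i, k in enumerate(self.sites)}
        order = sorted(
            range(len(self.subjects)),
            key=lambda i: (site_rank[self.subjects[i].site],
                           _COND_RANK[self.subjects[i].condition], i),
        )
        return Cohort([self.subjects[i] for i in order])


# ---------------------------------------------------------------------------
# manifest + matrix-file round trip

def load_cohort(
    manifest_path: str | Path,
    sym_tol: float = 1e-8,
    pd_tol: float = 1e-10,
    eig_floor: float | None = None,
) -> Cohort:
    """Read a manifest TSV and the matrix files it references.

    Every matrix is validated as SPD; errors name the offending subject.
    Subjects are grouped into site blocks (sites in first-appearance order)
    while preserving manifest order within each site.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str, comment="#")
    required = {"subject_id", "site", "condition", "path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
        )
    subjects: list[Subject] = []
    dim: int | None = None
    for row in df.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise FileNotFoundError(
                f"subject {row.subject_id!r}: matrix file {path} not found")
        M = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
        M = np.atleast_2d(M)
        if dim is None:
            dim = M.shape[0]
        elif M.shape != (dim, dim):
            raise ValueError(
                f"subject {row.subject_id!r}: matrix shape {M.shape} does not "
                f"match cohort dimension {dim}")
        try:
            M = validate_spd(M, sym_tol=sym_tol, pd_tol=pd_tol,
                             eig_floor=eig_floor)
        except ValueError as exc:
            raise ValueError(f"subject {row.subject_id!r}: {exc}") from exc
        subjects.append(Subject(str(row.subject_id), str(row.site),
                                str(row.condition), M))
    cohort = Cohort(subjects)
    # group into site blocks, manifest order within each block
    site_rank = {k: i for i, k in enumerate(cohort.sites)}
    order = sorted(range(len(subjects)),
                   key=lambda i: (site_rank[subjects[i].site], i))
    return Cohort([subjects[i] for i in order])


def save_cohort(cohort: Cohort, out_dir: str | Path,
                precision: int = 17) -> Path:
    """Write matrices as whitespace-delimited text plus a manifest TSV.

    Returns the manifest path. ``precision=17`` round-trips float64 exactly
    to ~1e-16; lower values trade file size for precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.txt"
        np.savetxt(out_dir / fname, s.matrix, fmt=f"%.{precision}g")
        rows.append((s.subject_id, s.site, s.condition, fname))
    manifest = pd.DataFrame(rows,
                            columns=["subject_id", "site", "condition", "path"])
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def save_cohort_npz(cohort: Cohort, path: str | Path) -> Path:
    """Single stacked container for large cohorts (binary, scratch use)."""
    path = Path(path)
    np.savez_compressed(
        path,
        matrices=np.asarray([s.matrix for s in cohort.subjects]),
        subject_id=np.asarray([s.subject_id for s in cohort.subjects]),
        site=np.asarray([s.site for s in cohort.subjects]),
        condition=np.asarray([s.condition for s in cohort.subjects]),
    )
    return path


def load_cohort_npz(path: str | Path) -> Cohort:
    with np.load(path, allow_pickle=False) as data:
        subjects = [
            Subject(str(i), str(k), str(c), validate_spd(M))
            for i, k, c, M in zip(data["subject_id"], data["site"],
                                  data["condition"], data["matrices"])
        ]
    return Cohort(subjects)


# ---------------------------------------------------------------------------
# pairwise distances

def pairwise_distances(
    cohort: Cohort,
    metric: MetricKind | str = MetricKind.AIRM,
    sort: bool = True,
) -> tuple[np.ndarray, Cohort]:
    """Pairwise geodesic distance matrix ``D_ij = d(S_i, S_j)``.

    Returns ``(D, ordered_cohort)`` where the ordering is the deterministic
    site-block / condition / original order (unless ``sort=False``).
    For LERM the matrix logs are computed once and distances reduce to
    Euclidean norms; for AIRM each pair costs one generalized
    eigendecomposition, accelerated by precomputed inverse square roots.
    """
    metric = MetricKind(metric)
    ordered = cohort.sorted_for_distances() if sort else cohort
    mats = [s.matrix for s in ordered.subjects]
    N = len(mats)
    D = np.zeros((N, N))
    if metric is MetricKind.LERM:
        logs = np.asarray([matrix_log(M) for M in mats]).reshape(N, -1)
        # ||x_i - x_j|| via the Gram expansion, then clean up round-off
        sq = np.sum(logs ** 2, axis=1)
        G = logs @ logs.T
        D2 = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
        D = np.sqrt(D2)
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2
    else:
        inv_sqrts = [matrix_inv_sqrt(M) for M in mats]
        for i in range(N):
            for j in range(i + 1, N):
                W = inv_sqrts[i] @ mats[j] @ inv_sqrts[i]
                w = np.linalg.eigvalsh(symmetrize(W))
                d = float(np.sqrt(np.sum(np.log(np.maximum(w, 1e-300)) ** 2)))
                D[i, j] = D[j, i] = d
    return D, ordered


def block_summary(D: np.ndarray, ordered: Cohort) -> pd.DataFrame:
    """Mean intra-/inter-site distances from a pairwise distance matrix.

    One row per ordered site pair ``(a, b)``; ``a == b`` rows are the mean
    over unordered within-site pairs.
    """
    sites = np.asarray([s.site for s in ordered.subjects])
    labels = ordered.sites
    rows = []
    for a in labels:
        ia = np.where(sites == a)[0]
        for b in labels:
            ib = np.where(sites == b)[0]
            if a == b:
                if len(ia) < 2:
                    continue
                iu, ju = np.triu_indices(len(ia), k=1)
                vals = D[np.ix_(ia, ia)][iu, ju]
            else:
                vals = D[np.ix_(ia, ib)].ravel()
            rows.append((a, b, "intra" if a == b else "inter",
                         float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["site_a", "site_b", "kind",
                                       "mean_distance", "n_pairs"])


# ---------------------------------------------------------------------------
# 2-D embedding of log-matrices

def log_vectorize(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Vectorize matrix logs: upper triangle, off-diagonal scaled by sqrt(2).

    With this weighting the Euclidean distance between two vectors equals
    the LERM geodesic distance between the matrices, in dimension
    ``n(n+1)/2`` instead of ``n^2``.
    """
    n = np.asarray(matrices[0]).shape[0]
    iu, ju = np.triu_indices(n)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return np.asarray([matrix_log(M)[iu, ju] * weights for M in matrices])


def embed_2d(cohort: Cohort, perplexity: float = 30.0,
             seed: int = 0) -> np.ndarray:
    """t-SNE embedding of vectorized matrix logarithms.

    Because the inputs are the √2-weighted upper-triangle log vectors, the
    similarity the embedding sees is exactly the LERM geodesic distance.
    Returns an ``N x 2`` coordinate array in cohort order.
    """
    from sklearn.manifold import TSNE

    N = len(cohort)
    if N < 5:
        raise ValueError("embedding needs at least 5 subjects")
    X = log_vectorize([s.matrix for s in cohort.subjects])
    perplexity = min(perplexity, (N - 1) / 3)
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                init="pca")
    return tsne.fit_transform(X)
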