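"""Distances, clustering and multivariate tests on presence/absence profiles.

Binary profiles are compared with either the Jaccard distance (joint
absences uninformative) or the binary Euclidean distance (square root of
the Hamming mismatch count).  On top of these sit Ward agglomerative
clustering, principal components of the centered binary matrix (which
reproduce the binary-Euclidean geometry exactly), a logistic PCA that
factorizes the Bernoulli natural-parameter matrix, and a PERMANOVA
pseudo-F permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .group_stats import TestResult, fisher_exact_2x2, kendall_tau_b
from .screening import PresenceMatrix

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "ClusterResult",
    "PermanovaResult",
    "distance_matrix",
    "ward_cluster",
    "cluster_source_table",
    "pca_binary",
    "logistic_pca",
    "permanova",
    "axis_quality_correlation",
]


@dataclass
class DistanceMatrix:
    """A symmetric pairwise distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class OrdinationResult:
    """Sample scores on ordered ordination axes."""

    ids: list[str]
    coordinates: np.ndarray  # n x k
    explained_variance_fraction: np.ndarray
    method: str
    objective_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if evf.size > 1 and not np.all(np.diff(evf) <= 1e-9):
            raise ValueError("axes must be ordered by decreasing explained variance")
        if evf.sum() > 1.0 + 1e-9:
            raise ValueError("explained variance fractions must sum to <= 1")


@dataclass
class ClusterResult:
    """Agglomerative merge tree and flat labels obtained by cutting it."""

    ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, heights non-decreasing
    labels_at_k: dict[int, np.ndarray] = field(default_factory=dict)

    def labels(self, k: int) -> np.ndarray:
        if k not in self.labels_at_k:
            self.labels_at_k[k] = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return self.labels_at_k[k]


@dataclass
class PermanovaResult:
    """PERMANOVA pseudo-F and its permutation p-value."""

    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_F,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(matrix: PresenceMatrix, metric: str) -> DistanceMatrix:
    """Pairwise distances between binary presence profiles.

    ``jaccard_binary``: ``1 - a / (a + b + c)`` with ``a`` shared presences
    and ``b``, ``c`` the mismatches; a pair of all-zero profiles has an
    empty union and is assigned distance 0 by convention (with a warning).
    ``euclidean_binary``: square root of the Hamming mismatch count.
    """
    if matrix.n_genomes < 2:
        raise ValueError("need >= 2 genomes for a distance matrix")
    x = matrix.cells.astype(np.float64)
    inter = x @ x.T
    row = np.diag(inter).copy()
    mismatch = row[:, None] + row[None, :] - 2.0 * inter
    if metric == "euclidean_binary":
        d = np.sqrt(np.maximum(mismatch, 0.0))
    elif metric == "jaccard_binary":
        union = row[:, None] + row[None, :] - inter
        empty = union == 0
        if (empty & ~np.eye(matrix.n_genomes, dtype=bool)).any():
            warnings.warn(
                "pair(s) of all-zero profiles: Jaccard distance set to 0 "
                "by convention",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(empty, 0.0, mismatch / np.where(empty, 1.0, union))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(ids=list(matrix.genome_ids), values=d, metric=metric)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def ward_cluster(dist: DistanceMatrix, k: int) -> ClusterResult:
    """Ward minimal-variance agglomeration of a distance matrix.

    Uses the Lance-Williams Ward update on the input distances (the
    "Ward.D2" convention: heights are monotone non-decreasing).  Flat
    labels are obtained by cutting the tree into ``k`` clusters.  With a
    non-Euclidean input such as Jaccard the procedure is heuristic rather
    than variance-exact, matching common practice.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dist.n:
        raise ValueError(f"k={k} exceeds number of samples {dist.n}")
    z = sch.linkage(dist.condensed(), method="ward")
    result = ClusterResult(ids=list(dist.ids), linkage=z)
    result.labels(k)
    return result


def cluster_source_table(
    labels: np.ndarray, source_groups: Sequence[str]
) -> np.ndarray:
    """2x2 contingency of cluster membership (k=2) against genome source."""
    labels = np.asarray(labels)
    groups = np.asarray([str(g) for g in source_groups])
    ulab = np.unique(labels)
    ugrp = np.unique(groups)
    if len(ulab) != 2 or len(ugrp) != 2:
        raise ValueError(
            f"need exactly 2 clusters and 2 source groups, got "
            f"{len(ulab)} and {len(ugrp)}"
        )
    table = np.array(
        [
            [int(((labels == l) & (groups == g)).sum()) for g in ugrp]
            for l in ulab
        ]
    )
    if (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate clustering: an empty cluster")
    return table


# ---------------------------------------------------------------------------
# linear PCA on the centered binary matrix
# ---------------------------------------------------------------------------

def pca_binary(matrix: PresenceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal components of the column-centered (unscaled) binary matrix.

    Because centering preserves pairwise differences, Euclidean distances
    among the full set of scores equal the binary-Euclidean distances of
    the raw profiles exactly.  Axis signs follow the convention that each
    axis's largest-magnitude loading is positive.
    """
    if matrix.n_genomes < 2 or matrix.n_keys < 2:
        raise ValueError("need >= 2 genomes and >= 2 keys for PCA")
    x = matrix.cells.astype(np.float64)
    xc = x - x.mean(axis=0, keepdims=True)
    if np.allclose(xc, 0.0):
        raise ValueError("constant presence matrix has zero variance")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for j in range(s.size):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    k = min(n_axes, s.size)
    scores = u * s
    evf = s**2 / float((s**2).sum())
    return OrdinationResult(
        ids=list(matrix.genome_ids),
        coordinates=scores[:, :k],
        explained_variance_fraction=evf[:k],
        method="pca_binary_centered",
    )


# ---------------------------------------------------------------------------
# logistic PCA
# ---------------------------------------------------------------------------

def _bernoulli_nll(theta: np.ndarray, x: np.ndarray) -> float:
    return float(np.logaddexp(0.0, theta).sum() - (x * theta).sum())


def logistic_pca(
    matrix: PresenceMatrix,
    rank: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    init: str = "svd",
) -> OrdinationResult:
    """Low-rank Bernoulli factorization of a binary matrix.

    Fits natural parameters ``Theta = mu + U V^T`` (per-feature offset plus
    a rank-``rank`` interaction) minimizing the Bernoulli negative
    log-likelihood by majorization-minimization: the logistic loss is
    bounded by a quadratic with curvature 1/4, so each iteration forms the
    working response ``Z = Theta + 4 (X - sigmoid(Theta))`` and projects it
    onto the offset-plus-low-rank set by a truncated SVD.  The objective is
    therefore non-increasing at every step; iteration stops when its
    relative change drops below ``tol``.  Deterministic; ``seed`` is used
    only for ``init="random"``.
    """
    x = matrix.cells.astype(np.float64)
    if not np.isin(matrix.cells, (0, 1)).all():
        raise ValueError("logistic PCA requires a binary matrix")
    n, p = x.shape
    if rank < 1 or rank >= min(n, p):
        raise ValueError(f"rank must be in [1, {min(n, p) - 1}]")
    colmean = np.clip(x.mean(axis=0), 1e-3, 1 - 1e-3)
    mu = np.log(colmean / (1 - colmean))
    if init == "svd":
        u0, s0, vt0 = np.linalg.svd(x - x.mean(axis=0, keepdims=True), full_matrices=False)
        low = 4.0 * (u0[:, :rank] * s0[:rank]) @ vt0[:rank]
    elif init == "random":
        rng = np.random.default_rng(seed)
        low = 0.1 * rng.standard_normal((n, p))
        u0, s0, vt0 = np.linalg.svd(low, full_matrices=False)
        low = (u0[:, :rank] * s0[:rank]) @ vt0[:rank]
    else:
        raise ValueError(f"unknown init {init!r}")
    theta = mu[None, :] + low
    trace = [_bernoulli_nll(theta, x)]
    for _ in range(max_iter):
        prob = 1.0 / (1.0 + np.exp(-theta))
        z = theta + 4.0 * (x - prob)
        mu = z.mean(axis=0)
        u, s, vt = np.linalg.svd(z - mu[None, :], full_matrices=False)
        theta = mu[None, :] + (u[:, :rank] * s[:rank]) @ vt[:rank]
        obj = _bernoulli_nll(theta, x)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(1.0, abs(trace[-2])):
            break
    u, s, vt = np.linalg.svd(theta - theta.mean(axis=0, keepdims=True), full_matrices=False)
    for j in range(rank):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = (u * s)[:, :rank]
    total = float((s**2).sum())
    evf = (s[:rank] ** 2 / total) if total > 0 else np.zeros(rank)
    return OrdinationResult(
        ids=list(matrix.genome_ids),
        coordinates=scores,
        explained_variance_fraction=evf,
        method="logistic_pca_mm",
        objective_trace=np.asarray(trace),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _ss_terms(d2: np.ndarray, membership: np.ndarray, sizes: np.ndarray) -> float:
    """Within-group sum of squares for one or many label permutations.

    ``membership`` is (n_groups, N, B) one-hot over B permutations.
    """
    ss_w = np.zeros(membership.shape[2])
    for g in range(membership.shape[0]):
        u = membership[g]  # N x B
        ss_w += np.einsum("ib,ib->b", u, d2 @ u) / (2.0 * sizes[g])
    return ss_w


def permanova(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    all_permutations: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F ratio with a label-permutation p-value.

    ``SS_total = sum_{i<j} d_ij^2 / N``, ``SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2``, ``pseudo-F = (SS_between/(g-1)) /
    (SS_within/(N-g))``; ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)``.  With ``all_permutations`` every labeling of
    the index vector is enumerated (exact p; feasible for small N only).
    """
    groups = np.asarray([str(g) for g in groups])
    n = dist.n
    if groups.shape[0] != n:
        raise ValueError("groups must match distance matrix ids")
    ugrp, inv = np.unique(groups, return_inverse=True)
    g = len(ugrp)
    if g < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(inv)
    if (sizes < 2).any():
        raise ValueError("every group must have >= 2 members")
    if not all_permutations and n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    d2 = dist.values**2
    ss_total = float(d2.sum()) / (2.0 * n)

    def f_of(label_idx: np.ndarray) -> np.ndarray:
        # label_idx: B x N integer group indices
        b = label_idx.shape[0]
        member = np.stack(
            [(label_idx == gi).T.astype(float) for gi in range(g)]
        )  # g x N x B
        ss_w = _ss_terms(d2, member, sizes)
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_b / (g - 1)) / (ss_w / (n - g))

    f_obs = float(f_of(inv[None, :])[0])
    if not math.isfinite(f_obs):
        warnings.warn(
            "zero within-group sum of squares: pseudo-F infinite, p set to "
            "its minimum attainable value",
            stacklevel=2,
        )
        if all_permutations:
            perms = np.array(list(itertools.permutations(range(n))))
            return PermanovaResult(math.inf, 1.0 / len(perms), len(perms) - 1, seed)
        return PermanovaResult(
            math.inf, 1.0 / (n_permutations + 1), n_permutations, seed
        )
    if all_permutations:
        perms = np.array(list(itertools.permutations(range(n))))
        f_perm = f_of(inv[perms])
        p = float((f_perm >= f_obs - 1e-12).sum()) / len(perms)
        n_used = len(perms) - 1
    else:
        rng = np.random.default_rng(seed)
        perm_idx = np.stack([rng.permutation(n) for _ in range(n_permutations)])
        f_perm = f_of(inv[perm_idx])
        p = (1.0 + float((f_perm >= f_obs - 1e-12).sum())) / (1.0 + n_permutations)
        n_used = n_permutations
    return PermanovaResult(f_obs, p, n_used, seed)


def axis_quality_correlation(
    ordination: OrdinationResult,
    axis: int,
    quality: Mapping[str, float],
) -> TestResult:
    """Kendall tau-b between one ordination axis and completeness scores."""
    if axis < 0 or axis >= ordination.coordinates.shape[1]:
        raise ValueError(f"axis {axis} out of range")
    pairs = [
        (ordination.coordinates[i, axis], quality[gid])
        for i, gid in enumerate(ordination.ids)
        if gid in quality
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 genomes with a completeness score")
    scores, comp = map(np.asarray, zip(*pairs))
    return kendall_tau_b(scores, comp)
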