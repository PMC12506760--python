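"""Multivariate shape statistics on normalized Fourier coefficients.

The shape pipeline: PCA of the NEF coefficient vectors (covariance
matrix, no per-variable standardization — the coefficients share units),
retention of the leading components covering a set fraction of variance
(default 99%), canonical discriminant analysis in the retained space,
pairwise Mahalanobis distances with label-permutation significance and a
Bonferroni correction, leave-one-out reclassification, per-group mean
shapes, and UPGMA dendrograms of the group distance matrix.

Distances are Mahalanobis D (not D^2): for group means mu_i, mu_j and
pooled within-group covariance W,

    D(i, j) = sqrt((mu_i - mu_j)^T W^{-1} (mu_i - mu_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import InputValidationError, NumericalError
from .size_stats import ClassificationReport

__all__ = [
    "PCASpace",
    "DiscriminantModel",
    "DistanceResult",
    "UPGMATree",
    "pca",
    "fit_da",
    "mahalanobis_matrix",
    "permutation_test_distances",
    "jackknife_shape_classification",
    "mean_shapes",
    "upgma",
]


@dataclass(frozen=True)
class PCASpace:
    loadings: np.ndarray  # (p, p) columns are eigenvectors
    eigenvalues: np.ndarray  # (p,) non-increasing
    scores: np.ndarray  # (N, p)
    mean: np.ndarray  # (p,)
    n_retained: int

    @property
    def variance_proportions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]


@dataclass(frozen=True)
class DiscriminantModel:
    groups: tuple[str, ...]
    group_means: np.ndarray  # (G, d) in retained-PC space
    pooled_cov: np.ndarray  # (d, d) W, denominator N - G
    axes: np.ndarray  # (d, n_axes) W-orthonormal canonical axes
    axis_eigenvalues: np.ndarray  # (n_axes,) non-increasing
    scores: np.ndarray  # (N, n_axes) canonical (DF) scores
    labels: np.ndarray  # (N,) group label per specimen

    @property
    def proportions(self) -> np.ndarray:
        """Share of discriminating variance per canonical axis."""
        return self.axis_eigenvalues / self.axis_eigenvalues.sum()


@dataclass(frozen=True)
class DistanceResult:
    groups: tuple[str, ...]
    distances: np.ndarray  # (G, G) symmetric, zero diagonal
    p_values: np.ndarray | None = None
    significant: np.ndarray | None = None  # Bonferroni-corrected flags
    replicates: int | None = None
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.distances, index=self.groups,
                          columns=self.groups)
        df.index.name = "group"
        return df


@dataclass(frozen=True)
class UPGMATree:
    """Rooted ultrametric dendrogram over group labels."""

    leaves: tuple[str, ...]  # input order
    newick: str
    merge_heights: tuple[float, ...]  # non-decreasing
    clusters: tuple[frozenset, ...]  # leaf set created at each merge


def pca(shapes: np.ndarray, retention: float = 0.99) -> PCASpace:
    """Principal components of the coefficient covariance matrix.

    ``n_retained`` is the smallest m whose cumulative variance
    proportion reaches ``retention``.
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputValidationError("need a 2-D matrix with >= 2 specimens")
    if not (0 < retention <= 1):
        raise InputValidationError("retention must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    total = np.trace(cov)
    if total <= 0:
        raise NumericalError("no variance: all shape vectors identical")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    cum = np.cumsum(evals) / evals.sum()
    n_retained = int(np.searchsorted(cum, retention - 1e-12)) + 1
    n_retained = min(n_retained, len(evals))
    return PCASpace(loadings=evecs, eigenvalues=evals, scores=Xc @ evecs,
                    mean=mean, n_retained=n_retained)


def _group_stats(X: np.ndarray, labels: np.ndarray, groups):
    means = np.stack([X[labels == g].mean(axis=0) for g in groups])
    N, d = X.shape
    G = len(groups)
    scatter = np.zeros((d, d))
    for i, g in enumerate(groups):
        Xg = X[labels == g] - means[i]
        scatter += Xg.T @ Xg
    W = scatter / (N - G)
    return means, W


def fit_da(p: PCASpace, groups) -> DiscriminantModel:
    """Canonical discriminant analysis in the retained-PC space.

    Solves the generalized eigenproblem B v = lambda W v with B the
    between-group covariance (denominator G - 1) and W the pooled
    within-group covariance (denominator N - G); axes are W-orthonormal,
    so canonical scores have pooled within-group variance 1.
    """
    labels = np.asarray(groups)
    X = p.retained_scores
    if len(labels) != X.shape[0]:
        raise InputValidationError("group labels do not match score rows")
    uniq = sorted(set(labels.tolist()))
    G = len(uniq)
    if G < 2:
        raise InputValidationError("need at least 2 groups")
    for g in uniq:
        if np.sum(labels == g) < 2:
            raise InputValidationError(f"group {g!r} has fewer than 2 specimens")
    N, d = X.shape
    if d >= N - G:
        raise NumericalError(
            f"retained dimension {d} >= N - G = {N - G}; lower the retention "
            "threshold"
        )
    means, W = _group_stats(X, labels, uniq)
    n_per = np.array([np.sum(labels == g) for g in uniq], dtype=float)
    grand = (n_per[:, None] * means).sum(axis=0) / n_per.sum()
    B = (n_per[:, None, None]
         * np.einsum("gi,gj->gij", means - grand, means - grand)).sum(axis=0)
    B /= (G - 1)
    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "singular pooled within-group covariance; lower the retention "
            "threshold"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(G - 1, d)
    axes = evecs[:, order[:n_axes]]
    axis_evals = np.clip(evals[order[:n_axes]], 0.0, None)
    for j in range(axes.shape[1]):
        k = np.argmax(np.abs(axes[:, j]))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
    scores = (X - grand) @ axes
    return DiscriminantModel(
        groups=tuple(uniq), group_means=means, pooled_cov=W, axes=axes,
        axis_eigenvalues=axis_evals, scores=scores, labels=labels,
    )


def _mahalanobis_from(means: np.ndarray, W: np.ndarray) -> np.ndarray:
    try:
        cho = linalg.cho_factor(W)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "singular pooled covariance; lower the retention threshold"
        ) from exc
    G = means.shape[0]
    D = np.zeros((G, G))
    for i in range(G):
        for j in range(i + 1, G):
            diff = means[i] - means[j]
            D[i, j] = D[j, i] = float(
                np.sqrt(diff @ linalg.cho_solve(cho, diff))
            )
    return D


def mahalanobis_matrix(m: DiscriminantModel) -> DistanceResult:
    """Pairwise Mahalanobis distances between group means under the
    pooled within-group covariance."""
    D = _mahalanobis_from(m.group_means, m.pooled_cov)
    return DistanceResult(groups=m.groups, distances=D)


def permutation_test_distances(
    shapes: np.ndarray,
    groups,
    R: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    retention: float = 0.99,
    bonferroni: bool = True,
) -> DistanceResult:
    """Mahalanobis distances with pairwise label-permutation p-values.

    For each pair only the two groups' labels are permuted (other groups
    keep their labels and their contribution to the pooled covariance);
    p = (1 + #{D_perm >= D_obs}) / (R + 1).  Significance flags apply a
    Bonferroni correction over the G(G-1)/2 pairs when requested.
    """
    if R < 1:
        raise InputValidationError(f"replicates must be >= 1, got {R}")
    if seed is None:
        raise InputValidationError("a seed is required for permutation tests")
    labels = np.asarray(groups)
    space = pca(shapes, retention=retention)
    model = fit_da(space, labels)
    uniq = list(model.groups)
    X = space.retained_scores
    G = len(uniq)
    D_obs = mahalanobis_matrix(model).distances
    n_pairs = G * (G - 1) // 2
    p = np.zeros((G, G))
    rng = np.random.default_rng(seed)
    others = {g: np.flatnonzero(labels == g) for g in uniq}
    for i in range(G):
        for j in range(i + 1, G):
            idx = np.concatenate([others[uniq[i]], others[uniq[j]]])
            ni = len(others[uniq[i]])
            count = 0
            lab_perm = labels.copy()
            for _ in range(R):
                perm = rng.permutation(idx)
                lab_perm[perm[:ni]] = uniq[i]
                lab_perm[perm[ni:]] = uniq[j]
                means, W = _group_stats(X, lab_perm, uniq)
                diff = means[i] - means[j]
                d = np.sqrt(diff @ np.linalg.solve(W, diff))
                if d >= D_obs[i, j] - 1e-12:
                    count += 1
            p[i, j] = p[j, i] = (1 + count) / (R + 1)
    np.fill_diagonal(p, 1.0)
    factor = n_pairs if bonferroni else 1
    significant = (p * factor) < alpha
    np.fill_diagonal(significant, False)
    return DistanceResult(groups=tuple(uniq), distances=D_obs, p_values=p,
                          significant=significant, replicates=R, seed=seed)


def jackknife_shape_classification(
    shapes: np.ndarray, groups, retention: float = 0.99
) -> ClassificationReport:
    """Leave-one-out reclassification by minimal Mahalanobis distance.

    The PCA basis is fit once on the full data and held fixed; for each
    held-out specimen the group means and pooled covariance are
    recomputed without it.  Ties break toward the lexicographically
    smaller group label.
    """
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    for g in uniq:
        if np.sum(labels == g) < 3:
            raise InputValidationError(
                f"group {g!r} needs n >= 3 for jackknife classification"
            )
    space = pca(shapes, retention=retention)
    X = space.retained_scores
    N, d = X.shape
    G = len(uniq)
    if d >= N - 1 - G:
        raise NumericalError(
            f"retained dimension {d} too large for leave-one-out with "
            f"N={N}, G={G}; lower the retention threshold"
        )
    index = {g: k for k, g in enumerate(uniq)}
    gi = np.array([index[g] for g in labels])
    sums = np.stack([X[gi == k].sum(axis=0) for k in range(G)])
    n_per = np.bincount(gi, minlength=G).astype(float)
    means_full = sums / n_per[:, None]
    scatter = np.zeros((d, d))
    for k in range(G):
        Xk = X[gi == k] - means_full[k]
        scatter += Xk.T @ Xk
    conf = np.zeros((G, G), dtype=int)
    for i in range(N):
        k0 = gi[i]
        xi = X[i]
        n_k = n_per[k0] - 1
        mu_k = (sums[k0] - xi) / n_k
        # remove specimen i from its group's scatter contribution
        diff_old = xi - means_full[k0]
        scatter_i = scatter - np.outer(diff_old, diff_old) * (
            n_per[k0] / (n_per[k0] - 1)
        )
        W = scatter_i / (N - 1 - G)
        try:
            cho = linalg.cho_factor(W)
        except linalg.LinAlgError as exc:
            raise NumericalError(
                "singular holdout covariance; lower the retention threshold"
            ) from exc
        best = None
        for k in range(G):
            mu = mu_k if k == k0 else means_full[k]
            delta = xi - mu
            d2 = float(delta @ linalg.cho_solve(cho, delta))
            key = (d2, uniq[k])
            if best is None or key < best:
                best = key
        conf[k0, index[best[1]]] += 1
    return ClassificationReport(
        groups=tuple(uniq),
        n_per_group=tuple(int(n) for n in n_per),
        confusion=conf,
    )


def mean_shapes(shapes: np.ndarray, groups) -> dict[str, np.ndarray]:
    """Arithmetic mean coefficient vector per group (input vector space)."""
    X = np.asarray(shapes, dtype=float)
    labels = np.asarray(groups)
    if len(labels) == 0:
        raise InputValidationError("empty group labels")
    return {g: X[labels == g].mean(axis=0) for g in sorted(set(labels.tolist()))}


def upgma(d: DistanceResult) -> UPGMATree:
    """Classic UPGMA (size-weighted average linkage) dendrogram.

    Merge heights are half the merge distance, so root-to-leaf path
    lengths are equal (ultrametric).  Ties break on the lexicographically
    smallest pair of cluster labels; Newick leaf order follows the input
    group order.
    """
    D = np.asarray(d.distances, dtype=float)
    G = len(d.groups)
    if D.shape != (G, G) or not np.allclose(D, D.T):
        raise InputValidationError("distance matrix must be square symmetric")
    if G < 2:
        raise InputValidationError("need at least 2 groups")
    # active clusters: id -> (newick, size, height, min_label, leafset, min_idx)
    active = {
        i: (str(d.groups[i]), 1, 0.0, str(d.groups[i]),
            frozenset([d.groups[i]]), i)
        for i in range(G)
    }
    dist = {(i, j): D[i, j] for i in range(G) for j in range(i + 1, G)}
    next_id = G
    heights: list[float] = []
    clusters: list[frozenset] = []
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for ai, i in enumerate(ids):
            for j in ids[ai + 1:]:
                dij = dist[(i, j) if i < j else (j, i)]
                pair_labels = tuple(sorted((active[i][3], active[j][3])))
                key = (dij, pair_labels)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist[(i, j) if i < j else (j, i)]
        h = dij / 2.0
        ni, nj = active[i][1], active[j][1]
        # children ordered by first appearance in the input group order
        kids = sorted([active[i], active[j]], key=lambda c: c[5])
        newick = "({}:{:.10g},{}:{:.10g})".format(
            kids[0][0], h - kids[0][2], kids[1][0], h - kids[1][2]
        )
        leafset = active[i][4] | active[j][4]
        heights.append(h)
        clusters.append(leafset)
        merged = (newick, ni + nj, h, min(active[i][3], active[j][3]),
                  leafset, min(active[i][5], active[j][5]))
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[(i, k) if i < k else (k, i)]
            djk = dist[(j, k) if j < k else (k, j)]
            dist[(k, next_id) if k < next_id else (next_id, k)] = (
                ni * dik + nj * djk
            ) / (ni + nj)
        del active[i], active[j]
        active[next_id] = merged
        next_id += 1
    root = next(iter(active.values()))
    return UPGMATree(
        leaves=tuple(str(g) for g in d.groups),
        newick=root[0] + ";",
        merge_heights=tuple(heights),
        clusters=tuple(clusters),
    )
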