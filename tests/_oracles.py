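"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: Fourier
coefficients by dense numerical quadrature, Mahalanobis by the direct
formula, UPGMA via scipy's average-linkage, one-way F via scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


def efa_oracle(points: np.ndarray, K: int, M: int = 200_000):
    """Fourier coefficients of the arc-length parameterisation of a
    closed polygon by trapezoidal quadrature on a dense grid (vertices
    included as nodes, so the only error is the smooth-part O(h^2))."""
    closed = np.vstack([points, points[:1]])
    seg = np.diff(closed, axis=0)
    dt = np.linalg.norm(seg, axis=1)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    s = np.union1d(np.linspace(0.0, T, M + 1), t)
    x = np.interp(s, t, closed[:, 0])
    y = np.interp(s, t, closed[:, 1])
    coeffs = np.empty((K, 4))
    for n in range(1, K + 1):
        cn = np.cos(2 * np.pi * n * s / T)
        sn = np.sin(2 * np.pi * n * s / T)
        coeffs[n - 1] = [
            2.0 / T * np.trapezoid(x * cn, s),
            2.0 / T * np.trapezoid(x * sn, s),
            2.0 / T * np.trapezoid(y * cn, s),
            2.0 / T * np.trapezoid(y * sn, s),
        ]
    A0 = float(np.trapezoid(x, s) / T)
    C0 = float(np.trapezoid(y, s) / T)
    return coeffs, A0, C0


def mahalanobis_oracle(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Direct-formula pairwise Mahalanobis distances with pooled
    within-group covariance (denominator N - G)."""
    uniq = sorted(set(labels.tolist()))
    G = len(uniq)
    N, d = X.shape
    means = np.stack([X[labels == g].mean(axis=0) for g in uniq])
    S = np.zeros((d, d))
    for i, g in enumerate(uniq):
        Xg = X[labels == g] - means[i]
        S += Xg.T @ Xg
    W = S / (N - G)
    Winv = np.linalg.inv(W)
    D = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            diff = means[i] - means[j]
            D[i, j] = np.sqrt(diff @ Winv @ diff)
    return D


def upgma_heights_oracle(D: np.ndarray) -> np.ndarray:
    """Sorted UPGMA merge heights (half the cophenetic merge distance)
    from scipy's average-linkage implementation."""
    Z = linkage(squareform(D, checks=False), method="average")
    return np.sort(Z[:, 2] / 2.0)


def star_polygon(rng: np.random.Generator, V: int = 64,
                 radial_spread: float = 0.35) -> np.ndarray:
    """Random star-shaped polygon around the origin, counter-clockwise.

    Angles are sorted uniform draws (distinct a.s.), radii independent
    in [1 - spread, 1 + spread]; these polygons are generic (elliptic
    first harmonic), exercising every branch of the normalization.
    """
    ang = np.sort(rng.uniform(0.0, 2.0 * np.pi, V))
    r = rng.uniform(1.0 - radial_spread, 1.0 + radial_spread, V)
    return np.c_[r * np.cos(ang), r * np.sin(ang)]
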