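"""Elliptic Fourier analysis (EFA) of closed contours.

A closed outline traced by arc length t in [0, T) decomposes into
harmonics n = 1..K, each contributing four coefficients::

    x(t) = A0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

For a polygonal contour the parameterisation is piecewise linear in t,
and the Fourier integrals have the exact closed form used here (the
classical chain-code/polygon EFA sums).  No resampling is performed:
the unequal-spacing sums are exact for polygons.

Normalized (NEF) coefficients are made invariant to size, rotation,
orientation and starting point using the first harmonic ellipse: the
start-point phase theta rotates harmonic n by n*theta, the ellipse
orientation psi is rotated away, and all coefficients are divided by the
semi-major axis length E.  After normalization a1'' = 1 and
b1'' = c1'' = 0 identically, so the shape vector keeps only d1'' (the
signed width-to-length ratio of the first ellipse) followed by the four
coefficients of each higher harmonic — 4K - 3 numbers in total.

Half the major axis of the first harmonic ellipse (E, in mm) is the
global size variable of the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputValidationError, NumericalError
from .io_contours import Contour

__all__ = [
    "EFACoefficients",
    "FirstEllipse",
    "NormalizedShape",
    "compute_efa",
    "first_ellipse",
    "size_of",
    "normalize",
    "reconstruct",
    "harmonic_power",
    "choose_harmonics",
    "max_harmonics",
]


@dataclass(frozen=True)
class EFACoefficients:
    """Raw elliptic Fourier coefficients of one contour (mm units)."""

    coeffs: np.ndarray  # (K, 4) rows (a_n, b_n, c_n, d_n)
    A0: float
    C0: float
    scale_mm_per_unit: float = 1.0

    @property
    def K(self) -> int:
        return self.coeffs.shape[0]


@dataclass(frozen=True)
class FirstEllipse:
    """Best-fitting ellipse from harmonic 1.

    ``start_phase`` (theta) is folded to [0, pi) as the ellipse itself is
    invariant under a half-turn of the start point; the sign-resolved
    phase used by the normalization is kept internally.
    """

    semi_major: float  # a*, mm
    semi_minor: float  # b*, mm
    orientation: float  # psi in (-pi, pi]
    start_phase: float  # theta in [0, pi)
    _theta_full: float = 0.0  # phase with the a1* > 0 ambiguity resolved


@dataclass(frozen=True)
class SizeMeasure:
    """Global size of a wing element: the first-ellipse semi-major axis (mm)."""

    value: float


@dataclass(frozen=True)
class NormalizedShape:
    """Similarity- and start-point-invariant shape vector.

    ``vector`` = (d1'', a2'', b2'', c2'', d2'', ..., aK'', ..., dK''),
    length 4K - 3.  Metadata records the normalization parameters
    (size E in mm, start phase theta, orientation psi).
    """

    vector: np.ndarray
    size_mm: float
    start_phase: float
    orientation: float

    @property
    def K(self) -> int:
        return (len(self.vector) + 3) // 4

    @property
    def d1(self) -> float:
        """Signed width-to-length ratio of the first harmonic ellipse."""
        return float(self.vector[0])

    def coeff_matrix(self) -> np.ndarray:
        """Expand back to a (K, 4) coefficient matrix with the implicit
        first-harmonic entries a1=1, b1=c1=0 restored."""
        K = self.K
        m = np.zeros((K, 4))
        m[0] = (1.0, 0.0, 0.0, self.vector[0])
        if K > 1:
            m[1:] = self.vector[1:].reshape(K - 1, 4)
        return m


def max_harmonics(c: Contour) -> int:
    """Largest meaningful harmonic count for a V-point polygon."""
    return c.n_points // 2 - 1


def _arclength(points: np.ndarray):
    closed = np.vstack([points, points[:1]])
    dxy = np.diff(closed, axis=0)  # (V, 2)
    dt = np.linalg.norm(dxy, axis=1)
    if np.any(dt == 0.0):
        raise NumericalError("zero-length segment in contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])  # (V+1,)
    return dxy, dt, t, t[-1]


def compute_efa(c: Contour, K: int) -> EFACoefficients:
    """Exact polygon EFA coefficients for harmonics 1..K.

    The offsets A0, C0 are the arc-length averages of x(t), y(t)
    (exact trapezoid of the piecewise-linear parameterisation).
    """
    kmax = max_harmonics(c)
    if not (1 <= K <= kmax):
        raise InputValidationError(
            f"specimen {c.specimen_id!r}: K={K} out of range [1, {kmax}] "
            f"for a {c.n_points}-point contour"
        )
    dxy, dt, t, T = _arclength(c.points)
    n = np.arange(1, K + 1)[:, None]  # (K, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T  # (K, V+1)
    dcos = np.diff(np.cos(phi), axis=1)  # (K, V)
    dsin = np.diff(np.sin(phi), axis=1)
    slope = dxy / dt[:, None]  # (V, 2) dx/dt, dy/dt per segment
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)  # (K,)
    a = const * (dcos @ slope[:, 0])
    b = const * (dsin @ slope[:, 0])
    cc = const * (dcos @ slope[:, 1])
    d = const * (dsin @ slope[:, 1])
    coeffs = np.stack([a, b, cc, d], axis=1)
    closed = np.vstack([c.points, c.points[:1]])
    mid = 0.5 * (closed[:-1] + closed[1:])
    A0 = float(np.sum(mid[:, 0] * dt) / T)
    C0 = float(np.sum(mid[:, 1] * dt) / T)
    return EFACoefficients(coeffs=coeffs, A0=A0, C0=C0,
                           scale_mm_per_unit=c.scale_mm_per_unit)


def _rot(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa], [sa, ca]])


def _resolve_first_harmonic(e: EFACoefficients):
    """Canonical start phase and orientation from harmonic 1.

    theta has a four-fold ambiguity (quarter turns of the start phase).
    The canonical choice makes the phase-0 semi-axis the major one and
    requires a1* > 0, which fixes theta uniquely for any non-circular
    first ellipse and makes the normalization start-point invariant.
    """
    a1, b1, c1, d1 = e.coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    theta0 = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1), denom)
    M = e.coeffs[0].reshape(2, 2)
    best = None
    for k in range(4):
        theta = (theta0 + k * np.pi / 2.0) % (2.0 * np.pi)
        Ms = M @ _rot(theta)
        axis1 = float(np.hypot(Ms[0, 0], Ms[1, 0]))
        axis2 = float(np.hypot(Ms[0, 1], Ms[1, 1]))
        if axis1 + 1e-12 * max(axis1, axis2) < axis2:
            continue  # phase-0 axis is the minor one
        if Ms[0, 0] < 0 or (Ms[0, 0] == 0 and Ms[1, 0] < 0):
            continue  # wrong half-line: a1* must be positive
        cand = (theta, Ms, axis1, axis2)
        if best is None or theta < best[0]:
            best = cand
    if best is None:  # numerically circular: fall back to k = 0 branch
        theta = theta0 % (2.0 * np.pi)
        Ms = M @ _rot(theta)
        if Ms[0, 0] < 0:
            theta = (theta + np.pi) % (2.0 * np.pi)
            Ms = M @ _rot(theta)
        best = (theta, Ms, float(np.hypot(Ms[0, 0], Ms[1, 0])),
                float(np.hypot(Ms[0, 1], Ms[1, 1])))
    theta, Ms, axis1, axis2 = best
    if axis1 <= 0.0:
        raise NumericalError("degenerate contour: first harmonic has no extent")
    psi = float(np.arctan2(Ms[1, 0], Ms[0, 0]))
    return theta, psi, axis1, axis2, Ms


def first_ellipse(e: EFACoefficients) -> FirstEllipse:
    """First harmonic ellipse parameters (axes in mm)."""
    theta, psi, axis1, axis2, _ = _resolve_first_harmonic(e)
    return FirstEllipse(
        semi_major=axis1,
        semi_minor=axis2,
        orientation=psi,
        start_phase=theta % np.pi,
        _theta_full=theta,
    )


def size_of(c: Contour, K: int = 1) -> SizeMeasure:
    """Global size: semi-major axis of the first harmonic ellipse, mm.

    Only harmonic 1 enters the first ellipse, so K = 1 suffices; larger
    K gives identical values.
    """
    return SizeMeasure(value=first_ellipse(compute_efa(c, K)).semi_major)


def normalize(e: EFACoefficients) -> NormalizedShape:
    """Normalized (NEF) coefficients: invariant to size, rotation,
    translation and starting point.

    Harmonic n is rotated by n*theta in phase (start-point shift), then
    by -psi spatially, then divided by the semi-major axis E.  The
    resulting a1'' = 1, b1'' = c1'' = 0 are dropped; d1'' (signed
    width-to-length ratio) leads the vector.
    """
    theta, psi, E, _, _ = _resolve_first_harmonic(e)
    Rpsi = _rot(-psi)
    K = e.K
    out = np.empty((K, 4))
    for n in range(1, K + 1):
        M = e.coeffs[n - 1].reshape(2, 2)
        Mn = Rpsi @ (M @ _rot(n * theta)) / E
        out[n - 1] = Mn.ravel()
    if abs(out[0, 0] - 1.0) > 1e-9 or abs(out[0, 1]) > 1e-9 or abs(out[0, 2]) > 1e-9:
        raise NumericalError(
            "first-harmonic normalization failed to reach canonical form"
        )
    # Half-period ambiguity: starting the trace half a period later and
    # rotating by 180 degrees negates exactly the even harmonics.  The
    # canonical branch makes the largest-magnitude even-harmonic
    # coefficient positive — a choice that depends only on the shape,
    # never on the input coordinates or start point.  (A shape with no
    # even harmonics has coinciding branches.)
    even = np.arange(2, K + 1, 2) - 1
    if len(even):
        flat = out[even].ravel()
        k = int(np.argmax(np.abs(flat)))
        if abs(flat[k]) > 1e-9 and flat[k] < 0:
            out[even] *= -1.0
            theta = (theta + np.pi) % (2.0 * np.pi)
            psi = float(np.arctan2(np.sin(psi + np.pi), np.cos(psi + np.pi)))
    vector = np.concatenate([[out[0, 3]], out[1:].ravel()])
    return NormalizedShape(vector=vector, size_mm=E,
                           start_phase=theta % np.pi, orientation=psi)


def reconstruct(
    shape: EFACoefficients | NormalizedShape, V_out: int
) -> np.ndarray:
    """Evaluate the Fourier outline at ``V_out`` equally spaced parameter
    values; returns a (V_out, 2) point array.

    For raw coefficients the offsets A0, C0 are included, so the outline
    sits where the contour was digitized.  For a NormalizedShape the
    outline is the canonical unit-semi-major shape at the origin.
    """
    if V_out < 8:
        raise InputValidationError("V_out must be at least 8")
    if isinstance(shape, NormalizedShape):
        coeffs, A0, C0 = shape.coeff_matrix(), 0.0, 0.0
    else:
        coeffs, A0, C0 = shape.coeffs, shape.A0, shape.C0
    K = coeffs.shape[0]
    t = np.linspace(0.0, 2.0 * np.pi, V_out, endpoint=False)
    n = np.arange(1, K + 1)[:, None]
    cos = np.cos(n * t[None, :])
    sin = np.sin(n * t[None, :])
    x = A0 + coeffs[:, 0] @ cos + coeffs[:, 1] @ sin
    y = C0 + coeffs[:, 2] @ cos + coeffs[:, 3] @ sin
    return np.stack([x, y], axis=1)


def harmonic_power(e: EFACoefficients) -> np.ndarray:
    """Cumulative power proportions over harmonics 1..K.

    Harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2; the
    returned array is the running sum normalized by the total, so the
    last entry is 1.
    """
    p = 0.5 * np.sum(e.coeffs**2, axis=1)
    total = p.sum()
    if total <= 0:
        raise NumericalError("contour has zero harmonic power")
    return np.cumsum(p) / total


def choose_harmonics(c: Contour, threshold: float = 0.9999) -> int:
    """Smallest K whose cumulative harmonic power reaches ``threshold``
    (computed at the contour's maximum harmonic count)."""
    if not (0.5 < threshold <= 1.0):
        raise InputValidationError(
            f"threshold must be in (0.5, 1], got {threshold}"
        )
    e = compute_efa(c, max_harmonics(c))
    cum = harmonic_power(e)
    idx = int(np.searchsorted(cum, threshold - 1e-15)) + 1
    return min(idx, e.K)
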