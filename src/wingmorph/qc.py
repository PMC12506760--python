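"""Digitizing repeatability and allometric size-shape regression.

Repeatability follows the intraclass-correlation formulation: each
shape variable is submitted to a one-way ANOVA with specimen as the
factor across replicate digitizations; the among-specimen variance
component s2_A = (MS_among - MS_within) / n0 (clamped at zero) yields
R_i = s2_A / (s2_A + s2_w).  The per-variable indices are combined into
one repeatability R by total-variance weighting, and the measurement
error is reported as ME% = 100 (1 - R).

Allometry is the dependence of shape on size: each retained principal
component is regressed on the global size variable and the single
determination coefficient is the trace ratio

    r2 = sum_i SS_explained_i / sum_i SS_total_i,

with the direction of the relationship taken as the sign of the
correlation between size and the allometric shape score (the projection
of shape onto the normalized vector of per-PC slopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputValidationError

__all__ = ["RepeatabilityResult", "AllometryResult", "repeatability",
           "allometry_r2"]


@dataclass(frozen=True)
class RepeatabilityResult:
    per_variable: pd.DataFrame  # MS_among, MS_within, s2_A, s2_w, R_i, totvar
    R: float  # combined, variance-weighted
    measurement_error_pct: float  # 100 * (1 - R)
    n_specimens: int
    n0: float  # replicates per specimen (harmonic-style correction if unbalanced)


@dataclass(frozen=True)
class AllometryResult:
    r2: float
    direction: int  # sign of the size vs allometric-score correlation
    slopes: np.ndarray  # per-PC regression slopes on size
    fitted: np.ndarray  # (N, p) fitted shape values


def repeatability(shape_matrix: np.ndarray, specimen_ids,
                  min_specimens: int = 5) -> RepeatabilityResult:
    """Repeatability index over replicate digitizations.

    Parameters
    ----------
    shape_matrix
        (M, p) array of shape variables, one row per digitization
        (replicates included).
    specimen_ids
        Length-M labels; rows sharing a label are replicates of the same
        specimen.  Every specimen must have the same number (>= 2) of
        replicates; unpaired specimens are reported by id.
    """
    X = np.asarray(shape_matrix, dtype=float)
    ids = np.asarray(specimen_ids)
    if X.ndim != 2 or len(ids) != X.shape[0]:
        raise InputValidationError("shape matrix rows must match specimen ids")
    uniq = sorted(set(ids.tolist()))
    counts = {s: int(np.sum(ids == s)) for s in uniq}
    n0 = max(counts.values())
    unpaired = sorted(s for s, k in counts.items() if k != n0 or k < 2)
    if unpaired:
        raise InputValidationError(
            f"specimens without a full replicate set: {unpaired}"
        )
    a = len(uniq)
    if a < min_specimens:
        raise InputValidationError(
            f"need at least {min_specimens} specimens with replicates, got {a}"
        )
    N = X.shape[0]
    rows = []
    for j in range(X.shape[1]):
        x = X[:, j]
        grand = x.mean()
        ss_within = 0.0
        ss_among = 0.0
        for s in uniq:
            v = x[ids == s]
            ss_within += float(np.sum((v - v.mean()) ** 2))
            ss_among += len(v) * (v.mean() - grand) ** 2
        ms_among = ss_among / (a - 1)
        ms_within = ss_within / (N - a)
        s2_a = max((ms_among - ms_within) / n0, 0.0)
        s2_w = ms_within
        tot = s2_a + s2_w
        r_i = s2_a / tot if tot > 0 else 1.0  # identical replicates: R = 1
        rows.append({
            "variable": j, "MS_among": ms_among, "MS_within": ms_within,
            "s2_A": s2_a, "s2_w": s2_w, "R": r_i, "total_variance": tot,
        })
    per = pd.DataFrame(rows)
    weights = per["total_variance"].to_numpy()
    if weights.sum() > 0:
        R = float(np.sum(weights * per["R"].to_numpy()) / weights.sum())
    else:
        R = 1.0
    return RepeatabilityResult(
        per_variable=per, R=R, measurement_error_pct=100.0 * (1.0 - R),
        n_specimens=a, n0=float(n0),
    )


def allometry_r2(pc_scores: np.ndarray, sizes) -> AllometryResult:
    """Multivariate determination coefficient of shape on size.

    Regresses each shape variable (retained PC score) on size and pools
    explained and total sums of squares across variables.  Equivalent to
    the univariate r2 when there is a single shape variable.
    """
    Y = np.asarray(pc_scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    x = np.asarray(sizes, dtype=float)
    if len(x) != Y.shape[0]:
        raise InputValidationError("sizes must match shape rows")
    if len(x) < 3:
        raise InputValidationError("need at least 3 specimens")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise InputValidationError("size is constant; allometry undefined")
    Yc = Y - Y.mean(axis=0)
    slopes = (xc @ Yc) / sxx  # (p,)
    fitted_c = np.outer(xc, slopes)
    ss_exp = float(np.sum(fitted_c**2))
    ss_tot = float(np.sum(Yc**2))
    r2 = ss_exp / ss_tot if ss_tot > 0 else 0.0
    norm = np.linalg.norm(slopes)
    if norm > 0:
        # canonical orientation of the allometric axis (largest-|slope|
        # entry positive) so the sign is data-driven, not an artefact of
        # the fit direction
        u = slopes / norm
        k = int(np.argmax(np.abs(u)))
        if u[k] < 0:
            u = -u
        score = Yc @ u
        corr = float(np.corrcoef(x, score)[0, 1]) if score.std() > 0 else 0.0
    else:
        corr = 0.0
    direction = int(np.sign(corr))
    return AllometryResult(
        r2=r2, direction=direction, slopes=slopes,
        fitted=fitted_c + Y.mean(axis=0),
    )
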