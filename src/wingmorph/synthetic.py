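"""Synthetic wing-element contour datasets with known ground truth.

The generator emulates the structure of a four-species wing-element
study: group-specific mean outline shapes (normalized Fourier
templates), Normal size distributions on the sub-millimetre scale of
mosquito wing cells, optional allometric size-shape coupling, and
replicate digitizations with radial point jitter.  Every stochastic
quantity is drawn from a single seeded generator, so a config with the
same seed reproduces the dataset exactly.

Shape noise lives in normalized-coefficient space (the within-group
shape distribution is then well defined and recovery is exact), while
digitizing error is point-space jitter — the two channels that real
datasets mix are kept separate and independently controllable.

A subtlety: polygonizing an evaluated Fourier series re-parameterises
the curve by arc length, so the polygon's own EFA differs from the
planted coefficients by a smooth, shape-dependent map (whose kernel is
the similarity/start-phase directions — planted vectors are generally
not exactly reachable).  Ground truth is therefore recorded in measured
shape space: :func:`contour_from_shape` returns both the points and the
contour's own normalized EFA vector, and that measured vector is what
recovery tests compare against.  Drawn sizes are exact by linear
rescaling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import efa
from .errors import InputValidationError, NumericalError
from .features import extract_features
from .io_contours import Contour, SpecimenRecord, SpecimenTable

__all__ = [
    "GroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "default_config",
    "contour_from_shape",
    "simulate_dataset",
    "recover_parameters",
    "calibrate_jitter",
    "calibrate_allometric_slope",
]


@dataclass(frozen=True)
class GroupSpec:
    """One species group: label, sample size, size distribution (mm) and
    its template offset in normalized-coefficient space."""

    label: str
    n: int
    size_mean: float
    size_sd: float
    offset: np.ndarray  # (4K-3,), scaled by cfg.divergence


@dataclass(frozen=True)
class SyntheticConfig:
    groups: tuple[GroupSpec, ...]
    base_template: np.ndarray  # (4K-3,)
    divergence: float
    coefficient_noise_sd: float
    allometric_slope: float  # coefficient change per mm of size
    allometric_direction: np.ndarray  # unit vector, (4K-3,)
    jitter_sd: float  # radial digitizing noise as fraction of semi-major
    points: int  # V, pseudo-landmarks per contour
    replicates: int
    seed: int
    element: str = "third_posterior"

    @property
    def K(self) -> int:
        return (len(self.base_template) + 3) // 4

    @property
    def N(self) -> int:
        return sum(g.n for g in self.groups)

    def validate(self) -> None:
        if self.seed is None:
            raise InputValidationError("a seed is mandatory")
        L = len(self.base_template)
        if (L + 3) % 4 != 0:
            raise InputValidationError(
                "template length must be 4K - 3 for integer K"
            )
        for g in self.groups:
            if g.n < 3:
                raise InputValidationError(f"group {g.label!r}: n >= 3 required")
            if not (g.size_sd > 0):
                raise InputValidationError(
                    f"group {g.label!r}: size_sd must be positive"
                )
            if len(g.offset) != L:
                raise InputValidationError(
                    f"group {g.label!r}: offset length mismatch"
                )
        if self.points < 4 * self.K + 2:
            raise InputValidationError(
                f"points={self.points} < 4K + 2 = {4 * self.K + 2}"
            )
        if self.replicates < 1:
            raise InputValidationError("replicates must be >= 1")
        if self.jitter_sd < 0 or self.coefficient_noise_sd < 0:
            raise InputValidationError("noise SDs must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    config: SyntheticConfig
    planted_templates: dict[str, np.ndarray]  # base + divergence * offset
    templates: dict[str, np.ndarray]  # measured-space group templates
    sizes: dict[tuple[str, str], float]  # (group, specimen_id) -> drawn size
    vectors: dict[tuple[str, str], np.ndarray]  # measured true shape vectors
    planted_clusters: tuple[frozenset, ...]  # nested hierarchy of labels


def _vec(entries: dict[int, float], L: int) -> np.ndarray:
    v = np.zeros(L)
    for i, x in entries.items():
        v[i] = x
    return v


def _offset_basis(L: int = 17) -> list[np.ndarray]:
    """Three orthonormal template-offset directions.

    Chosen on odd-harmonic coefficients (d3; c5; a d5/c3 mix) for two
    reasons: their planted-to-measured transmission is close to 1, and
    they leave the even harmonics untouched — the even harmonics carry
    the trace-phase canonicalization of the normalization, which must
    stay far from its decision boundary for replicate digitizations to
    be stable."""
    u1 = _vec({8: 1.0}, L)
    u2 = _vec({15: 1.0}, L)
    u3 = _vec({16: 0.8, 7: 0.6}, L)
    return [u1, u2, u3]


def hierarchical_offsets(delta: float = 0.008, L: int = 17
                         ) -> dict[str, np.ndarray]:
    """Group offsets planting the nested hierarchy ((A, B), C), D.

    A and B sit a small angle apart on a circle of radius ``delta``
    around the base shape; C sits on the same circle diametrically
    opposite; D is alone on an orthogonal axis at radius 3*delta.
    Equal radii for A, B, C keep the within-group noise distortion of
    the shape-realisation map comparable across those groups, so the
    planted distance ordering (A-B < {A,B}-C < everything-D) survives
    Mahalanobis whitening.  Pairwise template distances are 0.52, 1.98
    and >= 3.16 times delta.
    """
    u1, u2, u3 = _offset_basis(L)
    c, s = np.cos(np.pi / 12), np.sin(np.pi / 12)
    return {
        "sp_A": delta * (c * u1 + s * u2),
        "sp_B": delta * (c * u1 - s * u2),
        "sp_C": -delta * u1,
        "sp_D": 3.0 * delta * u3,
    }


def equidistant_offsets(edge: float = 0.008, L: int = 17
                        ) -> dict[str, np.ndarray]:
    """Four group offsets at the vertices of a regular tetrahedron with
    the given pairwise template distance (``edge``); all radii equal, so
    every pair separates identically as divergence grows."""
    u1, u2, u3 = _offset_basis(L)
    s = edge / (2.0 * np.sqrt(2.0))
    verts = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]
    labels = ["sp_A", "sp_B", "sp_C", "sp_D"]
    return {
        lab: s * (v[0] * u1 + v[1] * u2 + v[2] * u3)
        for lab, v in zip(labels, verts)
    }


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-scale default: four species groups with n = (30, 41, 35, 22)
    and third-posterior-cell size distributions (means 0.595/0.620/
    0.626/0.646 mm, SDs 0.035/0.032/0.042/0.025 mm).

    Templates are an elliptical base (width-to-length ratio d1 = 0.5)
    with mild higher harmonics, plus group-specific perturbations on
    harmonics 2-5 arranged as a nested hierarchy: groups A and B
    closest, C further, D (the large-bodied species analogue) most
    distinct.  K = 5 harmonics, vector length 17.
    """
    L = 17  # K = 5
    # the dominant even-harmonic coefficient (d2 = -0.09) anchors the
    # trace-phase canonicalization well away from its decision boundary
    base = _vec({0: 0.5, 2: 0.01, 3: 0.02, 4: -0.09, 5: 0.015,
                 7: 0.01, 10: 0.008, 11: -0.006, 13: 0.004}, L)
    offsets = hierarchical_offsets(delta=0.008, L=L)
    # allometric axis on odd harmonics (a3, a5), orthogonal to the
    # group-offset directions
    direction = _vec({5: 0.8, 13: 0.6}, L)
    groups = (
        GroupSpec("sp_A", 30, 0.595, 0.035, offsets["sp_A"]),
        GroupSpec("sp_B", 41, 0.620, 0.032, offsets["sp_B"]),
        GroupSpec("sp_C", 35, 0.626, 0.042, offsets["sp_C"]),
        GroupSpec("sp_D", 22, 0.646, 0.025, offsets["sp_D"]),
    )
    return SyntheticConfig(
        groups=groups,
        base_template=base,
        divergence=1.0,
        coefficient_noise_sd=0.008,
        allometric_slope=0.32,
        allometric_direction=direction / np.linalg.norm(direction),
        jitter_sd=0.008,
        points=120,
        replicates=1,
        seed=seed,
    )


def _shape_from_vector(vector: np.ndarray) -> efa.NormalizedShape:
    return efa.NormalizedShape(vector=np.asarray(vector, dtype=float),
                               size_mm=1.0, start_phase=0.0, orientation=0.0)


def contour_from_shape(
    vector: np.ndarray,
    V: int,
    size: float = 1.0,
    element: str = "third_posterior",
    specimen_id: str = "synthetic",
) -> tuple[np.ndarray, np.ndarray]:
    """Realise a planted coefficient vector as a V-gon of exact size.

    Returns ``(points, measured_vector)``: the polygon scaled so that
    its own first-harmonic semi-major axis equals ``size`` exactly
    (EFA size is exactly linear in scale), and its measured normalized
    shape vector — the ground truth the analysis pipeline recovers.
    """
    planted = np.asarray(vector, dtype=float)
    K = (len(planted) + 3) // 4
    pts = efa.reconstruct(_shape_from_vector(planted), V)
    c = Contour.create(specimen_id, element, pts)
    meas = efa.normalize(efa.compute_efa(c, K))
    return pts * (size / meas.size_mm), meas.vector.copy()


def _planted_hierarchy(groups: tuple[GroupSpec, ...]) -> tuple[frozenset, ...]:
    """Nested clusters implied by the group order: the first two groups
    are sisters, later groups attach outward in order."""
    labels = [g.label for g in groups]
    clusters = []
    for k in range(2, len(labels)):
        clusters.append(frozenset(labels[:k]))
    return tuple(clusters)


def simulate_dataset(cfg: SyntheticConfig) -> tuple[SpecimenTable, GroundTruth]:
    """Draw a labeled contour dataset from the configured model.

    Per specimen: size ~ Normal(mean, sd) truncated below at 0.1*mean;
    shape vector = template + coefficient noise + allometric shift
    proportional to (size - group mean); the contour is realised at
    ``cfg.points`` pseudo-landmarks.  Each replicate re-jitters the
    points radially (SD = jitter_sd * semi-major) and rolls the start
    index, emulating an independent digitization of the same wing.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[SpecimenRecord] = []
    planted_templates: dict[str, np.ndarray] = {}
    templates: dict[str, np.ndarray] = {}
    sizes: dict[tuple[str, str], float] = {}
    vectors: dict[tuple[str, str], np.ndarray] = {}
    for g in cfg.groups:
        template = cfg.base_template + cfg.divergence * g.offset
        planted_templates[g.label] = template
        _, templates[g.label] = contour_from_shape(
            template, cfg.points, element=cfg.element,
            specimen_id=f"{g.label}_template",
        )
        lo = (0.1 * g.size_mean - g.size_mean) / g.size_sd
        draws = sps.truncnorm.rvs(lo, np.inf, loc=g.size_mean,
                                  scale=g.size_sd, size=g.n,
                                  random_state=rng)
        for i in range(g.n):
            sid = f"{g.label}_{i + 1:03d}"
            size = float(draws[i])
            vec = template.copy()
            if cfg.coefficient_noise_sd > 0:
                vec = vec + rng.normal(0.0, cfg.coefficient_noise_sd,
                                       len(vec))
            vec = vec + (cfg.allometric_slope * (size - g.size_mean)
                         * cfg.allometric_direction)
            vec[0] = float(np.clip(vec[0], 1e-3, 0.999))
            sizes[(g.label, sid)] = size
            pts, measured = contour_from_shape(
                vec, cfg.points, size=size, element=cfg.element,
                specimen_id=sid,
            )
            vectors[(g.label, sid)] = measured
            for rep in range(1, cfg.replicates + 1):
                p = pts
                if cfg.jitter_sd > 0:
                    radii = np.linalg.norm(p, axis=1)
                    radii = np.where(radii == 0, 1.0, radii)
                    unit = p / radii[:, None]
                    p = p + unit * rng.normal(
                        0.0, cfg.jitter_sd * size, (len(p), 1)
                    )
                p = np.roll(p, int(rng.integers(len(p))), axis=0)
                contour = Contour.create(sid, cfg.element, p, replicate=rep)
                records.append(
                    SpecimenRecord(sid, g.label, cfg.element, rep, contour)
                )
    truth = GroundTruth(
        config=cfg,
        planted_templates=planted_templates,
        templates=templates,
        sizes=sizes,
        vectors=vectors,
        planted_clusters=_planted_hierarchy(cfg.groups),
    )
    return SpecimenTable(records), truth


def recover_parameters(table: SpecimenTable, truth: GroundTruth,
                       retention: float = 0.99) -> dict:
    """Run the analysis pipeline on a simulated dataset and compare with
    the planted ground truth.

    Reports the largest group size-mean error (mm), the recovered
    allometric r2, the jackknife shape kappa, and whether the UPGMA tree
    over group mean shapes contains every planted cluster.
    """
    from .qc import allometry_r2
    from .shape_stats import (fit_da, jackknife_shape_classification,
                              mahalanobis_matrix, pca, upgma)
    from .size_stats import adjusted_accuracy

    cfg = truth.config
    primary = table.select(element=cfg.element, replicate=1)
    groups, ids, sizes, shapes = extract_features(primary, cfg.K)
    size_err = {}
    for g in cfg.groups:
        drawn = np.array([truth.sizes[(g.label, sid)]
                          for sid in ids[groups == g.label]])
        measured = sizes[groups == g.label]
        size_err[g.label] = float(np.mean(measured) - np.mean(drawn))
    space = pca(shapes, retention=retention)
    allo = allometry_r2(space.retained_scores, sizes)
    report = jackknife_shape_classification(shapes, groups,
                                            retention=retention)
    kappa, kappa_pct = adjusted_accuracy(report)
    model = fit_da(space, groups)
    tree = upgma(mahalanobis_matrix(model))
    planted = set(truth.planted_clusters)
    topology_ok = planted.issubset(set(tree.clusters))
    return {
        "size_mean_error_mm": size_err,
        "max_abs_size_mean_error_mm": float(
            max(abs(v) for v in size_err.values())
        ),
        "allometry_r2": allo.r2,
        "allometry_direction": allo.direction,
        "shape_kappa": kappa,
        "shape_kappa_percent": kappa_pct,
        "upgma_newick": tree.newick,
        "topology_recovered": bool(topology_ok),
    }


def _pilot_me(cfg: SyntheticConfig, n_specimens: int, seeds) -> float:
    """Mean measurement-error percentage over pilot two-replicate
    datasets at the current jitter."""
    from .qc import repeatability

    small_groups = tuple(
        dataclasses.replace(g, n=max(3, n_specimens // len(cfg.groups)))
        for g in cfg.groups
    )
    mes = []
    for seed in seeds:
        pilot = dataclasses.replace(cfg, groups=small_groups, replicates=2,
                                    seed=seed)
        table, _ = simulate_dataset(pilot)
        sub = table.select(element=cfg.element, replicate=None)
        _, ids, _, shapes = extract_features(sub, cfg.K)
        mes.append(repeatability(shapes, ids).measurement_error_pct)
    return float(np.mean(mes))


def calibrate_jitter(cfg: SyntheticConfig, target_me_pct: float,
                     n_specimens: int = 20, n_pilot: int = 3,
                     pilot_seed: int | None = None,
                     lo: float = 1e-4, hi: float = 0.05,
                     n_iter: int = 18) -> SyntheticConfig:
    """Find the ``jitter_sd`` at which replicate digitizations carry
    roughly ``target_me_pct`` percent of the total shape variance.

    The measurement error grows monotonically (and strongly
    nonlinearly: a jagged polygon inflates arc length) with jitter, so
    the calibration bisects log(jitter) against the mean ME over
    ``n_pilot`` pilot datasets.
    """
    if not (0 < target_me_pct < 100):
        raise InputValidationError("target ME% must be in (0, 100)")
    base = cfg.seed if pilot_seed is None else pilot_seed
    seeds = [base + 7919 * j for j in range(n_pilot)]
    llo, lhi = np.log(lo), np.log(hi)
    if _pilot_me(dataclasses.replace(cfg, jitter_sd=lo), n_specimens,
                 seeds) > target_me_pct:
        raise NumericalError(
            "target ME% below the floor reachable at the minimum jitter"
        )
    out = cfg
    for _ in range(n_iter):
        mid = float(np.exp(0.5 * (llo + lhi)))
        out = dataclasses.replace(cfg, jitter_sd=mid)
        me = _pilot_me(out, n_specimens, seeds)
        if me < target_me_pct:
            llo = np.log(mid)
        else:
            lhi = np.log(mid)
    return out


def calibrate_allometric_slope(cfg: SyntheticConfig, target_r2: float,
                               n_iter: int = 2, n_pilot: int = 5,
                               pilot_seed: int | None = None
                               ) -> SyntheticConfig:
    """Scale ``allometric_slope`` so the recovered shape-on-size r2 is
    approximately ``target_r2`` (a proportion).

    Explained variance scales with slope^2 while the residual variance
    is slope-free, so slope' = slope * sqrt(t * O / ((1 - t) * E)) with
    E, O the mean explained/other variance over ``n_pilot`` pilot
    datasets at the current slope (averaging keeps single-draw sampling
    noise out of the calibration).
    """
    from .qc import allometry_r2
    from .shape_stats import pca

    if not (0 < target_r2 < 1):
        raise InputValidationError("target r2 must be in (0, 1)")
    seed = cfg.seed if pilot_seed is None else pilot_seed
    out = cfg
    if out.allometric_slope == 0:
        out = dataclasses.replace(out, allometric_slope=0.1)
    for it in range(n_iter):
        r2s = []
        for j in range(n_pilot):
            pilot = dataclasses.replace(out, seed=seed + 1000 * it + j)
            table, _ = simulate_dataset(pilot)
            _, _, sizes, shapes = extract_features(
                table.select(element=cfg.element, replicate=1), cfg.K
            )
            space = pca(shapes, retention=0.99)
            r2s.append(allometry_r2(space.retained_scores, sizes).r2)
        r2 = float(np.mean(r2s))
        if not (0 < r2 < 1):
            raise NumericalError("pilot allometry r2 degenerate")
        k2 = target_r2 * (1.0 - r2) / ((1.0 - target_r2) * r2)
        out = dataclasses.replace(
            out, allometric_slope=out.allometric_slope * float(np.sqrt(k2))
        )
    return out
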