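"""Group size statistics and size-based classification.

Covers the size half of the analysis: per-group summaries with a
compact letter display from pairwise permutation tests, a one-way
permutation ANOVA, leave-one-out (jackknife) maximum-likelihood
classification of specimens by global size, and the chance-corrected
(adjusted) assignment accuracy

    kappa = (Po - Pe) / (1 - Pe),   Pe = sum_i (n_i / N)^2,

i.e. Cohen's kappa with the chance expectation taken from the group
prior proportions.  Display percentages are rounded half away from
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputValidationError, NumericalError

__all__ = [
    "SizeSummary",
    "AnovaResult",
    "ClassificationReport",
    "summarize_sizes",
    "permutation_anova",
    "pairwise_letters",
    "jackknife_size_classification",
    "adjusted_accuracy",
    "round_half_away",
]


def _as_arrays(sizes, groups):
    x = np.asarray(sizes, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape or x.ndim != 1:
        raise InputValidationError("sizes and groups must be equal-length 1-D")
    return x, g


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (so 18.505 % -> 19 and
    53.125 -> 53.13 at two decimals); bankers' rounding is not what
    classification tables print.  Returns an int for ndigits = 0."""
    f = 10.0 ** ndigits
    r = np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
    return int(r) if ndigits == 0 else float(r)


@dataclass(frozen=True)
class SizeSummary:
    """Per-group size summary with significance letters."""

    table: pd.DataFrame  # group, n, mean, min, max, variance, sd, letters


@dataclass(frozen=True)
class AnovaResult:
    F_obs: float
    p_perm: float
    replicates: int
    seed: int


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and chance-corrected accuracy of a jackknife
    classification."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    confusion: np.ndarray  # rows true group, cols assigned group
    correct: tuple[int, ...] = field(init=False)

    def __post_init__(self):
        conf = np.asarray(self.confusion, dtype=int)
        if conf.shape != (len(self.groups), len(self.groups)):
            raise InputValidationError("confusion matrix shape mismatch")
        if tuple(conf.sum(axis=1)) != tuple(self.n_per_group):
            raise InputValidationError(
                "confusion row sums must equal group sizes"
            )
        object.__setattr__(self, "confusion", conf)
        object.__setattr__(self, "correct", tuple(np.diag(conf)))

    @classmethod
    def from_counts(cls, groups, n_per_group, correct) -> "ClassificationReport":
        """Build a report from per-group correct counts only (off-diagonal
        structure unknown — misassignments pooled into the next column);
        sufficient for all accuracy computations."""
        groups = tuple(groups)
        n_per_group = tuple(int(n) for n in n_per_group)
        correct = tuple(int(k) for k in correct)
        G = len(groups)
        conf = np.zeros((G, G), dtype=int)
        for i, (n, k) in enumerate(zip(n_per_group, correct)):
            if not (0 <= k <= n):
                raise InputValidationError(
                    f"group {groups[i]!r}: correct count {k} outside [0, {n}]"
                )
            conf[i, i] = k
            conf[i, (i + 1) % G] += n - k
        return cls(groups=groups, n_per_group=n_per_group, confusion=conf)

    @property
    def N(self) -> int:
        return int(sum(self.n_per_group))

    @property
    def observed_accuracy(self) -> float:
        """Po: total proportion of correct assignments."""
        return sum(self.correct) / self.N

    @property
    def chance_accuracy(self) -> float:
        """Pe: expected correct proportion under prior-proportional
        random assignment."""
        n = np.asarray(self.n_per_group, dtype=float)
        return float(np.sum((n / n.sum()) ** 2))

    def per_group_percent(self) -> list[float]:
        return [100.0 * k / n for k, n in zip(self.correct, self.n_per_group)]

    def to_frame(self) -> pd.DataFrame:
        kappa, kappa_pct = adjusted_accuracy(self)
        rows = [
            {
                "group": g,
                "n": n,
                "correct": k,
                "percent_correct": 100.0 * k / n,
            }
            for g, n, k in zip(self.groups, self.n_per_group, self.correct)
        ]
        df = pd.DataFrame(rows)
        df.attrs["observed_accuracy"] = self.observed_accuracy
        df.attrs["adjusted_accuracy"] = kappa
        df.attrs["adjusted_percent"] = kappa_pct
        return df


def adjusted_accuracy(report: ClassificationReport) -> tuple[float, int]:
    """Chance-corrected accuracy kappa = (Po - Pe)/(1 - Pe) and its
    display percentage (rounded half away from zero).

    Pe is the sum of squared group proportions, the probability of a
    chance correct assignment when specimens are assigned in proportion
    to group sizes.
    """
    Pe = report.chance_accuracy
    if Pe >= 1.0:
        raise NumericalError(
            "undefined adjustment: single group (chance accuracy = 1)"
        )
    Po = report.observed_accuracy
    kappa = (Po - Pe) / (1.0 - Pe)
    return kappa, round_half_away(100.0 * kappa)


def summarize_sizes(sizes, groups, letters: dict[str, str] | None = None
                    ) -> SizeSummary:
    """Per-group n, mean, min, max, sample variance (n-1) and SD, in mm.

    Full precision is retained; callers round to 3 decimals for display.
    ``letters`` (from :func:`pairwise_letters`) are attached when given.
    Rows are sorted by group label.
    """
    x, g = _as_arrays(sizes, groups)
    rows = []
    for label in sorted(set(g.tolist())):
        v = x[g == label]
        if len(v) < 2:
            raise InputValidationError(
                f"group {label!r} has n={len(v)} < 2 specimens"
            )
        rows.append({
            "group": label,
            "n": int(len(v)),
            "mean": float(v.mean()),
            "min": float(v.min()),
            "max": float(v.max()),
            "variance": float(v.var(ddof=1)),
            "sd": float(v.std(ddof=1)),
            "letters": letters.get(label, "") if letters else "",
        })
    return SizeSummary(table=pd.DataFrame(rows))


def _f_statistic(x: np.ndarray, onehot: np.ndarray, n_per: np.ndarray):
    """One-way F for rows of x (each row one permuted dataset)."""
    N = x.shape[-1]
    G = onehot.shape[1]
    grand = x.mean(axis=-1, keepdims=True)
    sums = x @ onehot  # (..., G)
    means = sums / n_per
    ss_between = np.sum(n_per * (means - grand) ** 2, axis=-1)
    ss_total = np.sum((x - grand) ** 2, axis=-1)
    ss_within = ss_total - ss_between
    df_b, df_w = G - 1, N - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    return np.where(ss_within <= 0,
                    np.where(ss_between <= 0, 0.0, np.inf), F)


def permutation_anova(sizes, groups, R: int = 1000,
                      seed: int | None = None) -> AnovaResult:
    """One-way ANOVA with a label-permutation null.

    The observed statistic is the classical one-way F; significance is
    the proportion of R wholesale label permutations with F at least as
    large, with the +1 correction p = (1 + #{F_perm >= F_obs})/(R + 1).
    """
    if R < 1:
        raise InputValidationError(f"replicates must be >= 1, got {R}")
    if seed is None:
        raise InputValidationError("a seed is required for permutation tests")
    x, g = _as_arrays(sizes, groups)
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise InputValidationError("need at least 2 groups")
    onehot = np.array([[lab == gi for lab in labels] for gi in g], dtype=float)
    n_per = onehot.sum(axis=0)
    F_obs = float(_f_statistic(x[None, :], onehot, n_per)[0])
    rng = np.random.default_rng(seed)
    # permute values wholesale: equivalent to permuting labels
    keys = rng.random((R, len(x)))
    perm = x[np.argsort(keys, axis=1)]
    F_perm = _f_statistic(perm, onehot, n_per)
    p = (1 + int(np.sum(F_perm >= F_obs - 1e-12))) / (R + 1)
    return AnovaResult(F_obs=F_obs, p_perm=p, replicates=R, seed=seed)


def pairwise_letters(sizes, groups, R: int = 1000, alpha: float = 0.05,
                     seed: int | None = None,
                     bonferroni: bool = False) -> dict[str, str]:
    """Compact letter display from pairwise permutation tests.

    Each pair of groups is tested on |mean difference| with R label
    permutations.  Groups share a letter iff they were not significantly
    different at ``alpha`` (optionally Bonferroni-corrected over pairs).
    Letters are assigned greedily from the maximal cliques of the
    non-significance graph, ordered by their smallest member, so the
    display is deterministic and invariant to input order up to
    relabeling.
    """
    if seed is None:
        raise InputValidationError("a seed is required for permutation tests")
    x, g = _as_arrays(sizes, groups)
    labels = sorted(set(g.tolist()))
    n_pairs = len(labels) * (len(labels) - 1) // 2
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va, vb = x[g == a], x[g == b]
            pooled = np.concatenate([va, vb])
            obs = abs(va.mean() - vb.mean())
            keys = rng.random((R, len(pooled)))
            perm = pooled[np.argsort(keys, axis=1)]
            da = perm[:, :len(va)].mean(axis=1)
            db = perm[:, len(va):].mean(axis=1)
            p = (1 + int(np.sum(np.abs(da - db) >= obs - 1e-12))) / (R + 1)
            if bonferroni:
                p = min(1.0, p * n_pairs)
            if p >= alpha:
                graph.add_edge(a, b)
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(graph)),
        key=lambda c: (c[0], c),
    )
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        for lab in clique:
            letters[lab].append(alphabet[idx % len(alphabet)])
    return {lab: ",".join(v) for lab, v in letters.items()}


def jackknife_size_classification(sizes, groups) -> ClassificationReport:
    """Leave-one-out maximum-likelihood classification by global size.

    Each specimen is removed in turn; every group's mean and sample
    variance are recomputed without it and the specimen is assigned to
    the group under whose Normal density its size is most likely ("the
    group to which the size is most similar").  Ties go to the smaller
    standardized distance |z|, then to the lexicographically smaller
    group label.  If a holdout leaves a group with zero variance the
    rule degrades to nearest group mean (logged via the z tie-break,
    since a zero-variance exact match has infinite likelihood).
    """
    x, g = _as_arrays(sizes, groups)
    labels = sorted(set(g.tolist()))
    G = len(labels)
    for lab in labels:
        if np.sum(g == lab) < 3:
            raise InputValidationError(
                f"group {lab!r} needs n >= 3 for jackknife classification"
            )
    conf = np.zeros((G, G), dtype=int)
    index = {lab: i for i, lab in enumerate(labels)}
    for i in range(len(x)):
        best = None
        for lab in labels:
            mask = g == lab
            if lab == g[i]:
                mask = mask.copy()
                mask[i] = False
            v = x[mask]
            mu, var = v.mean(), v.var(ddof=1)
            if var > 0:
                z = abs(x[i] - mu) / np.sqrt(var)
                loglik = -0.5 * np.log(2 * np.pi * var) - 0.5 * z * z
            else:
                # degenerate holdout: nearest-mean fallback
                z = abs(x[i] - mu)
                loglik = np.inf if z == 0 else -np.inf
            key = (-loglik, z, lab)
            if best is None or key < best:
                best = key
        conf[index[g[i]], index[best[2]]] += 1
    n_per = tuple(int(np.sum(g == lab)) for lab in labels)
    return ClassificationReport(groups=tuple(labels), n_per_group=n_per,
                                confusion=conf)
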