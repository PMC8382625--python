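"""Sex-stratified k-means clustering with gap-statistic model selection.

Within each cohort the five clinical variables are z-scored separately per
sex (population standard deviation, so two symmetric points map to z = +/-1)
and clustered with best-of-restarts Lloyd k-means. The number of clusters is
chosen with the gap statistic of Tibshirani, Walther & Hastie: observed
log within-cluster dispersion is compared against reference data drawn
uniformly over each column's observed range. The per-sex solutions are then
merged into one cohort model by minimal-cost centroid matching.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .data_model import CLUSTERING_VARIABLES, Cohort

__all__ = [
    "ClusterModel",
    "GapCurve",
    "KmeansSolution",
    "Scaler",
    "derive_seed",
    "fit_sex_stratified",
    "gap_statistic",
    "kmeans_restarts",
    "merge_sexes",
    "select_k",
    "standardize",
]

_SEXES = ("male", "female")


def derive_seed(seed: int, *parts) -> int:
    """Stable sub-seed (< 2^31) from a base seed and a label path."""
    import zlib

    text = ":".join([str(seed), *map(str, parts)])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class Scaler:
    """Per-variable location/scale used to map clinical values to z-scores."""

    mean: np.ndarray
    sd: np.ndarray
    variables: tuple[str, ...] = CLUSTERING_VARIABLES

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            bad = self.variables[int(np.argmin(self.sd))]
            raise ValueError(f"non-positive standard deviation for {bad!r}")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


@dataclass
class KmeansSolution:
    """Best-of-restarts k-means fit in z-space."""

    centroids: np.ndarray        # (k, 5)
    assignment: np.ndarray       # (n,) cluster indices 0..k-1
    objective: float             # total within-cluster sum of squares
    n_iter: int
    n_restarts: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass
class GapCurve:
    """Gap statistic over k = 1..kmax with reference-set dispersion."""

    k_values: np.ndarray
    log_wk: np.ndarray           # observed log W_k
    log_wstar_mean: np.ndarray   # mean over B reference sets of log W*_kb
    log_wstar_sd: np.ndarray     # sd over the reference sets
    gap: np.ndarray              # log_wstar_mean - log_wk
    s: np.ndarray                # sd * sqrt(1 + 1/B)
    n_reference: int


@dataclass
class ClusterModel:
    """Sex-stratified cluster model for one cohort.

    Centroids are stored per sex in z-space, already permuted into the
    unified cluster order (male solution order; the female solution is
    aligned to it by minimal-cost centroid matching, recorded in
    ``merge_permutation``). ``archetypes`` maps unified cluster index to
    archetype name once naming has been performed.
    """

    cohort_id: str
    k: int
    scalers: dict[str, Scaler]
    centroids: dict[str, np.ndarray]
    merge_permutation: list[int]
    seed: int
    variables: tuple[str, ...] = CLUSTERING_VARIABLES
    archetypes: dict[int, str] | None = None
    training_assignment: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if sorted(self.merge_permutation) != list(range(self.k)):
            raise ValueError("merge permutation must be a bijection on 0..k-1")
        for sex, c in self.centroids.items():
            if c.shape[0] != self.k:
                raise ValueError(f"{sex} centroids do not have k={self.k} rows")

    def to_json(self, path=None) -> str:
        from . import __version__

        payload = {
            "cohort_id": self.cohort_id,
            "k": self.k,
            "variables": list(self.variables),
            "seed": self.seed,
            "software_version": __version__,
            "merge_permutation": list(map(int, self.merge_permutation)),
            "scalers": {
                sex: {"mean": s.mean.tolist(), "sd": s.sd.tolist()}
                for sex, s in self.scalers.items()
            },
            "centroids": {sex: c.tolist() for sex, c in self.centroids.items()},
            # serialized cluster ids are 1-based
            "archetypes": (
                {str(i + 1): a for i, a in self.archetypes.items()}
                if self.archetypes else None
            ),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClusterModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            cohort_id=payload["cohort_id"],
            k=payload["k"],
            scalers={
                sex: Scaler(np.array(s["mean"]), np.array(s["sd"]),
                            tuple(payload["variables"]))
                for sex, s in payload["scalers"].items()
            },
            centroids={sex: np.array(c) for sex, c in payload["centroids"].items()},
            merge_permutation=list(payload["merge_permutation"]),
            seed=payload["seed"],
            variables=tuple(payload["variables"]),
            archetypes=(
                {int(i) - 1: a for i, a in payload["archetypes"].items()}
                if payload.get("archetypes") else None
            ),
        )


def sex_matrix(cohort: Cohort, sex: str) -> tuple[list[str], np.ndarray]:
    """Subject ids and (n, 5) value matrix for complete-case subjects of a sex."""
    ids, rows = [], []
    for s in cohort:
        if s.sex == sex and s.has_complete_clustering_variables:
            ids.append(s.subject_id)
            rows.append(s.clustering_values())
    return ids, np.asarray(rows, dtype=float).reshape(len(ids), 5)


def standardize(cohort: Cohort, sex: str) -> tuple[np.ndarray, Scaler]:
    """Z-score the five clustering variables for one sex of one cohort.

    Uses the population (ddof=0) standard deviation; each returned column has
    mean 0 and sd 1 to within 1e-10.
    """
    _, X = sex_matrix(cohort, sex)
    if X.shape[0] < 2:
        raise ValueError(f"need >= 2 complete-case subjects of sex {sex!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = CLUSTERING_VARIABLES[int(np.argmin(sd))]
        raise ValueError(f"zero-variance clustering variable {bad!r}")
    return (X - mean) / sd, Scaler(mean, sd)


def kmeans_restarts(X: np.ndarray, k: int, n_restarts: int = 100,
                    seed: int = 0, max_iter: int = 300) -> KmeansSolution:
    """Best of ``n_restarts`` Lloyd k-means runs with random-point init.

    Deterministic given ``seed``; returns the restart with the minimal total
    within-cluster sum of squared Euclidean distances. Exact distance ties in
    assignment go to the lowest cluster index.
    """
    X = np.asarray(X, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds number of distinct rows ({n_distinct})")
    km = KMeans(
        n_clusters=k, init="random", n_init=n_restarts, max_iter=max_iter,
        algorithm="lloyd", random_state=derive_seed(seed, "kmeans", k),
    ).fit(X)
    return KmeansSolution(
        centroids=km.cluster_centers_.copy(),
        assignment=km.labels_.copy(),
        objective=float(km.inertia_),
        n_iter=int(km.n_iter_),
        n_restarts=n_restarts,
    )


def gap_statistic(X: np.ndarray, kmax: int, B: int = 50, seed: int = 0,
                  n_restarts: int = 10) -> GapCurve:
    """Gap statistic with a uniform-over-column-range reference distribution.

    For each k in 1..kmax, ``Gap(k) = mean_b log W*_kb - log W_k`` where the
    B reference sets are drawn uniformly over the observed per-column range
    (the simplest Tibshirani reference), and ``s_k = sd_b(log W*_kb) *
    sqrt(1 + 1/B)``.
    """
    X = np.asarray(X, dtype=float)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")

    def log_w(data: np.ndarray, k: int, fit_seed: int) -> float:
        sol = kmeans_restarts(data, k, n_restarts=n_restarts, seed=fit_seed)
        return float(np.log(max(sol.objective, 1e-300)))

    ks = np.arange(1, kmax + 1)
    log_wk = np.array([log_w(X, k, derive_seed(seed, "obs", k)) for k in ks])

    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = np.random.default_rng(derive_seed(seed, "reference"))
    log_wstar = np.empty((B, kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            log_wstar[b, j] = log_w(ref, k, derive_seed(seed, "ref", b, k))

    mean_star = log_wstar.mean(axis=0)
    sd_star = log_wstar.std(axis=0, ddof=0)
    return GapCurve(
        k_values=ks,
        log_wk=log_wk,
        log_wstar_mean=mean_star,
        log_wstar_sd=sd_star,
        gap=mean_star - log_wk,
        s=sd_star * np.sqrt(1.0 + 1.0 / B),
        n_reference=B,
    )


def select_k(curve: GapCurve, rule: str = "one_se",
             flatten_eps: float = 0.25) -> int:
    """Choose the number of clusters from a gap curve.

    ``one_se``: smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}`` (the
    standard Tibshirani rule; valid under the null of one cluster).

    ``flatten``: smallest k whose forward increment ``Gap(k+1) - Gap(k)``
    drops below ``flatten_eps`` times the largest forward increment -- the
    point where the curve flattens with little added value of increasing k.
    This rule presumes a structured (rising-then-flat) curve.
    """
    gap, s = curve.gap, curve.s
    kmax = len(gap)
    if rule == "one_se":
        for j in range(kmax - 1):
            if gap[j] >= gap[j + 1] - s[j + 1]:
                return int(curve.k_values[j])
        return int(curve.k_values[-1])
    if rule == "flatten":
        inc = np.diff(gap)
        threshold = flatten_eps * inc.max()
        for j, step in enumerate(inc):
            if step < threshold:
                return int(curve.k_values[j])
        return int(curve.k_values[-1])
    raise ValueError(f"unknown rule {rule!r}")


def merge_sexes(centroids_a: np.ndarray, centroids_b: np.ndarray) -> list[int]:
    """Match two centroid sets; ``perm[i]`` is the b-row paired with a-row i.

    Minimises the total squared Euclidean distance between matched pairs,
    optimal over all k! pairings (Hungarian algorithm; the cost is additive
    over pairs, for which the assignment solution is exact).
    """
    a = np.asarray(centroids_a, dtype=float)
    b = np.asarray(centroids_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("centroid sets must have identical shape")
    cost = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(a.shape[0], dtype=int)
    perm[rows] = cols
    return perm.tolist()


def fit_sex_stratified(cohort: Cohort, k: int, n_restarts: int = 100,
                       seed: int = 0, min_per_sex: int | None = None) -> ClusterModel:
    """Fit per-sex k-means and merge the solutions into one cohort model.

    Each sex is standardized and clustered independently; the female
    solution's clusters are then aligned to the male solution's by
    minimal-cost centroid matching so that every subject carries a unified
    cluster id (recorded in ``training_assignment``).
    """
    floor = min_per_sex if min_per_sex is not None else 10 * k
    per_sex: dict[str, dict] = {}
    for sex in _SEXES:
        ids, _ = sex_matrix(cohort, sex)
        if len(ids) < floor:
            raise ValueError(
                f"cohort {cohort.cohort_id}: {len(ids)} complete-case "
                f"{sex} subjects < floor {floor}")
        Z, scaler = standardize(cohort, sex)
        sol = kmeans_restarts(Z, k, n_restarts=n_restarts,
                              seed=derive_seed(seed, cohort.cohort_id, sex))
        per_sex[sex] = {"ids": ids, "scaler": scaler, "solution": sol}

    male_sol: KmeansSolution = per_sex["male"]["solution"]
    female_sol: KmeansSolution = per_sex["female"]["solution"]
    perm = merge_sexes(male_sol.centroids, female_sol.centroids)
    inverse = {perm[i]: i for i in range(k)}

    assignment: dict[str, int] = {}
    for sid, label in zip(per_sex["male"]["ids"], male_sol.assignment):
        assignment[sid] = int(label)
    for sid, label in zip(per_sex["female"]["ids"], female_sol.assignment):
        assignment[sid] = inverse[int(label)]

    return ClusterModel(
        cohort_id=cohort.cohort_id,
        k=k,
        scalers={sex: per_sex[sex]["scaler"] for sex in _SEXES},
        centroids={
            "male": male_sol.centroids.copy(),
            "female": female_sol.centroids[np.asarray(perm)],
        },
        merge_permutation=list(perm),
        seed=seed,
        archetypes=None,
        training_assignment=assignment,
    )
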