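"""Polarity-invariant modified k-means microstate clustering.

Microstate clustering differs from vanilla k-means in two ways: a scalp map
and its polarity reversal are the same state, so peaks are assigned by
maximal *squared* spatial correlation; and the cluster "mean" is the
dominant spatial pattern of the assigned peaks — the first principal
component of their outer-product sum — rather than an arithmetic average
that would cancel across polarities.  The objective is the global explained
variance (GEV): the GFP-weighted fraction of peak-map variance captured by
the winning template.  Both alternating steps are coordinate ascent on GEV,
so iterations converge monotonically.

`ModifiedKMeans` is a scikit-learn estimator (fit / predict / transform);
`cluster_across_k`, `select_k_metacriterion` and `two_level_clustering`
implement the two-level subject->group procedure with map merging and a
median-vote meta-criterion for the number of maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.utils import check_random_state

from .exceptions import InvalidArgumentError, UndefinedCorrelationError
from .io import Recording
from .preproc import gfp, gfp_peaks

__all__ = [
    "TemplateMaps",
    "ClusteringRun",
    "spatial_correlation",
    "ModifiedKMeans",
    "modified_kmeans",
    "cluster_across_k",
    "select_k_metacriterion",
    "two_level_clustering",
    "match_templates",
]

MAP_LETTERS = "ABCDEFGHIJKL"


@dataclass
class TemplateMaps:
    """A set of k unit-norm, average-referenced template topographies."""

    maps: np.ndarray
    labels: list[str] = field(default_factory=list)
    gev_total: float = np.nan

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not self.labels:
            self.labels = [MAP_LETTERS[i] for i in range(self.maps.shape[0])]

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class ClusteringRun:
    """Audit record of one best-of-restarts fit at a fixed k."""

    k: int
    restarts: int
    gev: float
    assignment: np.ndarray
    templates: np.ndarray
    dispersion: float
    criterion_values: dict = field(default_factory=dict)
    peak_maps: np.ndarray | None = None


def spatial_correlation(u: np.ndarray, v: np.ndarray, ignore_polarity: bool = True) -> float:
    """Pearson correlation across channels of two average-referenced maps
    (absolute value when polarity is ignored)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidArgumentError("maps must have equal channel counts")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = np.linalg.norm(uc)
    nv = np.linalg.norm(vc)
    if nu < 1e-15 or nv < 1e-15:
        raise UndefinedCorrelationError("spatial correlation undefined for a flat map")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if ignore_polarity else r


def _center_norm(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-reference rows; return (centered, unit-norm rows, norms)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    if np.any(norms < 1e-12):
        raise UndefinedCorrelationError("peak maps must have non-zero spatial variance")
    return Xc, Xc / norms[:, None], norms


def _principal_pattern(Xc: np.ndarray) -> np.ndarray:
    """Unit-norm dominant eigenvector of sum_i x_i x_i^T for rows of Xc."""
    n, c = Xc.shape
    if n == 1:
        return Xc[0] / np.linalg.norm(Xc[0])
    if n <= c:
        g = Xc @ Xc.T
        w, u = np.linalg.eigh(g)
        v = Xc.T @ u[:, -1]
    else:
        w, u = np.linalg.eigh(Xc.T @ Xc)
        v = u[:, -1]
    nrm = np.linalg.norm(v)
    if nrm < 1e-15:
        v = Xc[0].copy()
        nrm = np.linalg.norm(v)
    return v / nrm


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-invariant modified k-means over GFP-peak topographies.

    Parameters
    ----------
    n_clusters : number of template maps k.
    n_init : random restarts; the restart with the highest GEV wins.
    max_iter, tol : per-restart convergence control (GEV improvement < tol).
    random_state : seed for restart initialization (peaks sampled without
        replacement as initial templates).

    Attributes (after fit)
    ----------------------
    cluster_centers_ : (k, C) unit-norm average-referenced templates.
    labels_ : winning template per training peak.
    gev_ : global explained variance of the training peaks, in [0, 1].
    dispersion_ : GFP-weighted unexplained variance (criterion ingredient).
    """

    def __init__(
        self,
        n_clusters: int = 4,
        n_init: int = 300,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _fit_once(self, Xc, Xn, w2, templates):
        k = self.n_clusters
        T = templates.copy()
        total = w2.sum()
        prev_gev = -np.inf
        labels = None
        for _ in range(self.max_iter):
            corr = Xn @ T.T
            labels = np.argmax(np.abs(corr), axis=1)
            fit = np.abs(corr[np.arange(len(labels)), labels])
            # re-seed empty clusters from worst-fit peaks; iterate because a
            # reseed can steal the only member of another cluster
            while True:
                present = np.bincount(labels, minlength=k) > 0
                missing = np.flatnonzero(~present)
                if missing.size == 0:
                    break
                for j in missing:
                    worst = int(np.argmin(fit))
                    labels[worst] = j
                    fit[worst] = np.inf  # never reseed the same peak twice
            for j in range(k):
                T[j] = _principal_pattern(Xc[labels == j])
            corr = Xn @ T.T
            labels = np.argmax(np.abs(corr), axis=1)
            r = corr[np.arange(len(labels)), labels]
            gev = float(w2 @ r**2 / total)
            if gev - prev_gev < self.tol:
                prev_gev = max(prev_gev, gev)
                break
            prev_gev = gev
        return prev_gev, labels, T

    def fit(self, X, y=None, init_templates: list[np.ndarray] | None = None):
        """Fit templates to peak maps X (n_peaks x n_channels).

        ``init_templates`` optionally adds deterministic warm starts (each a
        (k, C) array) on top of the random restarts.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidArgumentError("X must be 2-D (peaks x channels)")
        n, c = X.shape
        k = self.n_clusters
        if k < 1:
            raise InvalidArgumentError("n_clusters must be >= 1")
        if n < k:
            raise InvalidArgumentError(f"need at least k={k} peaks, got {n}")
        Xc, Xn, norms = _center_norm(X)
        w2 = norms**2
        rs = check_random_state(self.random_state)
        starts: list[np.ndarray] = []
        for _ in range(max(1, self.n_init)):
            idx = rs.choice(n, size=k, replace=False)
            starts.append(Xn[idx].copy())
        for T0 in init_templates or []:
            T0 = np.asarray(T0, dtype=float)
            T0c = T0 - T0.mean(axis=1, keepdims=True)
            starts.append(T0c / np.linalg.norm(T0c, axis=1, keepdims=True))
        best = (-np.inf, None, None)
        for T0 in starts:
            gev, labels, T = self._fit_once(Xc, Xn, w2, T0)
            if gev > best[0]:
                best = (gev, labels, T)
        self.gev_, self.labels_, self.cluster_centers_ = best
        corr = Xn @ self.cluster_centers_.T
        r = corr[np.arange(n), self.labels_]
        self.dispersion_ = float(w2 @ (1.0 - r**2))
        self.n_features_in_ = c
        return self

    def predict(self, X):
        """Winning template index per map (maximal absolute correlation)."""
        _, Xn, _ = _center_norm(np.asarray(X, dtype=float))
        return np.argmax(np.abs(Xn @ self.cluster_centers_.T), axis=1)

    def transform(self, X):
        """Polarity-invariant correlation distances 1 - |r| to each template."""
        _, Xn, _ = _center_norm(np.asarray(X, dtype=float))
        return 1.0 - np.abs(Xn @ self.cluster_centers_.T)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def modified_kmeans(
    peak_maps: np.ndarray,
    k: int,
    restarts: int = 300,
    seed: int | None = None,
    init_templates: list[np.ndarray] | None = None,
) -> tuple[ClusteringRun, TemplateMaps]:
    """Functional wrapper over :class:`ModifiedKMeans`."""
    est = ModifiedKMeans(n_clusters=k, n_init=restarts, random_state=seed)
    est.fit(peak_maps, init_templates=init_templates)
    run = ClusteringRun(
        k=k,
        restarts=restarts,
        gev=est.gev_,
        assignment=est.labels_,
        templates=est.cluster_centers_,
        dispersion=est.dispersion_,
        peak_maps=np.asarray(peak_maps, dtype=float),
    )
    return run, TemplateMaps(maps=est.cluster_centers_, gev_total=est.gev_)


def cluster_across_k(
    peak_maps: np.ndarray,
    k_range=range(1, 13),
    restarts: int = 300,
    seed: int | None = None,
) -> dict[int, ClusteringRun]:
    """Best-of-restarts fits for a contiguous k range.

    Each k is additionally warm-started from the previous k's solution plus
    the worst-fit peak, which makes GEV non-decreasing in k.
    """
    ks = sorted(k_range)
    X = np.asarray(peak_maps, dtype=float)
    Xc, Xn, _ = _center_norm(X)
    runs: dict[int, ClusteringRun] = {}
    prev: ClusteringRun | None = None
    for k in ks:
        warm = None
        if prev is not None and prev.k == k - 1:
            corr = Xn @ prev.templates.T
            fit = np.max(np.abs(corr), axis=1)
            extra = Xn[int(np.argmin(fit))]
            warm = [np.vstack([prev.templates, extra])]
        run, _ = modified_kmeans(X, k, restarts=restarts, seed=seed, init_templates=warm)
        runs[k] = run
        prev = run
    return runs


def _median_lower(values: list[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def select_k_metacriterion(runs: dict[int, ClusteringRun]) -> int:
    """Median vote over five internal validity criteria.

    Criteria: silhouette on 1-|r| distance (max), Calinski-Harabasz and
    Davies-Bouldin on polarity-aligned peaks, Krzanowski-Lai on the
    GFP-weighted dispersion curve, and the cross-validation criterion
    (residual variance penalized by the degrees of freedom spent on k
    templates).  Each criterion nominates its optimal k; the winner is the
    (lower) median of the nominations.  Every criterion value is stored in
    the runs' ``criterion_values`` for audit.
    """
    if len(runs) < 2:
        raise InvalidArgumentError("need fits for at least 2 candidate k values")
    ks = sorted(runs)
    k_min = ks[0]
    if runs[k_min].peak_maps is None:
        raise InvalidArgumentError("runs must carry their peak maps")
    # degenerate single-pattern data: nothing left to explain at the smallest k
    if runs[k_min].gev >= 1.0 - 1e-9:
        return k_min
    X = runs[ks[0]].peak_maps
    Xc, Xn, norms = _center_norm(X)
    n, c = Xn.shape
    # deterministic subsample for the O(n^2) silhouette distance matrix
    sub = np.linspace(0, n - 1, num=min(n, 400)).astype(int)
    dist = 1.0 - np.abs(Xn[sub] @ Xn[sub].T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)

    sil: dict[int, float] = {}
    ch: dict[int, float] = {}
    db: dict[int, float] = {}
    w = {k: runs[k].dispersion for k in ks}
    for k in ks:
        run = runs[k]
        corr = Xn @ run.templates.T
        labels = np.argmax(np.abs(corr), axis=1)
        signs = np.sign(corr[np.arange(n), labels])
        aligned = Xn * signs[:, None]
        vals: dict[str, float] = {"gev": run.gev, "dispersion": run.dispersion}
        if k >= 2 and len(np.unique(labels[sub])) >= 2:
            sil[k] = float(silhouette_score(dist, labels[sub], metric="precomputed"))
            ch[k] = float(calinski_harabasz_score(aligned, labels))
            db[k] = float(davies_bouldin_score(aligned, labels))
            vals.update(silhouette=sil[k], calinski_harabasz=ch[k], davies_bouldin=db[k])
        run.criterion_values = vals

    def argbest(scores: dict[int, float], maximize: bool) -> int | None:
        if not scores:
            return None
        best_k, best_v = None, None
        for k in sorted(scores):  # ascending k: ties resolve to the smaller k
            v = scores[k]
            if best_v is None or (v > best_v if maximize else v < best_v):
                best_k, best_v = k, v
        return best_k

    votes: list[int] = []
    for scores, maximize in ((sil, True), (ch, True), (db, False)):
        k_opt = argbest(scores, maximize)
        if k_opt is not None:
            votes.append(k_opt)
    # Krzanowski-Lai on the dispersion curve
    diff = {
        k: (k - 1) ** (2 / c) * w[k - 1] - k ** (2 / c) * w[k]
        for k in ks
        if (k - 1) in w
    }
    kl = {
        k: abs(diff[k]) / abs(diff[k + 1])
        for k in ks
        if k in diff and (k + 1) in diff and abs(diff[k + 1]) > 1e-30
    }
    k_opt = argbest(kl, maximize=True)
    if k_opt is not None:
        votes.append(k_opt)
        for k, v in kl.items():
            runs[k].criterion_values["krzanowski_lai"] = v
    # cross-validation criterion: residual variance x df penalty
    cv = {
        k: (w[k] / (n * (c - 1))) * ((c - 1) / (c - 1 - k)) ** 2
        for k in ks
        if k < c - 1
    }
    k_opt = argbest(cv, maximize=False)
    if k_opt is not None:
        votes.append(k_opt)
        for k, v in cv.items():
            runs[k].criterion_values["cv_criterion"] = v
    if not votes:
        return k_min
    return _median_lower(votes)


def match_templates(candidates: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair candidate maps with reference maps maximizing total |r|
    (Hungarian assignment).  Returns (column index per reference row,
    matched absolute correlations)."""
    cand = np.atleast_2d(candidates)
    ref = np.atleast_2d(reference)
    _, cn, _ = _center_norm(cand)
    _, rn, _ = _center_norm(ref)
    absr = np.abs(rn @ cn.T)
    rows, cols = linear_sum_assignment(-absr)
    return cols, absr[rows, cols]


def _merge_maps(
    templates: np.ndarray, weights: np.ndarray, threshold: float
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Greedily merge template pairs with |r| >= threshold into their
    weighted dominant pattern."""
    maps = [t.copy() for t in templates]
    wts = list(np.asarray(weights, dtype=float))
    events: list[tuple[int, int, float]] = []
    while len(maps) > 1:
        arr = np.asarray(maps)
        corr = np.abs(arr @ arr.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            break
        i, j = min(i, j), max(i, j)
        stacked = np.vstack(
            [maps[i] * np.sqrt(wts[i]), maps[j] * np.sqrt(wts[j])]
        )
        merged = _principal_pattern(stacked)
        events.append((int(i), int(j), float(corr[i, j])))
        maps[i] = merged
        wts[i] = wts[i] + wts[j]
        del maps[j], wts[j]
    return np.asarray(maps), events


def two_level_clustering(
    recordings: list[Recording],
    k_range=range(1, 13),
    merge_threshold: float = 0.80,
    restarts: int = 300,
    subject_restarts: int | None = None,
    subject_k: int | None = None,
    seed: int | None = None,
    min_peak_distance: int = 1,
) -> tuple[TemplateMaps, dict]:
    """Two-level (subject -> group) microstate clustering.

    Per subject, GFP-peak maps are clustered and the per-subject
    meta-criterion (or a fixed ``subject_k``) picks that subject's template
    count.  All subject templates are then pooled as input samples to a
    group-level modified k-means whose k is again chosen by meta-criterion;
    group maps correlated at ``merge_threshold`` or above are merged.

    Returns the group ``TemplateMaps`` and an audit dict (per-k GEV and
    criterion values, subject template counts, merge events).
    """
    if len(recordings) < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    if subject_restarts is None:
        subject_restarts = restarts
    subject_templates: list[np.ndarray] = []
    subject_ks: dict[str, int] = {}
    skipped: list[str] = []
    for rec in recordings:
        series = gfp(rec)
        peaks = gfp_peaks(series, min_separation_samples=min_peak_distance)
        if peaks.size == 0:
            warnings.warn(f"subject {rec.subject_id!r} has no GFP peaks; skipped")
            skipped.append(rec.subject_id)
            continue
        data = rec.data - rec.data.mean(axis=0, keepdims=True)
        peak_maps = data[:, peaks].T
        if subject_k is not None:
            run, _ = modified_kmeans(peak_maps, subject_k, restarts=subject_restarts, seed=seed)
            k_sub = subject_k
        else:
            k_max = min(max(k_range), max(2, peaks.size))
            runs = cluster_across_k(
                peak_maps, range(min(k_range), k_max + 1), restarts=subject_restarts, seed=seed
            )
            k_sub = select_k_metacriterion(runs)
            run = runs[k_sub]
        subject_ks[rec.subject_id] = k_sub
        subject_templates.append(run.templates)
    if not subject_templates:
        raise RuntimeError("all subjects were skipped: no usable GFP peaks")
    pooled = np.vstack(subject_templates)
    k_max = min(max(k_range), pooled.shape[0])
    group_runs = cluster_across_k(pooled, range(min(k_range), k_max + 1), restarts=restarts, seed=seed)
    k_group = select_k_metacriterion(group_runs)
    group_run = group_runs[k_group]
    counts = np.bincount(group_run.assignment, minlength=k_group).astype(float)
    merged, merge_events = _merge_maps(group_run.templates, counts, merge_threshold)
    est = ModifiedKMeans(n_clusters=merged.shape[0], n_init=1, random_state=seed)
    # one refit pass from the merged maps to report a consistent group GEV
    est.fit(pooled, init_templates=[merged])
    templates = TemplateMaps(maps=est.cluster_centers_, gev_total=est.gev_)
    audit = {
        "k_group": int(merged.shape[0]),
        "k_group_premerge": int(k_group),
        "subject_k": subject_ks,
        "skipped_subjects": skipped,
        "merge_events": merge_events,
        "group_gev": float(est.gev_),
        "gev_by_k": {int(k): float(r.gev) for k, r in group_runs.items()},
        "criterion_values": {int(k): r.criterion_values for k, r in group_runs.items()},
    }
    return templates, audit
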