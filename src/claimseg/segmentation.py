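"""Partitional clustering and choice of the number of clusters.

Lloyd's k-means with random-partition initialisation (each observation
is first assigned to one of k clusters at random, centroids are the
means of those random groups, and the algorithm alternates reassignment
and centroid updates until assignments are stable).  Multiple restarts
keep the best (lowest within-cluster SSE) solution; empty clusters are
repaired by reseeding the empty centroid at the point farthest from its
current centroid.

The number of clusters is chosen over a grid (default 2..20) with a
jump criterion on the partial-F statistic

    F(k) = ((SSE_{k-1} - SSE_k) / p) / (SSE_k / (n - k p))

the mean-square improvement from adding the k-th cluster over the
residual mean square (p coordinates per centroid).  F decreases in k
once real structure is exhausted; the selected k is the one whose F
drops the most relative to the next transition (the elbow of the
partial-F curve).  A Sugar-James style distortion-jump criterion
(transformed distortion d^(-p/2)) is available as an alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort_features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """A fitted k-means partition (cluster ids are 1-based)."""

    k: int
    centroids: np.ndarray  # (k, p)
    assignments: np.ndarray  # (n,), values in 1..k
    within_sse: float
    n_iter: int
    seed: int
    sse_history: list[float] = field(default_factory=list)
    row_ids: list[str] | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k": self.k,
            "seed": self.seed,
            "within_sse": self.within_sse,
            "n_iter": self.n_iter,
            "centroids": self.centroids.tolist(),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, features: FeatureMatrix) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        centroids = np.asarray(d["centroids"], dtype=float)
        labels = assign_to_centroids(features.values, centroids)
        sse = float(((features.values - centroids[labels - 1]) ** 2).sum())
        return cls(k=d["k"], centroids=centroids, assignments=labels,
                   within_sse=sse, n_iter=d["n_iter"], seed=d["seed"],
                   row_ids=features.row_ids)


def _as_array(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    return X


def assign_to_centroids(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Nearest-centroid labels, 1-based."""
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1


def _sq_dists(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x||^2 - 2 x.c + ||c||^2 ; clip tiny negatives from cancellation
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids ** 2).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _centroids_from_labels(X: np.ndarray, labels0: np.ndarray, k: int) -> np.ndarray:
    p = X.shape[1]
    cent = np.zeros((k, p))
    for c in range(k):
        mask = labels0 == c
        if mask.any():
            cent[c] = X[mask].mean(axis=0)
    return cent


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
           ) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    n, p = X.shape
    k = centroids.shape[0]
    centroids = centroids.copy()
    labels0 = np.full(n, -1)
    history: list[float] = []
    sse = np.inf
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, centroids)
        new_labels = d2.argmin(axis=1)
        point_d2 = d2[np.arange(n), new_labels]
        # repair empty clusters: reseed at the point farthest from its centroid
        for c in range(k):
            if not (new_labels == c).any():
                far = int(point_d2.argmax())
                new_labels[far] = c
                point_d2[far] = 0.0
        centroids = _centroids_from_labels(X, new_labels, k)
        new_sse = float(((X - centroids[new_labels]) ** 2).sum())
        if history and new_sse > history[-1] + 1e-9 * max(history[-1], 1.0):
            raise AssertionError(
                f"Lloyd iteration increased SSE: {history[-1]} -> {new_sse}")
        history.append(new_sse)
        converged = (new_labels == labels0).all() or (
            np.isfinite(sse) and sse - new_sse <= tol * max(sse, 1e-300))
        labels0 = new_labels
        sse = new_sse
        if converged:
            break
    return labels0, centroids, sse, len(history), history


def fit_kmeans(
    features: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: str = "random-partition",
    initial_centroids: np.ndarray | None = None,
) -> ClusterModel:
    """Best-of-restarts Lloyd k-means.

    ``init`` is ``"random-partition"`` (default) or ``"kmeans++"``.  An
    explicit ``initial_centroids`` array overrides both and runs a single
    deterministic Lloyd descent.
    """
    X = _as_array(features)
    n, p = X.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n={n}], got {k}")
    if k == 1 or initial_centroids is not None:
        n_restarts = 1

    best = None
    master = np.random.default_rng(seed)
    for r in range(n_restarts):
        rng = np.random.default_rng(master.integers(2 ** 31))
        if initial_centroids is not None:
            cent0 = np.asarray(initial_centroids, dtype=float)
            if cent0.shape != (k, p):
                raise ValueError(f"initial_centroids must be ({k}, {p})")
        elif k == 1:
            cent0 = X.mean(axis=0, keepdims=True)
        elif init == "random-partition":
            labels0 = rng.integers(0, k, n)
            # guarantee every cluster starts nonempty
            labels0[rng.choice(n, size=k, replace=False)] = np.arange(k)
            cent0 = _centroids_from_labels(X, labels0, k)
        elif init == "kmeans++":
            from sklearn.cluster import kmeans_plusplus
            cent0, _ = kmeans_plusplus(X, k, random_state=int(rng.integers(2 ** 31)))
        else:
            raise ValueError(f"unknown init {init!r}")
        labels, cent, sse, n_iter, history = _lloyd(X, cent0, max_iter, tol)
        if best is None or sse < best[2]:
            best = (labels, cent, sse, n_iter, history)

    labels, cent, sse, n_iter, history = best
    row_ids = features.row_ids if isinstance(features, FeatureMatrix) else None
    return ClusterModel(k=k, centroids=cent, assignments=labels + 1,
                        within_sse=sse, n_iter=n_iter, seed=seed,
                        sse_history=history, row_ids=row_ids)


def partial_f(sse_k: float, sse_k_plus_1: float, n: int, k: int, p: int) -> float:
    """Partial-F statistic for the transition k -> k+1 clusters.

    ((SSE_k - SSE_{k+1}) / p) / (SSE_{k+1} / (n - (k+1) p)): the per-
    coordinate mean-square improvement from the added cluster over the
    residual mean square.  Returns +inf when the finer model fits exactly.
    """
    if sse_k < sse_k_plus_1 - 1e-9 * max(sse_k, 1.0) or sse_k_plus_1 < 0:
        raise ValueError(f"need sse_k >= sse_k+1 >= 0, got {sse_k}, {sse_k_plus_1}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1, got n={n}, k={k}")
    if sse_k_plus_1 == 0:
        return float("inf")
    dof = n - (k + 1) * p
    if dof <= 0:
        raise ValueError(f"nonpositive residual dof: n={n}, k+1={k + 1}, p={p}")
    return ((sse_k - sse_k_plus_1) / p) / (sse_k_plus_1 / dof)


@dataclass
class KSelectionCurve:
    """Model-selection diagnostics over the k grid.

    ``partial_f_by_k[i]`` is the partial-F for the transition
    ``k_grid[i]-1 -> k_grid[i]`` (the improvement achieved on reaching
    that k); a baseline fit at ``k_grid[0]-1`` anchors the first entry.
    """

    k_grid: list[int]
    sse_by_k: list[float]
    partial_f_by_k: list[float]
    selected_k: int
    criterion: str
    baseline_sse: float  # SSE at k_grid[0]-1

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"k": self.k_grid, "sse": self.sse_by_k,
                      "partial_f": self.partial_f_by_k}).to_csv(
            path, index=False, float_format="%.10g")


def select_k(
    features: FeatureMatrix | np.ndarray,
    k_grid: list[int] | range = range(2, 21),
    seed: int = 0,
    n_restarts: int = 10,
    criterion: str = "partial_f_jump",
    max_iter: int = 300,
    tol: float = 1e-6,
) -> KSelectionCurve:
    """Fit over the k grid and pick the k where the improvement jumps most.

    For ``partial_f_jump`` (default), the elbow of the partial-F curve is
    read scale-free: restrict to transitions whose F clearly exceeds the
    noise floor (at least twice the median F over the grid — beyond the
    true k the statistic hovers around that floor), then select the k
    with the largest relative collapse ``F(k) / F(k+1)``: improvement is
    still strong on reaching k and falls away immediately after.  The
    last grid point is never selected; widen the grid if the curve has
    not flattened.  ``distortion_jump`` instead maximises
    ``d_k^(-p/2) - d_{k-1}^(-p/2)`` with d the mean per-point distortion.

    Monotone non-increase of SSE in k is guaranteed by warm-starting each
    k with the previous best centroids plus the farthest point, in
    addition to the random restarts.
    """
    X = _as_array(features)
    n, p = X.shape
    k_grid = list(k_grid)
    if any(b - a != 1 for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be contiguous increasing integers")
    if k_grid[0] < 2 or k_grid[-1] >= n:
        raise ValueError(f"k_grid must lie within [2, n-1], got {k_grid}")

    k0 = k_grid[0] - 1
    base_model = fit_kmeans(X, k0, seed=seed, n_restarts=n_restarts,
                            max_iter=max_iter, tol=tol)
    baseline_sse = base_model.within_sse
    prev_model = base_model

    models: dict[int, "ClusterModel"] = {}
    sse_by_k: list[float] = []
    for k in k_grid:
        model = fit_kmeans(X, k, seed=seed + k, n_restarts=n_restarts,
                           max_iter=max_iter, tol=tol)
        # warm start from the previous best: guarantees SSE(k) <= SSE(k-1)
        far = int(_sq_dists(X, prev_model.centroids)[
            np.arange(n), prev_model.assignments - 1].argmax())
        warm_cent = np.vstack([prev_model.centroids, X[far]])
        warm = fit_kmeans(X, k, seed=seed + k, initial_centroids=warm_cent,
                          max_iter=max_iter, tol=tol)
        if warm.within_sse < model.within_sse:
            model = warm
        models[k] = model
        sse_by_k.append(model.within_sse)
        prev_model = model

    f_by_k = []
    prev_sse = baseline_sse
    for k, sse in zip(k_grid, sse_by_k):
        f_by_k.append(partial_f(prev_sse, sse, n, k - 1, p))
        prev_sse = sse

    if criterion == "partial_f_jump":
        if len(k_grid) == 1:
            selected = k_grid[0]
        else:
            f = np.array(f_by_k)
            finite = f[np.isfinite(f)]
            floor = float(np.median(finite)) if len(finite) else 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = f[:-1] / f[1:]
            # inf/inf (both transitions fit exactly): no collapse
            ratios = np.nan_to_num(ratios, nan=0.0, posinf=np.inf)
            eligible = f[:-1] >= 2.0 * floor
            if eligible.any():
                idx = np.flatnonzero(eligible)
                selected = k_grid[int(idx[np.argmax(ratios[idx])])]
            else:
                selected = k_grid[int(np.argmax(ratios))]
    elif criterion == "distortion_jump":
        d = np.array([baseline_sse] + sse_by_k) / (n * p)
        with np.errstate(divide="ignore", over="ignore"):
            td = np.power(d, -p / 2.0)
        jumps = td[1:] - td[:-1]
        selected = k_grid[int(np.argmax(jumps))]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    logger.info("select_k: selected k=%d by %s over grid %s", selected, criterion, k_grid)
    return KSelectionCurve(k_grid=k_grid, sse_by_k=sse_by_k, partial_f_by_k=f_by_k,
                           selected_k=selected, criterion=criterion,
                           baseline_sse=baseline_sse)
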