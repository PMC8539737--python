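"""Bootstrap cluster-stability assessment.

Because k-means labels are arbitrary, a refit on a bootstrap resample
must first be aligned with the reference partition before membership can
be compared.  Alignment is by Cohen's kappa: for every (original,
replicate) label pair the chance-corrected agreement of the two binary
membership indicators is computed, and the one-to-one relabeling that
maximises total kappa is found by optimal assignment on the k x k kappa
matrix.

Two per-cluster indices are then reported over replicates:

* Rand-style observed agreement — the percentage of patients on which
  the two binary membership indicators for cluster c agree (in/in or
  out/out);
* Jaccard overlap — intersection over union of the two membership sets,
  a stricter measure that ignores the (usually large) both-out cell.

Jaccard <= agreement always holds for binary membership, so the Jaccard
column is the sensitive one.  These are per-cluster binary-membership
indices, not the pair-counting Rand index over whole partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cohort_features import FeatureMatrix
from .segmentation import ClusterModel, assign_to_centroids, fit_kmeans

logger = logging.getLogger(__name__)


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two binary vectors.

    Degenerate tables: when both raters are constant, kappa is 1 if they
    agree everywhere and 0 otherwise (the usual 0/0 is resolved by
    convention rather than returned as NaN).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("cohen_kappa: need two equal-length 1-D vectors")
    n = len(a)
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0 - 1e-15:  # both constant
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def match_labels(original: np.ndarray, replicate: np.ndarray, k: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Kappa-maximising one-to-one alignment of replicate labels.

    Both inputs are 1-based label vectors over the same patients.
    Returns ``(map_rep_to_orig, kappa_by_cluster)`` where
    ``map_rep_to_orig[j-1]`` is the original label assigned to replicate
    label j, and ``kappa_by_cluster[c-1]`` is the kappa of the matched
    pair for original cluster c.  The alignment maximises the sum of
    per-cluster kappas over all k! permutations via the Hungarian
    algorithm; ties resolve deterministically.
    """
    original = np.asarray(original)
    replicate = np.asarray(replicate)
    if original.shape != replicate.shape:
        raise ValueError("match_labels: assignments must cover the same patients")
    if original.max(initial=1) > k or replicate.max(initial=1) > k:
        raise ValueError(f"match_labels: labels exceed k={k}")
    K = np.empty((k, k))
    for i in range(k):
        oi = original == i + 1
        for j in range(k):
            K[i, j] = cohen_kappa(oi, replicate == j + 1)
    rows, cols = linear_sum_assignment(-K)
    map_rep_to_orig = np.empty(k, dtype=int)
    kappa_by_cluster = np.empty(k)
    for i, j in zip(rows, cols):
        map_rep_to_orig[j] = i + 1
        kappa_by_cluster[i] = K[i, j]
    return map_rep_to_orig, kappa_by_cluster


def rand_agreement(original_members: set, replicate_members: set, universe: set) -> float:
    """Percent observed agreement of binary membership for one cluster."""
    if not universe:
        raise ValueError("rand_agreement: empty universe")
    if not original_members <= universe or not replicate_members <= universe:
        raise ValueError("rand_agreement: member sets must lie within the universe")
    both_in = len(original_members & replicate_members)
    both_out = len(universe) - len(original_members | replicate_members)
    return 100.0 * (both_in + both_out) / len(universe)


def jaccard_overlap(original_members: set, replicate_members: set) -> float:
    """Percent overlap (intersection over union) of two membership sets.

    Both-empty is vacuous agreement, defined as 100 with a warning.
    """
    union = original_members | replicate_members
    if not union:
        logger.warning("jaccard_overlap: both membership sets empty; "
                       "returning 100 (vacuous agreement)")
        return 100.0
    return 100.0 * len(original_members & replicate_members) / len(union)


@dataclass
class StabilityReport:
    """Per-cluster stability over bootstrap replicates."""

    per_cluster: pd.DataFrame  # cluster, rand_mean, rand_sd, jaccard_mean, jaccard_sd
    replicates: pd.DataFrame  # replicate, cluster, rand, jaccard, kappa
    n_replicates: int
    n_skipped: int
    seed: int
    population: str = "unique"

    @property
    def overall(self) -> dict[str, float]:
        return {
            "rand_mean": float(self.per_cluster["rand_mean"].mean()),
            "jaccard_mean": float(self.per_cluster["jaccard_mean"].mean()),
        }

    def to_csv(self, per_cluster_path: str | Path,
               replicates_path: str | Path | None = None) -> None:
        self.per_cluster.to_csv(per_cluster_path, index=False, float_format="%.6g")
        if replicates_path is not None:
            self.replicates.to_csv(replicates_path, index=False, float_format="%.6g")


def run_stability(
    features: FeatureMatrix | np.ndarray,
    reference: ClusterModel,
    n_replicates: int = 500,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-6,
    population: str = "unique",
) -> StabilityReport:
    """Bootstrap the cohort, refit, align by kappa, and score each cluster.

    Each replicate resamples n patients with replacement, refits k-means
    (same k as the reference; replicate r uses seed ``seed + r``), aligns
    labels by kappa, and computes per-cluster agreement and overlap.
    With ``population="unique"`` (default) the comparison universe is the
    distinct patients drawn in the replicate; ``population="all"``
    instead scores every original patient, assigning out-of-sample
    patients to their nearest replicate centroid.

    Refit failures are skipped and counted, never silently absorbed.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    n = X.shape[0]
    k = reference.k
    if reference.assignments.shape[0] != n:
        raise ValueError("reference model was not fitted on these features")
    if population not in ("unique", "all"):
        raise ValueError(f"unknown population {population!r}")

    rows = []
    n_skipped = 0
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        idx = rng.integers(0, n, n)
        try:
            model = fit_kmeans(X[idx], k, seed=seed + r, n_restarts=n_restarts,
                               max_iter=max_iter, tol=tol)
        except Exception as exc:  # noqa: BLE001 - recorded, not absorbed
            logger.warning("stability replicate %d failed: %s", r, exc)
            n_skipped += 1
            continue
        universe = np.unique(idx) if population == "unique" else np.arange(n)
        orig = reference.assignments[universe]
        rep = assign_to_centroids(X[universe], model.centroids)
        mapping, kappas = match_labels(orig, rep, k)
        rep_aligned = mapping[rep - 1]
        for c in range(1, k + 1):
            omem = set(universe[orig == c].tolist())
            rmem = set(universe[rep_aligned == c].tolist())
            uni = set(universe.tolist())
            rows.append({
                "replicate": r, "cluster": c,
                "rand": rand_agreement(omem, rmem, uni),
                "jaccard": jaccard_overlap(omem, rmem),
                "kappa": kappas[c - 1],
            })

    replicates = pd.DataFrame(rows)
    if len(replicates):
        g = replicates.groupby("cluster")
        per_cluster = pd.DataFrame({
            "cluster": sorted(g.groups),
            "rand_mean": g["rand"].mean().to_numpy(),
            "rand_sd": g["rand"].std(ddof=1).to_numpy(),
            "jaccard_mean": g["jaccard"].mean().to_numpy(),
            "jaccard_sd": g["jaccard"].std(ddof=1).to_numpy(),
        })
    else:
        per_cluster = pd.DataFrame(columns=["cluster", "rand_mean", "rand_sd",
                                            "jaccard_mean", "jaccard_sd"])
    if n_skipped:
        logger.warning("run_stability: %d of %d replicates skipped",
                       n_skipped, n_replicates)
    return StabilityReport(per_cluster=per_cluster, replicates=replicates,
                           n_replicates=n_replicates, n_skipped=n_skipped,
                           seed=seed, population=population)
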