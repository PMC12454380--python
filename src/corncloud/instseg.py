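"""Adaptive-eps density clustering of seedling points into plant instances.

The neighborhood radius eps is estimated from the data itself: for every
point take the Euclidean distance to its k-th nearest neighbor (k = 55,
self excluded) and average over all points. Density-based clustering
(DBSCAN, minpts = 3) with that eps then separates the plants; points in no
cluster are noise (−1). Predicted clusters are matched one-to-one to
ground-truth plants with the Hungarian algorithm maximizing total pairwise
IoU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

__all__ = [
    "InstanceAssignment", "InsufficientPointsError",
    "estimate_eps", "corn_dbscan", "fixed_eps_dbscan", "match_instances",
]

DEFAULT_K = 55
DEFAULT_MINPTS = 3


class InsufficientPointsError(ValueError):
    """Fewer points than needed for the k-th nearest-neighbor estimate."""


@dataclass
class InstanceAssignment:
    labels: np.ndarray      # per point: -1 noise, 0..K-1 clusters
    eps_used: float
    k_neighbors: int = DEFAULT_K
    minpts: int = DEFAULT_MINPTS

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    @property
    def n_noise(self) -> int:
        return int((self.labels == -1).sum())


def estimate_eps(points: np.ndarray, k: int = DEFAULT_K) -> float:
    """Mean distance to the k-th nearest neighbor (self excluded).

    Requires at least k+1 points; scales linearly with the coordinates
    (homogeneity of degree 1).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n <= k:
        raise InsufficientPointsError(f"need > {k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    # column 0 is the point itself; the last column is the k-th true neighbor
    return float(dist[:, -1].mean())


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 0..K−1 by descending member count; −1 preserved."""
    out = np.full_like(labels, -1)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    for new_id, old_id in enumerate(ids[np.argsort(-counts, kind="stable")]):
        out[labels == old_id] = new_id
    return out


def corn_dbscan(points: np.ndarray, k: int = DEFAULT_K,
                minpts: int = DEFAULT_MINPTS) -> InstanceAssignment:
    """Adaptive-eps DBSCAN over seedling points.

    Falls back to k = N−1 (with a warning) for clouds of at most k points;
    clouds below minpts, or with a degenerate eps of 0, are all noise.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty point set")
    if n < minpts:
        log.warning("only %d points (< minpts=%d): all noise", n, minpts)
        return InstanceAssignment(np.full(n, -1), 0.0, k, minpts)
    k_eff = k
    if n <= k:
        k_eff = n - 1
        log.warning("only %d points; reducing k from %d to %d", n, k, k_eff)
    eps = estimate_eps(points, k_eff)
    if eps <= 0.0:
        log.warning("degenerate eps=0 (coincident points): all noise")
        return InstanceAssignment(np.full(n, -1), 0.0, k_eff, minpts)
    labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(points)
    return InstanceAssignment(_renumber_by_size(labels), eps, k_eff, minpts)


def fixed_eps_dbscan(points: np.ndarray, eps: float,
                     minpts: int = DEFAULT_MINPTS) -> InstanceAssignment:
    """Plain DBSCAN baseline at a user-chosen eps."""
    points = np.asarray(points, dtype=float)
    labels = DBSCAN(eps=eps, min_samples=minpts).fit_predict(points)
    return InstanceAssignment(_renumber_by_size(labels), float(eps), 0, minpts)


def match_instances(pred: InstanceAssignment | np.ndarray,
                    truth: np.ndarray) -> dict[int, int]:
    """One-to-one Hungarian matching of predicted clusters to truth plants.

    Maximizes the summed pairwise IoU of the contingency table between
    predicted clusters (ids ≥ 0; noise ignored) and truth instances
    (ids ≥ 1; background 0 ignored). Returns {pred_cluster_id: truth_id};
    surplus predicted clusters are absent from the mapping.
    """
    pred_labels = pred.labels if isinstance(pred, InstanceAssignment) else np.asarray(pred)
    truth = np.asarray(truth)
    if pred_labels.shape != truth.shape:
        raise ValueError("labelings must cover the same point list")
    pred_ids = [int(c) for c in np.unique(pred_labels) if c >= 0]
    truth_ids = [int(t) for t in np.unique(truth) if t > 0]
    if not pred_ids or not truth_ids:
        return {}
    iou = np.zeros((len(pred_ids), len(truth_ids)))
    for i, p in enumerate(pred_ids):
        p_mask = pred_labels == p
        for j, t in enumerate(truth_ids):
            t_mask = truth == t
            inter = int((p_mask & t_mask).sum())
            union = int((p_mask | t_mask).sum())
            iou[i, j] = inter / union if union else 0.0
    rows, cols = linear_sum_assignment(-iou)
    return {pred_ids[r]: truth_ids[c] for r, c in zip(rows, cols) if iou[r, c] > 0}
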