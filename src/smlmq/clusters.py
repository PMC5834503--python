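"""DBSCAN-based cluster quantification of localization data.

Two parameter regimes from the underlying experiments are used as
defaults: single-nanobody counting (ε = 40 nm, MinPts = 6) and
autophagosome/LC3B cluster analysis (ε = 50 nm, MinPts = 40).  Cluster
size is the mean Euclidean distance of member localizations from the
cluster's center of mass; the degree of clustering is the clustered
(core + border) fraction of all localizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .core_io import ROI, LocalizationTable

__all__ = [
    "NOISE",
    "ClusterAssignment",
    "ClusterSummary",
    "DensityClusterer",
    "dbscan",
    "cluster_stats",
    "nanobody_density",
    "localization_density",
]

NOISE = -1

ROLE_CORE = "core"
ROLE_BORDER = "border"
ROLE_NOISE = "noise"


@dataclass
class ClusterAssignment:
    """Per-point DBSCAN labels and roles.

    ``labels`` uses cluster ids ≥ 0 and ``NOISE`` (−1); ``roles`` is one of
    ``"core"``, ``"border"``, ``"noise"`` per point.  The neighborhood count
    that defines a core point includes the point itself.
    """

    labels: np.ndarray
    roles: np.ndarray
    eps_nm: float
    min_pts: int

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.labels[self.labels >= 0])))

    @property
    def n_points(self) -> int:
        return len(self.labels)


@dataclass
class ClusterSummary:
    n_clusters: int
    cluster_size_nm: np.ndarray          # per cluster, mean distance to center of mass
    degree_of_clustering: float          # clustered (core+border) fraction
    size_hist_counts: np.ndarray
    size_hist_edges_nm: np.ndarray
    centers_nm: np.ndarray               # (n_clusters, 2) centers of mass


def dbscan(points: np.ndarray, eps_nm: float, min_pts: int) -> ClusterAssignment:
    """Classical DBSCAN on 2D points (nm); deterministic for a fixed order.

    A point is core when its inclusive ε-neighborhood (counting the point
    itself) holds at least ``min_pts`` points; clusters are the connected
    components of core points, plus border points attached to a reachable
    cluster; the rest is noise.
    """
    if eps_nm <= 0:
        raise ValueError("eps_nm must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    points = np.asarray(points, float).reshape(-1, 2)
    if len(points) == 0:
        return ClusterAssignment(
            np.empty(0, np.int64), np.empty(0, object), eps_nm, min_pts
        )
    model = DBSCAN(eps=eps_nm, min_samples=min_pts).fit(points)
    labels = model.labels_.astype(np.int64)
    roles = np.full(len(points), ROLE_NOISE, dtype=object)
    roles[labels >= 0] = ROLE_BORDER
    roles[model.core_sample_indices_] = ROLE_CORE
    return ClusterAssignment(labels, roles, eps_nm, min_pts)


class DensityClusterer(ClusterMixin, BaseEstimator):
    """scikit-learn estimator facade over :func:`dbscan` (+ summary stats)."""

    def __init__(self, eps_nm: float = 50.0, min_pts: int = 40, hist_bin_nm: float = 100.0):
        self.eps_nm = eps_nm
        self.min_pts = min_pts
        self.hist_bin_nm = hist_bin_nm

    def fit(self, X: np.ndarray, y=None) -> "DensityClusterer":
        X = np.asarray(X, float).reshape(-1, 2)
        self.assignment_ = dbscan(X, self.eps_nm, self.min_pts)
        self.labels_ = self.assignment_.labels
        self.roles_ = self.assignment_.roles
        self.summary_ = cluster_stats(self.assignment_, X, self.hist_bin_nm)
        return self


def cluster_stats(
    assignment: ClusterAssignment, points: np.ndarray, bin_nm: float = 100.0
) -> ClusterSummary:
    """Cluster sizes, degree of clustering and a 100-nm size histogram.

    The size of a cluster is the average distance of its member points to
    the cluster center of mass (for points on a circle of radius r around
    the center this is exactly r; for an isotropic Gaussian cluster of
    scale σ it converges to σ·sqrt(π/2)).
    """
    points = np.asarray(points, float).reshape(-1, 2)
    labels = assignment.labels
    ids = np.unique(labels[labels >= 0])
    sizes = np.empty(len(ids))
    centers = np.empty((len(ids), 2))
    for i, cid in enumerate(ids):
        mem = points[labels == cid]
        com = mem.mean(axis=0)
        centers[i] = com
        sizes[i] = np.linalg.norm(mem - com, axis=1).mean()
    n = len(points)
    clustered = float(np.count_nonzero(labels >= 0)) / n if n else 0.0
    upper = np.ceil(max(sizes.max(), bin_nm) / bin_nm) * bin_nm if len(sizes) else bin_nm
    edges = np.arange(0.0, upper + bin_nm, bin_nm)
    counts, edges = np.histogram(sizes, bins=edges)
    return ClusterSummary(
        n_clusters=len(ids),
        cluster_size_nm=sizes,
        degree_of_clustering=clustered,
        size_hist_counts=counts,
        size_hist_edges_nm=edges,
        centers_nm=centers,
    )


def nanobody_density(
    table: LocalizationTable,
    roi: ROI,
    eps_nm: float = 40.0,
    min_pts: int = 6,
) -> float:
    """Single-probe density: DBSCAN cluster count inside a ROI per µm².

    Each multi-blink probe appears as one small dense cluster; the density
    is n_clusters / ROI area.
    """
    if roi.area_um2 <= 0:
        raise ValueError("ROI must have positive area")
    inside = roi.contains(table.xy)
    pts = table.xy[inside]
    if len(pts) == 0:
        return 0.0
    assignment = dbscan(pts, eps_nm, min_pts)
    return assignment.n_clusters / roi.area_um2


def localization_density(table: LocalizationTable, area_um2: float) -> float:
    """Raw localization count per µm² over a known (cell mask) area."""
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    return len(table) / area_um2
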