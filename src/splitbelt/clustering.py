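"""Subgroup discovery from flagged-stride counts.

Each participant contributes a single feature: the number of strides in a
task segment whose step length asymmetry falls outside their own baseline
confidence interval (below it for the Exp 2 ramp-up segment, above it for the
Exp 1 Ramp Down). Participants are grouped by density-based clustering
(DBSCAN) on this one-dimensional feature with automatically chosen
parameters: min_pts defaults to 4 (the classic DBSCAN recommendation) and
epsilon is derived from the sorted
k-nearest-neighbor distances and the dominant empty interval of the feature
(see ``auto_epsilon``), so no user input is required.
Cluster validity is assessed by silhouette scores on non-outlier points;
single-cluster and no-cluster outcomes are valid results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import NearestNeighbors


@dataclass
class ClusterResult:
    """Labels (−1 = outlier), silhouettes, and the chosen DBSCAN parameters."""

    feature: np.ndarray
    labels: np.ndarray
    silhouette_scores: np.ndarray | None
    silhouette_mean: float | None
    epsilon: float
    min_pts: int
    flag: str | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0].tolist()))

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def baseline_ci(
    baseline_sla,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Within-participant 95% percentile bootstrap CI of the mean baseline sla.

    Resamples strides of the tied-belt baseline block with replacement.
    """
    sla = np.asarray(baseline_sla, float)
    if len(sla) < 20:
        raise ValueError(f"need at least 20 baseline strides, got {len(sla)}")
    rng = np.random.default_rng(seed)
    means = sla[rng.integers(0, len(sla), size=(n_boot, len(sla)))].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def count_flagged_strides(sla, ci: tuple[float, float], direction: str) -> int:
    """Strides strictly outside the baseline CI in the given direction."""
    sla = np.asarray(sla, float)
    if len(sla) == 0:
        raise ValueError("empty segment")
    lo, hi = ci
    if direction == "below":
        return int(np.sum(sla < lo))
    if direction == "above":
        return int(np.sum(sla > hi))
    raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")


def auto_epsilon(feature: np.ndarray, min_pts: int) -> float:
    """Automatic DBSCAN epsilon for a one-dimensional feature.

    The largest k-NN distance (k = min_pts) is the smallest epsilon that keeps
    every group of ≥ min_pts mutually close points internally connected: any
    consecutive spacing inside such a group is bounded by some point's
    k-distance. When the data contain a density gap — an empty interval
    between sorted feature values wider than every k-distance — epsilon is
    placed mid-gap, so the clustering splits there while each side stays
    whole. Without such a gap, epsilon is the largest k-distance and the data
    form a single cluster. No user input is required.
    """
    x = np.sort(np.asarray(feature, float))
    k = min(min_pts, len(x) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x.reshape(-1, 1))
    dists, _ = nn.kneighbors(x.reshape(-1, 1))
    d_max = float(dists[:, -1].max())
    gaps = np.diff(x)
    g_max = float(gaps.max()) if len(gaps) else 0.0
    if g_max > d_max:
        return (g_max + d_max) / 2
    return max(d_max * (1 + 1e-9), 1e-12)


#: mean silhouette below which a candidate multi-cluster split is rejected
#: (Rousseeuw's strong-structure band starts near 0.71; 0.75 is conservative)
STRONG_SILHOUETTE = 0.75


def auto_cluster(feature, min_pts: int = 4, accept_silhouette: float = STRONG_SILHOUETTE) -> ClusterResult:
    """Density-based clustering of a 1-D feature with automatic parameters.

    DBSCAN runs at the automatically chosen epsilon; a multi-cluster outcome
    is kept only when it shows strong structure (mean silhouette ≥
    ``accept_silhouette`` over non-outlier points), otherwise the data are
    reported as a single cluster. Single-cluster and no-cluster outcomes are
    valid results.
    """
    feature = np.asarray(feature, float)
    if len(feature) < 4:
        raise ValueError(f"need at least 4 participants, got {len(feature)}")
    eps = auto_epsilon(feature, min_pts)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(feature.reshape(-1, 1))
    flag = None
    core = labels >= 0
    n_clusters = len(set(labels[core].tolist()))
    if n_clusters == 0:
        return ClusterResult(feature, labels, None, None, eps, min_pts, flag="all points outliers")
    if n_clusters == 1:
        return ClusterResult(
            feature, labels, None, None, eps, min_pts,
            flag="single cluster; silhouette undefined",
        )
    scores = np.full(len(feature), np.nan)
    scores[core] = silhouette_samples(feature[core].reshape(-1, 1), labels[core])
    mean_s = float(np.nanmean(scores[core]))
    if mean_s < accept_silhouette:
        labels = np.where(core, 0, labels)
        return ClusterResult(
            feature, labels, None, None, eps, min_pts,
            flag=f"split rejected (mean silhouette {mean_s:.3f} < {accept_silhouette}); single cluster",
        )
    if (~core).any():
        flag = f"{int((~core).sum())} outliers excluded from silhouette"
    return ClusterResult(feature, labels, scores, mean_s, eps, min_pts, flag=flag)
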