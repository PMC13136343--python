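"""Hierarchical clustering of co-bursting channels and its controls.

Channels are clustered on a 1 - Pearson-r distance with average linkage
(UPGMA), which groups channels that burst at the same peri-event times into
sequential modules.  Two controls quantify whether the modular structure is
genuine: a temporal-jitter surrogate that perturbs each burst time by a
random +/-50-100 ms shift (preserving per-channel event counts) and should
destroy millisecond-scale synchrony, and a bootstrap over channels whose
agreement with the original partition is summarized by the Adjusted Rand
Index (ARI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .coincidence import pairwise_correlation


@dataclass
class ClusterResult:
    """Outcome of one UPGMA clustering run."""

    distance_matrix: np.ndarray
    merge_tree: np.ndarray          # scipy linkage matrix (n-1, 4)
    labels: np.ndarray              # flat cluster id per channel
    leaf_order: np.ndarray          # display ordering from tree traversal
    n_clusters: int = 0

    def __post_init__(self) -> None:
        self.n_clusters = int(len(np.unique(self.labels)))


@dataclass
class StabilityResult:
    """Bootstrap cluster-stability summary."""

    ari_mean: float
    ari_sd: float
    n_boot: int
    synchrony_original: float | None = None
    synchrony_jittered: float | None = None


def correlation_distance(raster: np.ndarray) -> np.ndarray:
    """Distance d(i, j) = 1 - r(i, j) between channel time series.

    Constant channels are flagged and assigned distance 1 to every other
    channel (their correlation is undefined and set to zero).
    """
    r = pairwise_correlation(raster)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage_cluster(distance: np.ndarray,
                            n_clusters: int | None = None,
                            height: float | None = None) -> ClusterResult:
    """Agglomerative clustering with unweighted average linkage (UPGMA).

    Flat labels come from a cut at ``n_clusters``, at ``height``, or — when
    neither is given — at the cluster count in 2..min(10, n-1) that maximizes
    the mean silhouette on the precomputed distances.
    """
    d = np.asarray(distance, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 channels to cluster")
    z = linkage(squareform(d, checks=False), method="average")
    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        labels = fcluster(z, t=height, criterion="distance")
    else:
        labels = _silhouette_cut(d, z)
    return ClusterResult(distance_matrix=d, merge_tree=z,
                         labels=np.asarray(labels), leaf_order=leaves_list(z))


def _silhouette_cut(d: np.ndarray, z: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    if n == 2:
        return np.array([1, 2])
    best_labels, best_score = None, -np.inf
    for k in range(2, min(10, n - 1) + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(d, labels, metric="precomputed")
        if score > best_score:
            best_labels, best_score = labels, score
    if best_labels is None:  # degenerate distances; fall back to a 2-cut
        best_labels = fcluster(z, t=2, criterion="maxclust")
    return best_labels


def to_newick(result: ClusterResult, labels: list[str]) -> str:
    """Serialize the merge tree in Newick format, branch lengths from merge
    heights."""
    z = result.merge_tree
    n = z.shape[0] + 1
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k in range(z.shape[0]):
        a, b, h = int(z[k, 0]), int(z[k, 1]), float(z[k, 2])
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + z.shape[0] - 1] + ";"


def jitter_surrogate(events: pd.DataFrame, jitter_min: float = 0.050,
                     jitter_max: float = 0.100, seed: int = 0,
                     t_max: float | None = None) -> pd.DataFrame:
    """Perturb each event's peak time by an independent random shift.

    The shift magnitude is uniform on ``[jitter_min, jitter_max]`` seconds
    with an equiprobable sign, so overall per-channel burst rates are
    preserved while millisecond timing is destroyed.  Shifts that would leave
    the recording are reflected at the boundary.
    """
    if jitter_min > jitter_max:
        raise ValueError("jitter_min must be <= jitter_max")
    rng = np.random.default_rng(seed)
    out = events.copy()
    n = len(out)
    mag = rng.uniform(jitter_min, jitter_max, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    t = out["peak_time"].to_numpy(dtype=float) + mag * sign
    t = np.abs(t)  # reflect at zero
    if t_max is not None:
        over = t > t_max
        t[over] = 2.0 * t_max - t[over]
    out["peak_time"] = t
    return out


def synchrony(raster: np.ndarray) -> float:
    """Mean pairwise Pearson correlation across channels.

    Pairs involving a zero-variance channel are excluded; with no valid pair
    the index is undefined (NaN, flagged by warning).  Values can be slightly
    negative for anticorrelated series and are reported unclipped.
    """
    x = np.asarray(raster, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 channels")
    valid = np.flatnonzero(x.std(axis=1) > 0)
    if valid.size < 2:
        warnings.warn("no channel pair with variance; synchrony undefined")
        return float("nan")
    r = np.corrcoef(x[valid])
    iu = np.triu_indices(valid.size, k=1)
    return float(r[iu].mean())


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-adjusted agreement between two partitions.

    1 for identical partitions, 0 expected under random labeling, down to
    negative values for systematic disagreement.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def bootstrap_stability(rasters, n_boot: int = 100, seed: int = 0,
                        n_clusters: int | None = None) -> StabilityResult:
    """Bootstrap channels with replacement and recluster, per trial.

    ``rasters`` is a single channels x bins matrix or a list of them (one per
    word/trial).  For each replicate, channels are resampled with
    replacement, the resampled raster reclustered, and the ARI computed
    between original and replicate labels restricted to the unique channels
    present in the replicate; replicates with fewer than two unique channels
    are redrawn.  ARIs are summarized per trial (mean, SD over replicates)
    and then averaged across trials.
    """
    if isinstance(rasters, np.ndarray):
        rasters = [rasters]
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    trial_means, trial_sds = [], []
    for mat in rasters:
        mat = np.asarray(mat, dtype=float)
        n = mat.shape[0]
        if n < 3:
            raise ValueError("need >= 3 channels for bootstrap stability")
        base = average_linkage_cluster(correlation_distance(mat),
                                       n_clusters=n_clusters)
        aris = []
        for _ in range(n_boot):
            for _attempt in range(100):
                idx = rng.integers(0, n, size=n)
                uniq, first = np.unique(idx, return_index=True)
                if uniq.size >= 2:
                    break
            res = average_linkage_cluster(correlation_distance(mat[idx]),
                                          n_clusters=n_clusters)
            aris.append(adjusted_rand_index(base.labels[uniq],
                                            res.labels[first]))
        aris = np.asarray(aris)
        trial_means.append(aris.mean())
        trial_sds.append(aris.std(ddof=1) if aris.size > 1 else 0.0)
    return StabilityResult(ari_mean=float(np.mean(trial_means)),
                           ari_sd=float(np.mean(trial_sds)), n_boot=n_boot)
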