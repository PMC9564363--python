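"""Protein abundance profiles: normalization, k-means clustering, sector calls.

A protein abundance profile (PAP) is the vector of log2(x_i / x̄) values of
one protein across the six bent-root conditions (three 5-cm sectors — above
bending ABS, bending BS, below bending BBS — each split into the convex ``cx``
and concave ``cv`` side). Profiles are grouped by k-means; a cluster is called
"peaking" in a condition when its centroid value there reaches the sector
score threshold (0.3 log2 units by default), and only peaking clusters seed
downstream subnetworks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Fixed condition order used by every table in the pipeline.
CONDITIONS: tuple[str, ...] = (
    "ABS-cx", "BS-cx", "BBS-cx", "ABS-cv", "BS-cv", "BBS-cv",
)

#: Default sector-call threshold on centroid values (log2 units).
SECTOR_THRESHOLD: float = 0.3


def normalize_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw spot densities to abundance profiles.

    Each value becomes ``log2(x_i / mean_over_conditions(x))`` so every
    protein's profile is centred on its own mean abundance: the profile is
    invariant to rescaling a protein's row by any positive constant, and the
    mean of ``2**profile`` over conditions is exactly 1.

    Parameters
    ----------
    table:
        Proteins x conditions table of strictly positive densities.

    Raises
    ------
    ValueError
        If any value is non-positive or non-finite; the offending protein and
        condition are named.
    """
    values = table.to_numpy(dtype=float)
    bad = ~(np.isfinite(values) & (values > 0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive abundance for protein {table.index[i]!r} in "
            f"condition {table.columns[j]!r}: {values[i, j]!r}"
        )
    row_means = values.mean(axis=1, keepdims=True)
    normalized = np.log2(values / row_means)
    return pd.DataFrame(normalized, index=table.index, columns=table.columns)


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of k-means on normalized profiles.

    Cluster labels are re-indexed in decreasing cluster-size order (ties by
    the fitted label) so that label 0 is always the largest cluster; the
    original arbitrary k-means labels carry no meaning.
    """

    k: int
    assignments: pd.Series  # protein ID -> cluster label in 0..k-1
    centroids: pd.DataFrame  # k x n_conditions, log2 units
    withinss: np.ndarray  # per-cluster sum of squared distances
    sizes: np.ndarray  # per-cluster member counts
    seed: int
    n_iter: int = field(compare=False, default=0)

    @property
    def total_withinss(self) -> float:
        return float(self.withinss.sum())


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 6,
    n_init: int = 25,
    max_iter: int = 300,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster profiles with k-means (k-means++ seeding, best of ``n_init``).

    Lloyd's algorithm with Euclidean distance; the restart with the lowest
    total within-cluster sum of squares wins. Fully deterministic given
    ``seed``.
    """
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of proteins ({len(profiles)})")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)

    raw_labels = km.labels_
    sizes_raw = np.bincount(raw_labels, minlength=k)
    # stable size-descending relabeling
    order = sorted(range(k), key=lambda c: (-sizes_raw[c], c))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw_labels])
    centroids = km.cluster_centers_[order]

    withinss = np.zeros(k)
    for c in range(k):
        members = X[labels == c]
        withinss[c] = ((members - centroids[c]) ** 2).sum()

    return ClusteringResult(
        k=k,
        assignments=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(
            centroids, index=range(k), columns=profiles.columns
        ),
        withinss=withinss,
        sizes=np.bincount(labels, minlength=k),
        seed=seed,
        n_iter=int(km.n_iter_),
    )


def assign_sectors(
    centroids: pd.DataFrame | ClusteringResult,
    threshold: float = SECTOR_THRESHOLD,
) -> dict[int | str, tuple[str, ...]]:
    """Call the conditions in which each cluster centroid peaks.

    A cluster is assigned every condition whose centroid value is >= the
    threshold; the set may be empty (such clusters seed no subnetwork).
    Accepts either a fitted :class:`ClusteringResult` or a bare centroid
    matrix (rows = clusters, columns = conditions).
    """
    if isinstance(centroids, ClusteringResult):
        centroids = centroids.centroids
    assignment: dict[int | str, tuple[str, ...]] = {}
    for label, row in centroids.iterrows():
        assignment[label] = tuple(c for c in centroids.columns if row[c] >= threshold)
    return assignment
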