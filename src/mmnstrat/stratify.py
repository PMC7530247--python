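"""Outlier screening, elbow-based k selection, and k-means stratification.

Subjects are clustered on their 24-channel feature vectors (MMN
amplitude, MMN 6-month change, or delta-band AverageDifference).
Features enter k-means raw — unstandardized — because the channels share
units and comparable scales and standardizing would change the cluster
geometry.  The number of clusters is chosen from the within-cluster
sum-of-squares curve J(k): the automated rule takes the k with the
largest second difference (the sharpest bend), which reproduces the
visual elbow readout while remaining testable.

AverageDifference features are screened first with an (unscaled) median
absolute deviation filter on the 24-channel sum — the index is a sum of
squared power differences and single extreme observations otherwise
capture a cluster of their own.  MMN-amplitude runs are not screened.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .montage import FRONTOCENTRAL_24

#: semantic label conventions per feature source
_LABEL_RULES = {
    # source: (label for cluster 1, label for cluster 2, cluster-1 picks)
    "mmn": ("Better functioning", "Poorer functioning", "most_negative"),
    "mmn_change": ("Better functioning", "Poorer functioning", "most_negative"),
    "avgdiff_delta": ("higher AverageDifference", "lower AverageDifference",
                      "highest"),
}

RUN_DESIGNS = (
    "HC+baselineFEP", "HC+followupFEP", "baselineFEP+followupFEP", "FEP_change",
)


@dataclass
class FeatureMatrix:
    """Observations x 24 channels, with provenance for labeling rules."""

    data: pd.DataFrame  # index = observation ids, columns = canonical sites
    source: str  # "mmn" | "mmn_change" | "avgdiff_delta"
    run_design: str | None = None

    def __post_init__(self) -> None:
        if self.source not in _LABEL_RULES:
            raise ValueError(f"unknown feature source {self.source!r}")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if list(self.data.columns) != list(FRONTOCENTRAL_24):
            raise ValueError("columns must be the canonical 24-site list")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ElbowCurve:
    k_values: np.ndarray
    J: np.ndarray  # within-cluster sum of squares per k
    chosen_k: int

    def second_differences(self) -> np.ndarray:
        """J(k-1) - 2 J(k) + J(k+1) for interior k."""
        return self.J[:-2] - 2 * self.J[1:-1] + self.J[2:]


@dataclass
class ClusterResult:
    assignments: pd.Series  # observation id -> semantic cluster number (1-based)
    centroids: np.ndarray  # k x 24, row order matches semantic numbering
    labels: dict[int, str]
    cost: float
    seed: int
    n_restarts: int
    outliers: list = field(default_factory=list)

    def members(self, cluster: int) -> pd.Index:
        return self.assignments.index[self.assignments == cluster]


def mad_outlier_filter(
    channel_sums: pd.Series | np.ndarray, threshold: float = 3.0
) -> tuple[np.ndarray, list]:
    """Flag observations more than ``threshold`` MADs from the median.

    MAD is the plain median of absolute deviations from the median, with
    no normal-consistency scaling.  Returns ``(keep_mask, outlier_ids)``.
    A zero MAD means no finite deviation criterion exists: nothing is
    flagged and a warning is emitted.
    """
    s = pd.Series(channel_sums)
    if len(s) < 3:
        raise ValueError("need at least 3 observations for MAD screening")
    x = s.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        warnings.warn("MAD is zero; outlier screening skipped", stacklevel=2)
        return np.ones(len(x), dtype=bool), []
    keep = np.abs(x - med) <= threshold * mad
    return keep, list(s.index[~keep])


def _fit_kmeans(X: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    """Best-of-restarts Lloyd fit over two init families.

    k-means++ restarts are complemented by restarts initialized at the
    centroids of random partitions: point-seeded inits alone can be
    unable to reach the globally optimal (Lloyd-stable) partition on
    small instances, where the optimum's basin contains no data-point
    pair.
    """
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    km.fit(X)
    best = km
    rng = np.random.default_rng(seed)
    for _ in range(max(5, n_restarts // 2)):
        labels = rng.integers(0, k, X.shape[0])
        if len(np.unique(labels)) < k:
            continue
        cents = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        cand = KMeans(n_clusters=k, init=cents, n_init=1).fit(X)
        if cand.inertia_ < best.inertia_:
            best = cand
    for attempt in range(1, 6):  # guard against degenerate empty clusters
        if len(np.unique(best.labels_)) == k:
            return best
        best = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                      random_state=seed + attempt)
        best.fit(X)
    raise RuntimeError(f"k-means produced an empty cluster for k={k} "
                       "after 5 reseeded attempts")


def elbow_select_k(
    X: FeatureMatrix | pd.DataFrame | np.ndarray,
    k_max: int = 10,
    seed: int = 0,
    n_restarts: int = 50,
) -> ElbowCurve:
    """Within-cluster sum-of-squares curve J(k), k = 1..k_max, with the
    automated elbow choice (largest second difference of J)."""
    arr = X.values if isinstance(X, FeatureMatrix) else np.asarray(
        X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    n = arr.shape[0]
    if n < k_max:
        warnings.warn(f"only {n} rows; truncating k_max from {k_max} to {n}",
                      stacklevel=2)
        k_max = n
    if k_max < 3:
        raise ValueError("k_max must be at least 3 to locate an elbow")
    ks = np.arange(1, k_max + 1)
    J = np.array([_fit_kmeans(arr, int(k), seed, n_restarts).inertia_
                  for k in ks])
    second = J[:-2] - 2 * J[1:-1] + J[2:]
    chosen = int(ks[1:-1][int(np.argmax(second))])
    return ElbowCurve(k_values=ks, J=J, chosen_k=chosen)


def kmeans_cluster(
    X: FeatureMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterResult:
    """Best-of-restarts k-means with semantic relabeling.

    Cluster 1 is, by convention, the cluster with the more negative
    grand-mean feature for MMN-based sources ("Better functioning": a
    larger MMN is more negative) and the higher grand mean for the
    AverageDifference source ("higher AverageDifference").
    """
    arr = X.values
    if arr.shape[0] < k:
        raise ValueError(f"{arr.shape[0]} rows cannot form {k} clusters")
    km = _fit_kmeans(arr, k, seed, n_restarts)

    lab1, lab2, rule = _LABEL_RULES[X.source]
    grand = km.cluster_centers_.mean(axis=1)
    order = np.argsort(grand) if rule == "most_negative" else np.argsort(-grand)
    remap = {int(orig): new + 1 for new, orig in enumerate(order)}
    assignments = pd.Series(
        [remap[int(l)] for l in km.labels_], index=X.data.index, name="cluster"
    )
    labels = {1: lab1, 2: lab2} if k == 2 else {
        i + 1: f"cluster {i + 1}" for i in range(k)}
    return ClusterResult(
        assignments=assignments,
        centroids=km.cluster_centers_[order],
        labels=labels,
        cost=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def screen_and_cluster(
    X: FeatureMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 50,
    mad_threshold: float = 3.0,
) -> ClusterResult:
    """MAD-screen the 24-channel sums, then cluster the kept rows.

    This is the standard path for AverageDifference features; MMN runs
    call :func:`kmeans_cluster` directly (they are not screened).
    """
    sums = X.data.sum(axis=1)
    keep, outliers = mad_outlier_filter(sums, threshold=mad_threshold)
    kept = FeatureMatrix(data=X.data.loc[keep], source=X.source,
                         run_design=X.run_design)
    res = kmeans_cluster(kept, k=k, seed=seed, n_restarts=n_restarts)
    res.outliers = outliers
    return res
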