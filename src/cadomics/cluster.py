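"""K-means clustering of each omics layer with model-order selection and
stability diagnostics.

Both layers (median/log2 metabolites, 0/0.5/1 encoded candidate SNPs) are
clustered with Euclidean k-means (k-means++ seeding, best of 25 restarts).
The elbow scan selects k at the maximal-curvature point of the inertia curve
(second-difference rule); a weak elbow is flagged rather than silently
accepted.  Stability between two solutions is the per-cluster set Jaccard
|A∩B| / |A∪B| after maximum-weight bipartite matching of the cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .io import check_aligned, log


@dataclass
class ClusterSolution:
    k: int
    assignments: pd.Series  # subject -> label in 1..k
    centroids: np.ndarray
    inertia: float
    silhouette_mean: float
    silhouette: pd.Series
    layer: str = ""

    def __post_init__(self) -> None:
        labels = set(self.assignments.unique())
        if not labels <= set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")

    def members(self, label: int) -> set:
        return set(self.assignments.index[self.assignments == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_label": self.assignments, "silhouette": self.silhouette}
        )


@dataclass
class ElbowCurve:
    k_values: list[int]
    inertia: list[float]
    selected_k: int
    weak_elbow: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "inertia": self.inertia})


@dataclass
class StabilityReport:
    """Per-matched-cluster Jaccard similarities between two partitions."""

    pair_jaccard: pd.DataFrame  # columns: label_a, label_b, jaccard
    min_jaccard: float
    crosstab: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.pair_jaccard


def _as_matrix(x) -> tuple[np.ndarray, pd.Index]:
    if hasattr(x, "values") and isinstance(getattr(x, "values"), pd.DataFrame):
        frame = x.values  # NormalizedMatrix
    elif isinstance(x, pd.DataFrame):
        frame = x
    else:
        raise TypeError(f"cannot cluster {type(x).__name__}")
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("input contains non-finite values")
    return arr, frame.index


def kmeans_fit(
    x,
    k: int,
    n_restarts: int = 25,
    seed: int = 0,
    layer: str = "",
    silhouette: bool = True,
) -> ClusterSolution:
    """Euclidean k-means, k-means++ seeding, best of ``n_restarts`` by inertia.

    ``silhouette=False`` skips the O(n²) silhouette computation for large fits.
    """
    arr, index = _as_matrix(x)
    n = arr.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k >= n:
        raise ValueError(f"k={k} must be below the number of subjects ({n})")
    km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
    labels = km.fit_predict(arr) + 1
    sil = (silhouette_samples(arr, labels, metric="euclidean") if silhouette
           else np.full(n, np.nan))
    assignments = pd.Series(labels, index=index, name="cluster_label")
    log.info("kmeans_fit layer=%s k=%d n=%d inertia=%.3f", layer, k, n, km.inertia_)
    return ClusterSolution(
        k=k,
        assignments=assignments,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        silhouette_mean=float(np.nanmean(sil)) if silhouette else float("nan"),
        silhouette=pd.Series(sil, index=index, name="silhouette"),
        layer=layer,
    )


def elbow_scan(
    x,
    k_range=range(2, 11),
    n_restarts: int = 25,
    seed: int = 0,
    weak_elbow_ratio: float = 0.15,
) -> ElbowCurve:
    """Inertia per k with maximal-curvature (second-difference) selection.

    The selected k maximizes d²(k) = inertia(k−1) − 2·inertia(k) + inertia(k+1);
    when the best curvature is below ``weak_elbow_ratio`` of the total inertia
    drop the curve is flagged as having a weak elbow.
    """
    ks = list(k_range)
    if len(ks) < 2:
        raise ValueError("k_range must contain at least 2 values")
    arr, _ = _as_matrix(x)
    inertia = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, init="k-means++", random_state=seed)
        km.fit(arr)
        inertia.append(float(km.inertia_))
    # enforce the best-of-restarts monotonicity that a perfect optimizer would give
    inertia = list(np.minimum.accumulate(inertia))
    if len(ks) == 2:
        selected, weak = ks[0], True
    else:
        d2 = np.array(
            [inertia[i - 1] - 2 * inertia[i] + inertia[i + 1] for i in range(1, len(ks) - 1)]
        )
        best = int(np.argmax(d2))
        selected = ks[best + 1]
        total_drop = inertia[0] - inertia[-1]
        weak = bool(total_drop <= 0 or d2[best] < weak_elbow_ratio * total_drop)
    return ElbowCurve(ks, inertia, selected, weak_elbow=weak)


def pairwise_jaccard(a: ClusterSolution, b: ClusterSolution) -> pd.DataFrame:
    """Jaccard similarity of every (cluster of a, cluster of b) pair."""
    mat = np.zeros((a.k, b.k))
    for i in range(a.k):
        ai = a.members(i + 1)
        for j in range(b.k):
            bj = b.members(j + 1)
            union = len(ai | bj)
            mat[i, j] = len(ai & bj) / union if union else 0.0
    return pd.DataFrame(mat, index=range(1, a.k + 1), columns=range(1, b.k + 1))


def compare_partitions(a: ClusterSolution, b: ClusterSolution) -> StabilityReport:
    """Match clusters by maximum-weight bipartite assignment on Jaccard."""
    check_aligned(a.assignments.index, b.assignments.index)
    jac = pairwise_jaccard(a, b)
    rows, cols = linear_sum_assignment(-jac.to_numpy())
    pairs = pd.DataFrame(
        {
            "label_a": jac.index[rows],
            "label_b": jac.columns[cols],
            "jaccard": jac.to_numpy()[rows, cols],
        }
    )
    crosstab = pd.crosstab(a.assignments, b.assignments)
    return StabilityReport(pairs, float(pairs["jaccard"].min()), crosstab)


_GROUP_RANK = {"control": 0, "high-risk": 1, "CAD": 2}
_SEX_RANK = {"female": 0, "male": 1}


def order_subjects_for_heatmap(cohort: pd.DataFrame) -> pd.Index:
    """Stable ordering: group (control<high-risk<CAD), then sex (F<M), then age."""
    for col in ("group", "sex", "age"):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks column {col!r}")
    keys = pd.DataFrame(
        {
            "g": cohort["group"].map(_GROUP_RANK),
            "s": cohort["sex"].map(_SEX_RANK),
            "a": cohort["age"],
        },
        index=cohort.index,
    )
    if keys.isna().any().any():
        raise ValueError("unknown group/sex label or missing age")
    return keys.sort_values(["g", "s", "a"], kind="stable").index
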