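"""Model selection and clustering-quality metrics.

The number of phenotypes is chosen with the elbow method: K-Means is run
for a range of k, the within-cluster sum of squared errors (SSE) is
recorded, and the elbow is located at the maximum discrete second
difference of the SSE curve — the point after which the rate of SSE
reduction slows most sharply.  Cluster quality is summarised by the mean
silhouette coefficient (SC, higher is better) and the Davies-Bouldin index
(DBI, lower is better); both delegate to scikit-learn and are checked
against naive pairwise-distance oracles in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

logger = logging.getLogger(__name__)

__all__ = ["SseCurve", "sse_curve", "select_k_elbow", "silhouette", "davies_bouldin"]


@dataclass
class SseCurve:
    ks: list[int]
    sse: list[float]

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.sse):
            raise ValueError("ks and sse must have equal length")
        if any(k2 <= k1 for k1, k2 in zip(self.ks, self.ks[1:])):
            raise ValueError("ks must be strictly increasing")


def sse_curve(
    Z: np.ndarray,
    k_range: range | list[int],
    seed: int = 0,
    n_init: int = 10,
) -> SseCurve:
    """Within-cluster SSE of seeded K-Means for each k in ``k_range``."""
    Z = np.asarray(Z, dtype=float)
    ks = sorted(int(k) for k in k_range)
    if ks[0] < 1 or ks[-1] > Z.shape[0]:
        raise ValueError(f"k_range must lie within [1, {Z.shape[0]}]")
    sse = [
        float(KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z).inertia_)
        for k in ks
    ]
    return SseCurve(ks, sse)


def select_k_elbow(curve: SseCurve) -> int:
    """Elbow of an SSE curve: k with the largest discrete second difference.

    The second difference is defined on interior points of the curve; ties
    break to the smallest k.  A flat curve (no drop anywhere) returns the
    smallest k with a warning.
    """
    if len(curve.ks) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    sse = np.asarray(curve.sse, dtype=float)
    if np.allclose(sse, sse[0]):
        logger.warning("SSE curve is flat; no elbow, returning smallest k")
        return curve.ks[0]
    d2 = sse[:-2] - 2.0 * sse[1:-1] + sse[2:]
    return curve.ks[1 + int(np.argmax(d2))]


def silhouette(Z: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient s(i) = (b−a)/max(a,b) over all points."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(Z, dtype=float), labels))


def davies_bouldin(Z: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of max_{j≠i}(S_i+S_j)/M_ij."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([Z[labels == u].mean(axis=0) for u in uniq])
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            if np.allclose(centroids[i], centroids[j]):
                raise ValueError("coincident centroids make DBI undefined")
    return float(davies_bouldin_score(Z, labels))
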