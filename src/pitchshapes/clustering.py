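"""Tactical clustering of per-instant shape descriptors.

k-means with Euclidean distance groups the match's per-frame MFC vectors
into recurring organization shapes; the number of clusters is chosen by
the elbow of the inertia-vs-k curve (automated kneedle-style rule: the k
whose inertia point lies farthest from the chord joining the curve's
endpoints, on a normalized curve). The inertia curve is always returned so
an analyst can override the automatic choice. Occurrence statistics then
report, per half, the percentage of frames spent in each cluster, plus a
label-versus-time timeline.

The MFC vectors are clustered raw (no standardization): all 100
components already share the fractal-dimension scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .errors import DataError
from .mfd import MFCDescriptor

DEFAULT_K_MAX = 10
DEFAULT_N_INIT = 10


def _as_matrix(descriptors) -> np.ndarray:
    if isinstance(descriptors, np.ndarray):
        X = np.asarray(descriptors, dtype=float)
    else:
        X = np.asarray(
            [d.F if isinstance(d, MFCDescriptor) else np.asarray(d, float) for d in descriptors],
            dtype=float,
        )
    if X.ndim != 2 or len(X) == 0:
        raise DataError("descriptors must form a nonempty 2D matrix")
    return X


def inertia_curve(X: np.ndarray, k_max: int, seed: int = 0, n_init: int = DEFAULT_N_INIT) -> np.ndarray:
    """Within-cluster sum of squares for k = 1..k_max (same seed schedule)."""
    X = _as_matrix(X)
    k_max = min(k_max, len(X))
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        out[k - 1] = km.inertia_
    return out


def elbow_k(descriptors, k_max: int = DEFAULT_K_MAX, seed: int = 0) -> tuple[int, np.ndarray]:
    """Choose k at the knee of the inertia curve.

    Both axes are normalized to [0, 1] and the knee is the k maximizing
    the distance from the inertia point to the straight line joining the
    curve's endpoints. If the curve is not non-increasing (a k-means
    anomaly) a warning is raised and the k with the largest second
    difference is returned instead. Returns (k, inertia curve).
    """
    if k_max < 3:
        raise DataError("k_max must be >= 3 to locate an elbow")
    X = _as_matrix(descriptors)
    inertias = inertia_curve(X, k_max, seed=seed)
    ks = np.arange(1, len(inertias) + 1, dtype=float)
    span = inertias[0] - inertias[-1]
    if span <= 0:
        warnings.warn(
            "inertia curve is flat or increasing; falling back to the "
            "maximum-second-difference rule",
            stacklevel=2,
        )
        return _second_difference_k(inertias), inertias
    if np.any(np.diff(inertias) > 1e-9 * max(inertias[0], 1.0)):
        warnings.warn(
            "inertia not non-increasing in k; falling back to the "
            "maximum-second-difference rule",
            stacklevel=2,
        )
        return _second_difference_k(inertias), inertias
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (inertias - inertias[-1]) / span  # decreasing 1 -> 0
    # distance from (x, y) to the chord y = 1 - x
    dist = (1.0 - x - y) / np.sqrt(2.0)
    return int(ks[np.argmax(np.abs(dist))]), inertias


def _second_difference_k(inertias: np.ndarray) -> int:
    if len(inertias) < 3:
        return 1
    second = inertias[:-2] - 2 * inertias[1:-1] + inertias[2:]
    return int(np.argmax(second) + 2)  # second difference at k = i+2


@dataclass
class ClusterResult:
    """k-means assignment of match frames to shape clusters.

    Labels are 1-based (C1..Ck). ``occurrence`` is a DataFrame of percent
    of frames per cluster per half (each half summing to 100);
    ``timeline`` is a (t, half, label) frame for the bar-chart view.
    """

    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float
    occurrence: pd.DataFrame | None = None
    timeline: pd.DataFrame | None = None
    inertias: np.ndarray | None = None


class TacticalKMeans(ClusterMixin, BaseEstimator):
    """k-means over MFC feature vectors with automatic elbow selection.

    Parameters
    ----------
    n_clusters : int or "auto", default "auto"
        Fixed k, or elbow-selected from the inertia curve.
    k_max : int, default 10
        Largest k scanned when ``n_clusters="auto"``.
    n_init : int, default 10
        k-means++ restarts; the best inertia wins.
    random_state : int, default 0
        Seed for initialization (deterministic results per seed).

    Attributes
    ----------
    k_ : int — the number of clusters used.
    labels_ : ndarray — 0-based cluster labels (sklearn convention).
    cluster_centers_, inertia_ : fitted k-means state.
    inertias_ : ndarray or None — inertia curve when k was elbow-selected.
    """

    def __init__(
        self,
        n_clusters: int | str = "auto",
        k_max: int = DEFAULT_K_MAX,
        n_init: int = DEFAULT_N_INIT,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.k_max = k_max
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if self.n_clusters == "auto":
            self.k_, self.inertias_ = elbow_k(X, k_max=self.k_max, seed=self.random_state)
        else:
            k = int(self.n_clusters)
            if k < 1 or k > len(X):
                raise DataError(f"k={k} must be in [1, n_frames={len(X)}]")
            self.k_, self.inertias_ = k, None
        self._kmeans = KMeans(
            n_clusters=self.k_, n_init=self.n_init, random_state=self.random_state
        ).fit(X)
        self.labels_ = self._kmeans.labels_
        self.cluster_centers_ = self._kmeans.cluster_centers_
        self.inertia_ = float(self._kmeans.inertia_)
        return self

    def predict(self, X):
        return self._kmeans.predict(_as_matrix(X))


def kmeans_mfc(descriptors, k: int, seed: int = 0, n_init: int = DEFAULT_N_INIT) -> ClusterResult:
    """Standard k-means on MFC vectors with L2 distance; labels 1-based."""
    X = _as_matrix(descriptors)
    if k > len(X) or k < 1:
        raise DataError(f"k={k} must be in [1, n_frames={len(X)}]")
    est = TacticalKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return ClusterResult(
        k=k,
        assignments=est.labels_ + 1,
        centroids=est.cluster_centers_,
        inertia=est.inertia_,
    )


def occurrence_stats(
    result: ClusterResult,
    half_labels: Sequence[int],
    times: Sequence[float] | None = None,
) -> ClusterResult:
    """Attach per-half occurrence percentages and the timeline.

    ``occurrence`` rows are halves, columns clusters C1..Ck, values the
    percentage of that half's frames in each cluster (rows sum to 100).
    """
    halves = np.asarray(half_labels)
    if len(halves) != len(result.assignments):
        raise DataError("half_labels must align with assignments")
    clusters = np.arange(1, result.k + 1)
    rows = {}
    for half in np.unique(halves):
        sel = result.assignments[halves == half]
        counts = np.array([(sel == c).sum() for c in clusters], dtype=float)
        rows[half] = 100.0 * counts / counts.sum()
    result.occurrence = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"C{c}" for c in clusters]
    ).rename_axis("half")
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(halves), dtype=float)
    if len(t) != len(halves):
        raise DataError("times must align with assignments")
    result.timeline = pd.DataFrame(
        {"t": t, "half": halves, "label": result.assignments}
    )
    return result


def representative_shapes(
    result: ClusterResult,
    descriptors,
    image_ids: Sequence[str],
    times: Sequence[float] | None = None,
) -> dict[int, str | None]:
    """One exemplar image id per cluster: the frame whose MFC is nearest
    its centroid; ties broken by earliest time. Empty clusters map to
    None with a warning."""
    X = _as_matrix(descriptors)
    ids = list(image_ids)
    if len(ids) != len(X):
        raise DataError("image_ids must align with descriptors")
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(ids), dtype=float)
    out: dict[int, str | None] = {}
    for c in range(1, result.k + 1):
        members = np.flatnonzero(result.assignments == c)
        if len(members) == 0:
            warnings.warn(f"cluster C{c} is empty; no exemplar", stacklevel=2)
            out[c] = None
            continue
        d = np.linalg.norm(X[members] - result.centroids[c - 1], axis=1)
        order = np.lexsort((t[members], d))
        out[c] = ids[members[order[0]]]
    return out
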