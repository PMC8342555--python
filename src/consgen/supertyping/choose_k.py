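"""Cluster-number selection by majority vote over validity indices.

For each candidate K the rows are clustered by k-means (many restarts),
then a panel of cluster-validity indices each votes for its optimal K;
the majority wins, ties resolved toward the smaller K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

DEFAULT_INDICES = ("calinski_harabasz", "silhouette", "davies_bouldin",
                   "dunn", "gap")


@dataclass
class ChooseKResult:
    best_k: int
    votes: dict          # index name -> K it voted for
    scores: dict         # index name -> {K: score}
    labels: dict         # K -> k-means labels used for scoring


def _dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    clusters = np.unique(labels)
    diameters = []
    for c in clusters:
        pts = x[labels == c]
        diameters.append(pdist(pts).max() if len(pts) > 1 else 0.0)
    max_diam = max(diameters)
    if max_diam == 0:
        return np.inf
    min_sep = np.inf
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            min_sep = min(min_sep, cdist(x[labels == a], x[labels == b]).min())
    return min_sep / max_diam


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def _gap_statistic(x, labels_by_k, rng, n_refs=20):
    """Gap statistic with uniform reference over the bounding box;
    votes via the Tibshirani one-standard-error rule."""
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = sorted(labels_by_k)
    log_w = {k: np.log(max(_within_dispersion(x, labels_by_k[k]), 1e-12))
             for k in ks}
    gap, sk = {}, {}
    for k in ks:
        ref_logs = []
        for _ in range(n_refs):
            ref = rng.uniform(lo, hi, size=x.shape)
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(2**31))).fit(ref)
            ref_logs.append(np.log(max(km.inertia_, 1e-12)))
        ref_logs = np.array(ref_logs)
        gap[k] = float(ref_logs.mean() - log_w[k])
        sk[k] = float(ref_logs.std(ddof=1) * np.sqrt(1 + 1 / n_refs))
    for k in ks[:-1]:
        if gap[k] >= gap[k + 1] - sk[k + 1]:
            return k, gap
    return ks[-1], gap


def choose_k(
    matrix: "pd.DataFrame | np.ndarray",
    k_range=range(2, 9),
    indices=DEFAULT_INDICES,
    seed: "int | None" = None,
    n_restarts: int = 50,
) -> ChooseKResult:
    """Majority-rule optimal cluster number for a descriptor matrix."""
    x = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else \
        np.asarray(matrix, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("all rows identical: cluster number undefined")
    ks = [k for k in k_range if k < len(x)]
    if len(ks) < 2:
        raise ValueError("k_range leaves fewer than 2 feasible K values")
    rng = np.random.default_rng(seed)

    labels_by_k = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2**31)))
        labels_by_k[k] = km.fit_predict(x)

    votes: dict = {}
    scores: dict = {}
    for index in indices:
        if index == "calinski_harabasz":
            s = {k: calinski_harabasz_score(x, labels_by_k[k]) for k in ks}
            votes[index] = max(s, key=s.get)
        elif index == "silhouette":
            s = {k: silhouette_score(x, labels_by_k[k]) for k in ks}
            votes[index] = max(s, key=s.get)
        elif index == "davies_bouldin":
            s = {k: davies_bouldin_score(x, labels_by_k[k]) for k in ks}
            votes[index] = min(s, key=s.get)
        elif index == "dunn":
            s = {k: _dunn_index(x, labels_by_k[k]) for k in ks}
            votes[index] = max(s, key=s.get)
        elif index == "gap":
            votes[index], s = _gap_statistic(x, labels_by_k, rng)
        else:
            raise ValueError(f"unknown validity index {index!r}")
        scores[index] = s

    tally: dict = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    top = max(tally.values())
    best = min(k for k, v in tally.items() if v == top)  # ties -> smaller K
    return ChooseKResult(best, votes, scores, labels_by_k)
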