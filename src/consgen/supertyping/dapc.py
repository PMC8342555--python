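"""Supertype assignment by discriminant analysis of principal components."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from consgen.types import AlleleCatalog


@dataclass
class SupertypeAssignment:
    assignments: dict        # allele name -> supertype label (1..K)
    K: int
    coordinates: "pd.DataFrame | None"   # discriminant coordinates
    votes: "dict | None" = None          # index votes carried from choose_k

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if not labels <= set(range(1, self.K + 1)):
            raise ValueError("labels must lie in 1..K")


def dapc_assign(
    matrix: pd.DataFrame,
    K: int,
    seed: "int | None" = None,
    variance_retained: float = 0.90,
    n_restarts: int = 50,
) -> SupertypeAssignment:
    """Cluster alleles into K supertypes by PCA + k-means + LDA.

    Columns are centred/scaled; principal axes covering
    ``variance_retained`` of the variance (capped at n - K) feed a
    k-means partition, refined by linear discriminant analysis whose
    assignment gives the final labels.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    names = list(matrix.index)
    x = matrix.to_numpy(dtype=float)
    if K == 1:
        return SupertypeAssignment({n: 1 for n in names}, 1, None)
    if K > len(names):
        raise ValueError(f"K={K} exceeds number of alleles {len(names)}")
    rng = np.random.default_rng(seed)

    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd

    max_axes = max(min(len(names) - K, np.linalg.matrix_rank(xs)), 1)
    pca = PCA(n_components=max_axes, random_state=int(rng.integers(2**31)))
    pcs = pca.fit_transform(xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_retained) + 1)
    pcs = pcs[:, :min(n_keep, max_axes)]

    km = KMeans(n_clusters=K, n_init=n_restarts,
                random_state=int(rng.integers(2**31)))
    groups = km.fit_predict(pcs)
    if len(np.unique(groups)) < K:
        raise ValueError("k-means produced fewer than K groups")

    n_disc = min(K - 1, pcs.shape[1])
    lda = LinearDiscriminantAnalysis(n_components=n_disc)
    lda.fit(pcs, groups)
    labels = lda.predict(pcs)
    coords = pd.DataFrame(
        lda.transform(pcs), index=names,
        columns=[f"LD{i + 1}" for i in range(n_disc)],
    )
    # stable label order: rank clusters by first appearance
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    assignments = {n: order[lab] for n, lab in zip(names, labels)}
    return SupertypeAssignment(assignments, K, coords)


def supertype_frequencies(
    assignment: SupertypeAssignment,
    catalog: AlleleCatalog,
    single_allele: str = "homozygote",
) -> pd.DataFrame:
    """Per-population supertype frequency table (rows sum to 1)."""
    freqs = catalog.allele_frequencies(single_allele=single_allele)
    sts = sorted(set(assignment.assignments.values()))
    rows = {}
    for pop, afreq in freqs.items():
        row = {st: 0.0 for st in sts}
        for allele, f in afreq.items():
            row[assignment.assignments[allele]] += f
        rows[pop] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"ST{c}" for c in df.columns]
    return df
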