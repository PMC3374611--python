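"""Hierarchical gene-probe clustering under 1 - correlation dissimilarity.

Probes are clustered with Ward's minimum-variance linkage on the
correlation dissimilarity D = 1 - r.  By default the agglomeration runs on
d' = sqrt(2 D): for row-standardized profiles d'^2 is exactly the squared
Euclidean distance, so Ward's variance criterion is well defined.  The
number of clusters is a user choice guided by the R^2-vs-k curve
(1 - SS_within/SS_total on standardized profiles); cluster centroids
(per-sample median, mean, or first principal component scores) summarize
each cluster for downstream covariate use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

CENTROID_METHODS = ("median", "mean", "pc1")


@dataclass
class ClusterSolution:
    """A cut of the probe dendrogram plus its diagnostics."""

    k: int
    assignment: pd.Series  # probe id -> cluster label in 1..k
    merge_tree: np.ndarray  # scipy linkage matrix
    r2_curve: pd.Series  # k -> R^2
    centroids: pd.DataFrame  # cluster x sample
    centroid_method: str


def correlation_dissimilarity(m: pd.DataFrame) -> pd.DataFrame:
    """Probe x probe dissimilarity D_ij = 1 - Pearson r(profile_i, profile_j).

    Values lie in [0, 2]; D is symmetric with zero diagonal.  Raises for
    zero-variance probes (their correlation is undefined), naming them.
    """
    vals = m.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = vals.std(axis=1)
    dead = m.index[sd == 0]
    if len(dead):
        raise ValueError(
            f"zero-variance probes: {', '.join(map(str, dead[:10]))}"
        )
    r = np.corrcoef(vals)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=m.index, columns=m.index)


def _standardize_rows(vals: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so Euclidean^2 = 2(1-r)."""
    c = vals - vals.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(c, axis=1, keepdims=True)
    if (nrm == 0).any():
        raise ValueError("zero-variance row cannot be standardized")
    return c / nrm


def ward_tree(d: pd.DataFrame, linkage_input: str = "sqrt2d") -> np.ndarray:
    """Ward linkage matrix from a correlation dissimilarity matrix.

    ``linkage_input="sqrt2d"`` feeds sqrt(2 D) (the Euclidean embedding of
    standardized profiles) to the agglomeration; ``"raw"`` feeds D as-is.
    """
    if linkage_input == "sqrt2d":
        dist = np.sqrt(2.0 * d.to_numpy(dtype=float))
    elif linkage_input == "raw":
        dist = d.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown linkage_input {linkage_input!r}")
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method="ward")


def cut_tree(merge_tree: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage matrix into k clusters labelled 1..k."""
    n = merge_tree.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    return fcluster(merge_tree, t=k, criterion="maxclust")


def ward_cluster(
    d: pd.DataFrame, k: int, linkage_input: str = "sqrt2d"
) -> tuple[pd.Series, np.ndarray]:
    """Cluster probes from a dissimilarity matrix; returns (assignment, tree)."""
    tree = ward_tree(d, linkage_input=linkage_input)
    labels = cut_tree(tree, k)
    return pd.Series(labels, index=d.index, name="cluster"), tree


def r2_curve(
    m: pd.DataFrame, merge_tree: np.ndarray, k_range: Iterable[int]
) -> pd.Series:
    """R^2(k) = 1 - SS_within(k)/SS_total on row-standardized profiles."""
    z = _standardize_rows(m.to_numpy(dtype=float))
    grand = z.mean(axis=0)
    ss_total = float(((z - grand) ** 2).sum())
    out = {}
    for k in sorted(set(int(k) for k in k_range)):
        labels = cut_tree(merge_tree, k)
        ss_within = 0.0
        for lab in np.unique(labels):
            sub = z[labels == lab]
            ss_within += float(((sub - sub.mean(axis=0)) ** 2).sum())
        out[k] = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0
    return pd.Series(out, name="r2")


def elbow_k(r2: pd.Series) -> int:
    """k maximizing the second difference of the R^2 curve (advisory only)."""
    ks = r2.index.to_numpy()
    v = r2.to_numpy()
    if len(ks) < 3:
        return int(ks[0])
    second = v[:-2] - 2 * v[1:-1] + v[2:]
    return int(ks[1:-1][np.argmax(second)])


def cluster_centroids(
    m: pd.DataFrame, assignment: pd.Series, method: str = "median"
) -> pd.DataFrame:
    """Per-cluster summary profile over samples.

    median/mean are elementwise over the cluster's probes; pc1 is the
    per-sample score vector of the first principal component of the
    cluster's probe x sample submatrix, sign-oriented to correlate
    positively with the cluster mean profile.
    """
    if method not in CENTROID_METHODS:
        raise ValueError(f"method must be one of {CENTROID_METHODS}")
    assignment = assignment.reindex(m.index)
    if assignment.isna().any():
        raise ValueError("assignment missing for some probes")
    rows = {}
    for lab in sorted(assignment.unique()):
        sub = m.loc[assignment[assignment == lab].index].to_numpy(dtype=float)
        if sub.shape[0] == 0:
            raise ValueError(f"empty cluster {lab}")
        if method == "median":
            rows[lab] = np.median(sub, axis=0)
        elif method == "mean":
            rows[lab] = sub.mean(axis=0)
        else:  # pc1
            # samples are the observations: per-probe centering, scores in sample space
            centered = sub - sub.mean(axis=1, keepdims=True)
            u, sv, vt = np.linalg.svd(centered, full_matrices=False)
            score = vt[0] * sv[0]
            meanp = sub.mean(axis=0)
            if np.corrcoef(score, meanp)[0, 1] < 0:
                score = -score
            rows[lab] = score
    out = pd.DataFrame.from_dict(rows, orient="index", columns=m.columns)
    out.index.name = "cluster"
    return out


def concentration_check(
    fine_assignment: pd.Series,
    coarse_assignment: pd.Series,
    top: int = 2,
    threshold: float = 0.40,
) -> pd.DataFrame:
    """Fraction of each coarse cluster held by its `top` largest fine clusters.

    Used to check that pre-selection did not distort the clustering: for
    each cluster of the selected-probe solution, how concentrated are its
    probes within the clusters of the all-probe solution?  Clusters with
    fraction <= threshold are flagged.
    """
    shared = fine_assignment.index.intersection(coarse_assignment.index)
    if len(shared) == 0:
        raise ValueError("assignments share no probes")
    fine = fine_assignment.loc[shared]
    coarse = coarse_assignment.loc[shared]
    recs = []
    for lab in sorted(coarse.unique()):
        members = coarse[coarse == lab].index
        counts = fine.loc[members].value_counts()
        frac = counts.iloc[:top].sum() / len(members)
        recs.append((lab, len(members), float(frac), frac <= threshold))
    return pd.DataFrame(
        recs, columns=["cluster", "n_probes", "top_fraction", "flagged"]
    ).set_index("cluster")


def cluster_genes(
    m: pd.DataFrame,
    k: int,
    centroid_method: str = "median",
    linkage_input: str = "sqrt2d",
    r2_ks: Optional[Iterable[int]] = None,
) -> ClusterSolution:
    """One-call clustering: dissimilarity -> Ward tree -> cut -> centroids."""
    d = correlation_dissimilarity(m)
    assignment, tree = ward_cluster(d, k, linkage_input=linkage_input)
    if r2_ks is None:
        n = len(m)
        r2_ks = sorted({1, k, n, *np.linspace(1, n, num=min(25, n), dtype=int)})
    curve = r2_curve(m, tree, r2_ks)
    centroids = cluster_centroids(m, assignment, method=centroid_method)
    return ClusterSolution(
        k=k,
        assignment=assignment,
        merge_tree=tree,
        r2_curve=curve,
        centroids=centroids,
        centroid_method=centroid_method,
    )
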