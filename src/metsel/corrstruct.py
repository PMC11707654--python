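"""Trait correlation structure on phenotypic means and on BLUPs.

Pairwise Pearson correlations (with two-sided p-values and complete-pairs
handling of missing entries) and hierarchical clustering of traits with
distance 1 - r, reproducing the numbers behind correlation-network and
heatmap-cluster displays.  BLUP-based correlations are expected to be
attenuated relative to mean-based ones because of shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["CorrelationResult", "pairwise_correlations", "cluster_traits"]


@dataclass
class CorrelationResult:
    basis: str  # "means" or "BLUPs"
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    n_used: pd.DataFrame
    edges: pd.DataFrame  # trait_a, trait_b, r for |r| >= threshold
    threshold: float


def _star(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    for thr, s in [(0.001, "***"), (0.01, "**"), (0.05, "*")]:
        if p <= thr:
            return s
    return "ns"


def pairwise_correlations(
    two_way: pd.DataFrame, basis: str = "means", edge_threshold: float = 0.3
) -> CorrelationResult:
    """Pearson r and two-sided p per trait pair on complete pairs.

    Constant traits get undefined (NaN) correlations off-diagonal rather
    than an error for the whole table.  ``edges`` lists the pairs whose
    absolute correlation reaches ``edge_threshold`` (the data behind a
    correlation network plot).
    """
    if len(two_way) < 3:
        raise ValueError("need at least 3 genotypes for correlations")
    traits = list(two_way.columns)
    p_ = len(traits)
    r = np.eye(p_)
    pv = np.zeros((p_, p_))
    nmat = np.zeros((p_, p_), dtype=int)
    for i in range(p_):
        nmat[i, i] = two_way[traits[i]].notna().sum()
    for i in range(p_):
        for j in range(i + 1, p_):
            pair = two_way[[traits[i], traits[j]]].dropna()
            n = len(pair)
            nmat[i, j] = nmat[j, i] = n
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if n < 3 or x.nunique() < 2 or y.nunique() < 2:
                r[i, j] = r[j, i] = np.nan
                pv[i, j] = pv[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            pv[i, j] = pv[j, i] = pp
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(pv, index=traits, columns=traits)
    rows = []
    for i in range(p_):
        for j in range(i + 1, p_):
            if np.isfinite(r[i, j]) and abs(r[i, j]) >= edge_threshold:
                rows.append({"trait_a": traits[i], "trait_b": traits[j],
                             "r": r[i, j], "p_value": pv[i, j],
                             "signif": _star(pv[i, j])})
    edges = pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p_value", "signif"])
    return CorrelationResult(basis=basis, r_matrix=r_df, p_matrix=p_df,
                             n_used=pd.DataFrame(nmat, index=traits, columns=traits),
                             edges=edges, threshold=edge_threshold)


def cluster_traits(
    data: pd.DataFrame,
    is_correlation: bool = False,
    n_clusters: int = 2,
    linkage_method: str = "average",
):
    """Hierarchical clustering of traits with distance 1 - r.

    ``data`` is either a genotype x trait matrix (correlations computed
    internally) or an already-computed correlation matrix
    (``is_correlation=True``).  Returns a dict with the scipy linkage
    matrix, flat cluster labels per trait at the requested cut, and the
    deterministic leaf order.
    """
    if is_correlation:
        r = data.copy()
    else:
        if data.shape[1] < 2:
            raise ValueError("need at least 2 traits to cluster")
        r = pairwise_correlations(data).r_matrix
    if r.isna().any().any():
        bad = sorted({t for t in r.columns if r[t].isna().any()})
        raise ValueError(f"undefined correlations involving traits: {bad}")
    traits = list(r.columns)
    dist = 1.0 - r.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    leaves = hierarchy.leaves_list(Z)
    return {
        "linkage": Z,
        "clusters": pd.Series(labels, index=traits, name="cluster"),
        "leaf_order": [traits[i] for i in leaves],
        "distance": pd.DataFrame(dist, index=traits, columns=traits),
    }
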