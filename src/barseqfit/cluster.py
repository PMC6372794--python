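"""Clustering of normalized temporal profiles, cofitness, and archetype labels.

The selected genes' cheesecloth-minus-control profiles are grouped by
agglomerative hierarchical clustering (default Euclidean/Ward).  Cofitness —
the Pearson correlation between two genes' profiles — supports
guilt-by-association function prediction.  Because the original cluster
groups in this kind of experiment are curated by eye, a set of explicit
threshold rules assigns each profile to a temporal archetype as a
reproducible surrogate; outputs are labeled as rule-derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from .errors import InputError

METRICS = ("euclidean", "correlation")
LINKAGES = ("average", "ward", "complete")

ARCHETYPES = ("recovery", "hyperadhesive", "biosynthesis", "modification", "unclassified")


@dataclass
class ArchetypeThresholds:
    """Log2-fitness thresholds quantifying the temporal profile classes.

    theta_strong: minimum final fitness of a strong (biosynthesis-like)
    adhesion-defect profile; theta_mild: minimum final fitness of a modest
    (modification-like) profile; theta_neg: early/overall depth marking a
    hyperadhesive dip; floor: lowest final or intermediate value compatible
    with a non-hyperadhesive call; rho_recovery: minimum rebound (final minus
    minimum) for a recovery call.
    """

    theta_strong: float = 2.0
    theta_mild: float = 0.5
    theta_neg: float = -1.0
    floor: float = -0.5
    rho_recovery: float = 1.5

    def __post_init__(self) -> None:
        if not (self.theta_strong > self.theta_mild > 0 > self.theta_neg):
            raise InputError("require theta_strong > theta_mild > 0 > theta_neg")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # locus -> cluster id (1..k)
    tree: np.ndarray  # scipy linkage matrix (merges and heights)


def profile_distance(
    norm: pd.DataFrame, metric: str = "euclidean"
) -> tuple[pd.DataFrame, pd.Index]:
    """Symmetric zero-diagonal distance matrix between gene profiles.

    ``euclidean`` is the L2 distance on profile vectors; ``correlation`` is
    1 - Pearson r.  Zero-variance profiles have no defined correlation: they
    get distance 1 to everything (0 to themselves) and are returned flagged.
    """
    if metric not in METRICS:
        raise InputError(f"metric must be one of {METRICS}")
    if len(norm) < 2:
        raise InputError("need at least 2 genes")
    if norm.isna().any().any():
        raise InputError("profiles contain missing values")
    x = norm.to_numpy(dtype=float)
    flagged = norm.index[x.std(axis=1) == 0.0]
    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    else:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x)
        d = 1.0 - r
        zero_var = np.isin(norm.index, flagged)
        d[zero_var, :] = 1.0
        d[:, zero_var] = 1.0
        np.fill_diagonal(d, 0.0)
        d = np.clip(d, 0.0, None)
        d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=norm.index, columns=norm.index), flagged


def hierarchical_cluster(
    distances: pd.DataFrame, linkage: str = "ward", k: int = 6
) -> ClusterAssignment:
    """Agglomerative clustering of a precomputed distance matrix, cut to k.

    Genes are processed in lexicographic order so the result is invariant to
    input row order; cluster ids are renumbered 1..k by first appearance.
    """
    if linkage not in LINKAGES:
        raise InputError(f"linkage must be one of {LINKAGES}")
    n = len(distances)
    if not 1 <= k <= n:
        raise InputError(f"k={k} outside 1..{n}")
    order = sorted(distances.index)
    d = distances.loc[order, order].to_numpy(dtype=float)
    condensed = squareform(d, checks=False)
    tree = scipy_linkage(condensed, method=linkage)
    flat = cut_tree(tree, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    labels = []
    for c in flat:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(relabel[c])
    return ClusterAssignment(
        labels=pd.Series(labels, index=pd.Index(order, name="locus"), name="cluster"),
        tree=tree,
    )


def cofitness_matrix(norm: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Gene-by-gene Pearson correlation of temporal profiles.

    Diagonal is 1.  Zero-variance profiles yield correlation 0 everywhere
    (by convention, never an exception) and are returned flagged.
    """
    if norm.shape[1] < 2:
        raise InputError("need at least 2 passages per profile")
    x = norm.to_numpy(dtype=float)
    flagged_mask = x.std(axis=1) == 0.0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    r[flagged_mask, :] = 0.0
    r[:, flagged_mask] = 0.0
    np.fill_diagonal(r, 1.0)
    return (
        pd.DataFrame(r, index=norm.index, columns=norm.index),
        norm.index[flagged_mask],
    )


def top_cofit_partners(
    gene: str,
    matrix: pd.DataFrame,
    n: int,
    flagged: pd.Index | None = None,
) -> list[tuple[str, float]]:
    """The n most correlated partner genes, ties broken by identifier."""
    if gene not in matrix.index:
        raise InputError(f"unknown gene {gene!r}")
    flagged = pd.Index([]) if flagged is None else pd.Index(flagged)
    if gene in flagged:
        warnings.warn(f"gene {gene!r} has a zero-variance profile; no partners")
        return []
    row = matrix.loc[gene].drop(index=gene).drop(index=flagged, errors="ignore")
    ordered = (
        pd.DataFrame({"partner": row.index, "r": row.to_numpy()})
        .sort_values(["r", "partner"], ascending=[False, True], kind="stable")
        .head(n)
    )
    return list(ordered.itertuples(index=False, name=None))


def label_archetypes(
    norm: pd.DataFrame, thresholds: ArchetypeThresholds | None = None
) -> pd.Series:
    """Assign each profile to a temporal archetype by first-matching rule.

    Rules, in order (g is the per-passage normalized fitness vector):

    1. recovery — early strong dip (min(g1, g2) <= theta_neg), rebound of at
       least rho_recovery, and a final value no lower than the floor;
    2. hyperadhesive — dips to theta_neg and stays at or below the floor;
    3. biosynthesis — ends at or above theta_strong, never below the floor;
    4. modification — ends in [theta_mild, theta_strong), never below floor;
    5. unclassified otherwise.

    Recovery precedes hyperadhesive so dip-then-rise profiles are not
    swallowed by rule 2.
    """
    th = thresholds or ArchetypeThresholds()
    if norm.isna().any().any():
        raise InputError("profiles contain missing values")
    g = norm.to_numpy(dtype=float)
    g_last = g[:, -1]
    g_min = g.min(axis=1)
    early_min = g[:, : min(2, g.shape[1])].min(axis=1)

    labels = np.full(len(norm), "unclassified", dtype=object)
    recovery = (
        (early_min <= th.theta_neg)
        & (g_last - g_min >= th.rho_recovery)
        & (g_last >= th.floor)
    )
    hyper = ~recovery & (g_min <= th.theta_neg) & (g_last <= th.floor)
    biosyn = ~recovery & ~hyper & (g_last >= th.theta_strong) & (g_min >= th.floor)
    modif = (
        ~recovery
        & ~hyper
        & ~biosyn
        & (g_last >= th.theta_mild)
        & (g_last < th.theta_strong)
        & (g_min >= th.floor)
    )
    labels[recovery] = "recovery"
    labels[hyper] = "hyperadhesive"
    labels[biosyn] = "biosynthesis"
    labels[modif] = "modification"
    return pd.Series(labels, index=norm.index, name="archetype")
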