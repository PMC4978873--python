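"""Woodland typology: clustering plots into vegetation types.

The legend is built the way the field study did it: Bray-Curtis
dissimilarities between plots on the relative AGB abundance of each
species, an average-linkage tree for inspection and naming, and the
number of distinct types selected by the Calinski-Harabasz criterion over
k-means partitions.  Plots are then assigned to types, and plot metrics
are amalgamated within chronosequence classes to give the per-(class,
type) parameters that drive the village-scale production functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from . import inventory
from .config import RunConfig

#: Indicator species conventionally naming each woodland type.
DEFAULT_INDICATORS: dict[str, str] = {
    "Androstachys forest": "A. johnsonii",
    "Mopane woodland": "C. mopane",
    "Combretum woodland": "Combretum spp.",
    "Boscia woodland": "B. albitrunca",
    "shrub Mopane": "Aloe spp.",
}


class DegenerateMatrixError(ValueError):
    """The abundance matrix cannot support clustering (one distinct row)."""


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity, ``sum|x-y| / sum(x+y)``, in [0, 1].

    Undefined (raises) when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def abundance_matrix(plots: list[inventory.Plot], config: RunConfig) -> pd.DataFrame:
    """Plot x species matrix of relative AGB shares (rows sum to 1).

    Plots with no live stems carry no compositional signal and are
    excluded; they are typed from their land-cover stratum downstream.
    """
    rows: dict[str, dict[str, float]] = {}
    for p in plots:
        shares: dict[str, float] = {}
        for s in inventory.live_stems(p):
            dbh = inventory.correct_dbh(s.diameter, s.pom, config.taper)
            shares[s.species] = shares.get(s.species, 0.0) + \
                inventory.stem_agb(dbh, config.allometry)
        if shares:
            rows[p.plot_id] = shares
    mat = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    mat = mat.div(mat.sum(axis=1), axis=0)
    return mat.sort_index(axis=1)


def legend_linkage(matrix: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on Bray-Curtis dissimilarities (for the legend)."""
    condensed = pdist(matrix.to_numpy(), metric="braycurtis")
    return linkage(condensed, method="average")


@dataclass
class TypologyResult:
    k: int
    labels: pd.Series  # plot_id -> cluster index (0..k-1)
    ch_scores: dict[int, float]
    indicator_species: dict[int, str]
    linkage_matrix: np.ndarray | None = field(default=None, repr=False)


def select_k(matrix: pd.DataFrame, k_max: int = 8, seed: int = 0,
             k_min: int = 2, restarts: int = 25) -> TypologyResult:
    """Choose the number of woodland types by the Calinski-Harabasz criterion.

    For each k in [k_min, k_max], k-means (with ``restarts`` seeded
    restarts) partitions the relative-abundance rows and CH(k) =
    [B/(k-1)] / [W/(n-k)] is computed; the argmax wins, with ties broken
    toward smaller k.  The average-linkage legend tree is retained for
    inspection.
    """
    X = matrix.to_numpy()
    n = len(X)
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be below the number of plots ({n})")
    if len(np.unique(X, axis=0)) < 2:
        raise DegenerateMatrixError("abundance matrix has a single distinct row")
    ch_scores: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        labels_by_k[k] = km.labels_
        if len(np.unique(km.labels_)) < 2:
            ch_scores[k] = -np.inf
            continue
        ch_scores[k] = float(calinski_harabasz_score(X, km.labels_))
    best_k = max(sorted(ch_scores), key=lambda k: (ch_scores[k], -k))
    labels = pd.Series(labels_by_k[best_k], index=matrix.index, name="cluster")
    indicators = {
        int(c): str(matrix.loc[labels[labels == c].index].mean(axis=0).idxmax())
        for c in np.unique(labels_by_k[best_k])
    }
    return TypologyResult(k=best_k, labels=labels, ch_scores=ch_scores,
                          indicator_species=indicators,
                          linkage_matrix=legend_linkage(matrix))


def name_clusters(matrix: pd.DataFrame, labels: pd.Series,
                  legend: dict[str, str] = DEFAULT_INDICATORS) -> dict[int, str]:
    """Name clusters by matching them to legend types on indicator shares.

    Solves the assignment that maximises, over cluster-type pairs, the
    cluster's mean relative AGB share of the type's indicator species.
    Clusters left unmatched (k larger than the legend) are named after
    their own top species.
    """
    clusters = sorted(int(c) for c in labels.unique())
    types = list(legend)
    score = np.zeros((len(clusters), len(types)))
    for i, c in enumerate(clusters):
        sub = matrix.loc[labels[labels == c].index]
        means = sub.mean(axis=0)
        for j, t in enumerate(types):
            score[i, j] = means.get(legend[t], 0.0)
    ri, ci = linear_sum_assignment(-score)
    mapping: dict[int, str] = {}
    for i, j in zip(ri, ci):
        mapping[clusters[i]] = types[j]
    for i, c in enumerate(clusters):
        if c not in mapping:
            sub = matrix.loc[labels[labels == c].index]
            mapping[c] = f"cluster: {sub.mean(axis=0).idxmax()}"
    return mapping


def assign_types(plots: list[inventory.Plot], matrix: pd.DataFrame,
                 config: RunConfig, k: int | None = None,
                 legend: dict[str, str] = DEFAULT_INDICATORS) -> pd.Series:
    """Cluster plots and return plot_id -> woodland-type name.

    When ``k`` is None it is fixed to the legend size (the land-cover
    classes the upscaling needs); the CH-selected k is available through
    :func:`select_k` for reporting.  Plots absent from the matrix (no live
    stems) fall back to their sampling stratum, or "other".
    """
    k = k or len(legend)
    km = KMeans(n_clusters=k, n_init=config.kmeans_restarts,
                random_state=config.seed).fit(matrix.to_numpy())
    clusters = pd.Series(km.labels_, index=matrix.index)
    names = name_clusters(matrix, clusters, legend)
    labels = clusters.map(names)
    out = {}
    for p in plots:
        if p.plot_id in labels.index:
            out[p.plot_id] = labels[p.plot_id]
        else:
            out[p.plot_id] = p.stratum if p.stratum else "other"
    return pd.Series(out, name="type")


def label_agreement(true_labels: pd.Series, pred_labels: pd.Series) -> float:
    """Best-bipartite-matching label agreement between two partitions.

    Builds the confusion matrix, solves the assignment that maximises the
    matched count, and returns the matched fraction in [0, 1].
    """
    idx = true_labels.index.intersection(pred_labels.index)
    conf = pd.crosstab(true_labels.loc[idx], pred_labels.loc[idx])
    ri, ci = linear_sum_assignment(-conf.to_numpy())
    matched = conf.to_numpy()[ri, ci].sum()
    return float(matched / len(idx))


def amalgamate(metrics: pd.DataFrame, labels: pd.Series,
               class_map: dict[str, str], min_n: int = 4) -> pd.DataFrame:
    """Per-(class, type) means and SEs of per-plot metrics.

    ``metrics`` is a per-plot frame (indexed by plot_id) with a ``village``
    column and numeric metric columns.  Plots are pooled within
    chronosequence classes; SEs are suppressed (NaN) below ``min_n`` plots,
    and n is counted per metric (NaN metric values, e.g. grass on burnt
    plots, do not count).
    """
    df = metrics.copy()
    df["type"] = labels.reindex(df.index)
    df["class"] = df["village"].map(class_map)
    if df["class"].isna().any():
        missing = sorted(df.loc[df["class"].isna(), "village"].unique())
        raise ValueError(f"villages without a chronosequence class: {missing}")
    num_cols = [c for c in df.columns
                if c not in ("village", "class", "type") and
                pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for (cls, typ), grp in df.groupby(["class", "type"], sort=True):
        for m in num_cols:
            mean, se = inventory.mean_se(grp[m], min_n=min_n)
            rows.append({"class": cls, "type": typ, "metric": m, "mean": mean,
                         "se": se, "n": int(grp[m].notna().sum())})
    return pd.DataFrame(rows)


def counts_table(labels: pd.Series, villages: pd.Series,
                 class_map: dict[str, str]) -> pd.DataFrame:
    """Plots per village x woodland type, with class, village and type
    margins — the bookkeeping table for the amalgamation step."""
    df = pd.DataFrame({"type": labels, "village": villages.reindex(labels.index)})
    df["class"] = df["village"].map(class_map)
    tab = pd.crosstab([df["class"], df["village"]], df["type"])
    tab["total"] = tab.sum(axis=1)
    class_totals = tab.groupby(level="class").sum()
    class_totals.index = pd.MultiIndex.from_tuples(
        [(c, "(class total)") for c in class_totals.index],
        names=["class", "village"])
    grand = tab.sum(axis=0).to_frame().T
    grand.index = pd.MultiIndex.from_tuples([("(all)", "(total)")],
                                            names=["class", "village"])
    return pd.concat([tab, class_totals, grand]).sort_index()
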