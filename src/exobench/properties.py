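"""Intrinsic pathway metrics that explain enrichment detectability.

Six per-pathway quantities are computed:

* size — number of metabolites in the pathway set;
* exchangeable ratio — fraction of the pathway's non-side metabolites that
  possess an exchange reaction (how visible the pathway can be in an
  exometabolomic profile);
* uniqueness score — for the pathway's knockout profile, the sum over its
  |z| >= thr metabolites of 1/n_m, where n_m counts the knockout profiles
  containing that metabolite (rewards profile-specific metabolites);
* clustering coefficient, degree and neighbourhood connectivity of the
  pathway's node in the pathway-overlap graph (nodes = pathways, edge iff
  two pathways share at least one non-side metabolite, weight = number of
  shared metabolites; statistics are computed on the unweighted topology).

Also here: per-knockout z-score dispersion summaries, rank-sum TP-vs-FN
comparisons with Benjamini-Hochberg adjustment, and a standardised PCA of
the metric table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .model import MetabolitePathwaySets
from .simulate import ZScoreProfile

__all__ = [
    "PathwayProperties",
    "exchangeable_ratio",
    "thresholded_metabolites",
    "uniqueness_score",
    "build_pathway_graph",
    "graph_statistics",
    "ko_zscore_dispersion",
    "properties_table",
    "compare_tp_fn",
    "pathway_pca",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "size",
    "exchangeable_ratio",
    "uniqueness_score",
    "clustering_coefficient",
    "degree",
    "neighbourhood_connectivity",
)


@dataclass(frozen=True)
class PathwayProperties:
    pathway_id: str
    size: int
    exchangeable_ratio: float | None
    uniqueness_score: float
    clustering_coefficient: float
    degree: int
    neighbourhood_connectivity: float


def exchangeable_ratio(
    pathway_id: str,
    sets_no_side: MetabolitePathwaySets,
    background: frozenset[str],
) -> float | None:
    """Share of the pathway's non-side metabolites that are exchangeable.

    ``sets_no_side`` must be the side-compound-free pathway sets; a pathway
    with no non-side metabolite has no defined ratio (None).
    """
    members = sets_no_side[pathway_id]
    if not members:
        return None
    return len(members & background) / len(members)


def thresholded_metabolites(
    profiles: dict[str, ZScoreProfile], thr: float = 2.0
) -> dict[str, frozenset[str]]:
    """Per scenario, the metabolites with |z| >= thr."""
    return {
        pid: frozenset(m for m, z in pr.zscores.items() if abs(z) >= thr)
        for pid, pr in profiles.items()
    }


def uniqueness_score(
    scenario: str,
    profiles: dict[str, ZScoreProfile],
    thr: float = 2.0,
) -> float:
    """Sum of 1/n_m over the scenario's |z| >= thr metabolites.

    n_m is the number of knockout profiles whose thresholded set contains m;
    metabolites unique to this profile contribute 1, widely shared ones
    almost nothing.  An empty thresholded set scores 0.
    """
    sets = thresholded_metabolites(profiles, thr)
    if scenario not in sets:
        raise KeyError(f"scenario {scenario!r} has no profile")
    counts: dict[str, int] = {}
    for members in sets.values():
        for m in members:
            counts[m] = counts.get(m, 0) + 1
    return float(sum(1.0 / counts[m] for m in sets[scenario]))


def build_pathway_graph(sets_no_side: MetabolitePathwaySets) -> nx.Graph:
    """Pathway-overlap graph: edge iff >=1 shared non-side metabolite.

    Edge weight is the number of shared metabolites; the weight is carried
    for export/layout, topology statistics ignore it.
    """
    g = nx.Graph()
    pids = sorted(sets_no_side.sets)
    g.add_nodes_from(pids)
    for i, p in enumerate(pids):
        for q in pids[i + 1:]:
            shared = len(sets_no_side[p] & sets_no_side[q])
            if shared >= 1:
                g.add_edge(p, q, weight=shared)
    return g


def graph_statistics(graph: nx.Graph, node: str) -> tuple[float, int, float]:
    """(clustering coefficient, degree, neighbourhood connectivity) of a node.

    Unweighted: clustering = 2 * triangles / (deg * (deg - 1)) (0 for
    degree < 2); neighbourhood connectivity = mean degree of the node's
    neighbours (0 for an isolated node).
    """
    if node not in graph:
        raise KeyError(f"{node!r} not in graph")
    deg = graph.degree(node)
    clustering = float(nx.clustering(graph, node))
    neighbours = list(graph.neighbors(node))
    ncon = float(np.mean([graph.degree(v) for v in neighbours])) if neighbours else 0.0
    return clustering, int(deg), ncon


def ko_zscore_dispersion(
    scenario: str,
    profile: ZScoreProfile,
    sets: MetabolitePathwaySets,
) -> dict | None:
    """z-scores of the knocked-out pathway's own metabolites, with spread.

    Returns the z values present in the profile, their sample standard
    deviation and the 1.5*IQR outliers, or None when the pathway has no
    metabolite in the profile.  Pathways whose knockout barely moves their
    own metabolites (low sd) are the ones enrichment tends to miss.
    """
    own = sets[scenario]
    zs = np.array([z for m, z in sorted(profile.zscores.items()) if m in own])
    if zs.size == 0:
        return None
    q1, q3 = np.percentile(zs, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = zs[(zs < lo) | (zs > hi)]
    sd = float(zs.std(ddof=1)) if zs.size > 1 else 0.0
    return {
        "scenario": scenario,
        "zscores": zs,
        "sd": sd,
        "outliers": outliers,
    }


def properties_table(
    sets_full: MetabolitePathwaySets,
    sets_no_side: MetabolitePathwaySets,
    background: frozenset[str],
    profiles: dict[str, ZScoreProfile],
    thr: float = 2.0,
    size_includes_side: bool = True,
) -> pd.DataFrame:
    """All six metrics for every pathway that has a knockout profile."""
    graph = build_pathway_graph(sets_no_side)
    rows = []
    for pid in sorted(profiles):
        clustering, degree, ncon = graph_statistics(graph, pid)
        size_sets = sets_full if size_includes_side else sets_no_side
        rows.append(
            {
                "pathway": pid,
                "size": len(size_sets[pid]),
                "exchangeable_ratio": exchangeable_ratio(pid, sets_no_side, background),
                "uniqueness_score": uniqueness_score(pid, profiles, thr),
                "clustering_coefficient": clustering,
                "degree": degree,
                "neighbourhood_connectivity": ncon,
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def compare_tp_fn(
    properties: pd.DataFrame,
    labels: dict[str, dict[str, str]],
) -> pd.DataFrame:
    """Two-sided rank-sum tests of each metric between TP and FN pathways.

    ``labels`` maps method -> {pathway -> "TP" | "FN"}.  P-values are
    Benjamini-Hochberg adjusted across the whole metric x method family.
    Methods with fewer than one pathway on either side are skipped.
    """
    rows = []
    for method, lab in sorted(labels.items()):
        tp = [p for p, v in lab.items() if v == "TP" and p in properties.index]
        fn = [p for p, v in lab.items() if v == "FN" and p in properties.index]
        if not tp or not fn:
            continue
        for metric in METRIC_COLUMNS:
            if metric not in properties.columns:
                continue
            x = properties.loc[tp, metric].dropna()
            y = properties.loc[fn, metric].dropna()
            if x.empty or y.empty:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"metric": metric, "method": method,
                         "statistic": float(stat), "p_raw": float(p)})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["p_adjusted"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


def pathway_pca(
    properties: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the standardised metric table.

    Columns are centred and scaled to unit variance; constant or incomplete
    columns are dropped with a warning.  Component signs are fixed so the
    largest-magnitude loading of each axis is positive, which makes the
    result deterministic.  Returns (coordinates, loadings,
    explained-variance on the eigenvalue scale, summing to the number of
    retained columns).
    """
    data = properties[list(c for c in METRIC_COLUMNS if c in properties.columns)]
    data = data.dropna(axis=1, how="any").astype(float)
    keep = data.columns[data.std(ddof=0) > 0]
    if len(keep) < len(data.columns):
        dropped = sorted(set(data.columns) - set(keep))
        warnings.warn(f"dropping constant metric columns: {dropped}")
    data = data[keep]
    if data.shape[0] < 3 or data.shape[1] < 1:
        raise ValueError("need >=3 pathways and >=1 varying metric for PCA")
    z = (data - data.mean()) / data.std(ddof=0)
    pca = PCA()
    coords = pca.fit_transform(z.to_numpy())
    load = pca.components_
    for i in range(load.shape[0]):
        j = int(np.argmax(np.abs(load[i])))
        if load[i, j] < 0:
            load[i] *= -1.0
            coords[:, i] *= -1.0
    names = [f"PC{i + 1}" for i in range(load.shape[0])]
    # eigenvalue scale (population variance), sums to the column count
    explained = pca.explained_variance_ * (len(z) - 1) / len(z)
    return (
        pd.DataFrame(coords, index=data.index, columns=names),
        pd.DataFrame(load, index=names, columns=data.columns),
        explained,
    )
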