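"""Correlation-based co-occurrence networks and their topology statistics.

A network is built per treatment group from a rarefied ASV table: all
pairwise ASV correlations are computed, p-values are Benjamini-Hochberg
adjusted over every tested pair, and pairs with adjusted p below the
threshold become signed edges.  The topology vector mirrors the metrics used
to compare such networks between treatments: node/edge counts,
positive/negative edge ratio, average degree, clustering coefficient,
density, characteristic path length and modularity.  Group comparison uses
repeated 70%-depth subsampling with a Mann-Whitney test per metric.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .asv import AsvTable
from .stats import mann_whitney

__all__ = [
    "build_network",
    "NetworkMetrics",
    "network_metrics",
    "modularity_best",
    "NetworkComparison",
    "compare_network_groups",
]

METRIC_NAMES = [
    "n_nodes",
    "n_edges",
    "pos_neg_ratio",
    "average_degree",
    "clustering_coefficient",
    "density",
    "path_length",
    "modularity",
]

#: Graphs up to this many nodes get an exhaustive modularity search;
#: larger graphs use Louvain with a fixed internal seed.
EXACT_MODULARITY_MAX_NODES = 8


def _pearson_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrix with two-sided p-values from the t transform."""
    n = x.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p


def build_network(
    table: AsvTable,
    method: str = "pearson",
    alpha: float = 0.05,
    prevalence_filter: float = 0.2,
) -> nx.Graph:
    """Build a signed co-occurrence network from a (rarefied) ASV table.

    ASVs present in no more than ``prevalence_filter`` of the samples are
    removed before correlation (low-prevalence taxa destabilise correlation
    estimates).  All remaining pairs are tested; Benjamini-Hochberg FDR
    adjustment is applied across every pair, and edges with adjusted
    p < ``alpha`` are kept with attributes ``r`` (signed correlation),
    ``p_adj`` and ``sign`` (+1/-1).  Nodes that end up with no edge are
    dropped from the graph; their count is recorded in
    ``graph.graph["n_isolated_dropped"]``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples to estimate correlations")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    prevalence = (table.counts > 0).mean(axis=0)
    keep = prevalence.index[prevalence > prevalence_filter]
    sub = table.counts[keep]
    asvs = list(sub.columns)
    x = sub.to_numpy(dtype=float)
    m = len(asvs)

    graph = nx.Graph(
        method=method,
        alpha=alpha,
        prevalence_filter=prevalence_filter,
        n_asvs_tested=m,
    )
    if m < 2:
        graph.graph["n_isolated_dropped"] = m
        return graph

    if method == "pearson":
        r, p = _pearson_matrix(x)
    else:
        # rank-transform columns (midranks) then Pearson = Spearman
        ranks = np.apply_along_axis(sps.rankdata, 0, x)
        r, p = _pearson_matrix(ranks)

    iu, ju = np.triu_indices(m, k=1)
    r_pairs = r[iu, ju]
    p_pairs = p[iu, ju]
    valid = ~np.isnan(r_pairs)  # constant columns give nan correlations
    p_adj = np.full_like(p_pairs, np.nan)
    if valid.sum() > 0:
        p_adj[valid] = multipletests(p_pairs[valid], method="fdr_bh")[1]

    for k in np.flatnonzero(valid):
        if p_adj[k] < alpha:
            a, b = asvs[iu[k]], asvs[ju[k]]
            graph.add_edge(
                a,
                b,
                r=float(r_pairs[k]),
                p_adj=float(p_adj[k]),
                sign=1 if r_pairs[k] > 0 else -1,
            )
    graph.graph["n_isolated_dropped"] = m - graph.number_of_nodes()
    return graph


@dataclass(frozen=True)
class NetworkMetrics:
    """Topology summary of a co-occurrence network.

    ``pos_neg_ratio`` is ``inf`` (with ``pos_neg_ratio_defined=False``) when
    the network has no negative edge.
    """

    n_nodes: int
    n_edges: int
    pos_neg_ratio: float
    average_degree: float
    clustering_coefficient: float
    density: float
    path_length: float
    modularity: float
    n_components: int = 1
    pos_neg_ratio_defined: bool = True

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in METRIC_NAMES})


def _exhaustive_modularity(graph: nx.Graph) -> float:
    """Maximum Newman Q over every partition of the node set (tiny graphs)."""
    nodes = list(graph.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield [[head]] + part

    best = -math.inf
    for part in partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in part], weight=None)
        if q > best:
            best = q
    return best


def modularity_best(graph: nx.Graph) -> float:
    """Best-partition Newman modularity (unweighted, resolution 1).

    Exact (exhaustive over partitions) for graphs with at most
    ``EXACT_MODULARITY_MAX_NODES`` nodes, Louvain with a fixed seed above
    that, so the value is deterministic for a given graph.
    """
    if graph.number_of_edges() == 0:
        return 0.0
    if graph.number_of_nodes() <= EXACT_MODULARITY_MAX_NODES:
        return _exhaustive_modularity(graph)
    parts = nx.community.louvain_communities(graph, weight=None, seed=0)
    return nx.community.modularity(graph, parts, weight=None)


def network_metrics(graph: nx.Graph) -> NetworkMetrics:
    """Compute the topology-metric vector of a co-occurrence network.

    Clustering is the mean local clustering coefficient over all nodes
    (degree < 2 contributes 0); path length is the mean shortest path over
    *connected* pairs only (components are counted separately); modularity is
    Newman Q of the best partition of the unsigned graph.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    e = graph.number_of_edges()
    signs = [d.get("sign", 1) for _, _, d in graph.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = len(signs) - n_pos
    if n_neg > 0:
        ratio, defined = n_pos / n_neg, True
    else:
        ratio, defined = math.inf, False

    avg_degree = 2.0 * e / n
    clustering = nx.average_clustering(graph) if n > 0 else 0.0
    density = nx.density(graph)

    # mean shortest path over connected pairs, pooled across components
    total, pairs = 0.0, 0
    components = list(nx.connected_components(graph))
    for comp in components:
        if len(comp) < 2:
            continue
        sub = graph.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += len(comp) * (len(comp) - 1)
    path_length = total / pairs if pairs else 0.0

    q = modularity_best(graph)
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        pos_neg_ratio=ratio,
        average_degree=avg_degree,
        clustering_coefficient=clustering,
        density=density,
        path_length=path_length,
        modularity=q,
        n_components=len(components),
        pos_neg_ratio_defined=defined,
    )


# -- group comparison by subsample permutation ----------------------------

@dataclass
class NetworkComparison:
    """Replicate metric distributions per group and Mann-Whitney p per factor."""

    replicates: pd.DataFrame  # columns: group, replicate, <metrics>
    p_values: pd.DataFrame  # index: metric; columns: factor names
    summary: pd.DataFrame  # mean metric per group
    params: dict = field(default_factory=dict)


def _subsample_table(table: AsvTable, fraction: float, rng) -> AsvTable:
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        depth = int(math.floor(fraction * row.sum()))
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AsvTable(counts, table.metadata)


def compare_network_groups(
    tables: Mapping[object, AsvTable],
    subsample_fraction: float = 0.7,
    n_reps: int = 50,
    seed: Optional[int] = None,
    factors: Optional[Mapping[object, Mapping[str, object]]] = None,
    method: str = "pearson",
    alpha: float = 0.05,
    prevalence_filter: float = 0.2,
) -> NetworkComparison:
    """Compare network topology between groups by repeated subsampling.

    Per replicate and group, every sample is subsampled without replacement
    to ``subsample_fraction`` of its reads, the network is rebuilt and its
    metrics recorded.  Per metric, replicate distributions are compared with
    a two-sided Mann-Whitney test, either pairwise between groups (default)
    or pooled by the levels of each named factor when ``factors`` maps each
    group to its factor levels (e.g. ``{("FTS","M"): {"system": "FTS",
    "diet": "M"}, ...}``).

    Groups with fewer than 4 samples are excluded with a warning; at least
    two groups and ``n_reps >= 20`` are required.
    """
    if n_reps < 20:
        raise ValueError("n_reps must be at least 20 for a meaningful comparison")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    usable = {}
    for g, t in tables.items():
        if t.n_samples < 4:
            warnings.warn(f"group {g!r} has fewer than 4 samples; excluded")
            continue
        usable[g] = t
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 4 samples")

    rng = np.random.default_rng(seed)
    rows = []
    for g, t in usable.items():
        for rep in range(n_reps):
            sub = _subsample_table(t, subsample_fraction, rng)
            net = build_network(
                sub, method=method, alpha=alpha, prevalence_filter=prevalence_filter
            )
            if net.number_of_nodes() == 0:
                metrics = {name: 0.0 for name in METRIC_NAMES}
            else:
                metrics = network_metrics(net).as_series().to_dict()
            rows.append({"group": g, "replicate": rep, **metrics})
    reps = pd.DataFrame(rows)

    # finite values only for rank tests: undefined (inf) ratios are treated
    # as the largest rank, which the Mann-Whitney handles via midranks after
    # capping at a large finite value
    def finite(series):
        vals = series.to_numpy(dtype=float)
        if np.isinf(vals).any():
            cap = np.nanmax(np.where(np.isinf(vals), np.nan, vals))
            cap = 1.0 if not np.isfinite(cap) else cap
            vals = np.where(np.isinf(vals), cap * 10 + 1, vals)
        return vals

    comparisons: dict[str, dict[str, float]] = {}
    if factors:
        for factor in next(iter(factors.values())):
            levels = pd.unique(pd.Series([factors[g][factor] for g in usable]))
            if len(levels) != 2:
                raise ValueError(
                    f"factor {factor!r} must have exactly 2 levels for the test"
                )
            g_a = [g for g in usable if factors[g][factor] == levels[0]]
            g_b = [g for g in usable if factors[g][factor] == levels[1]]
            comparisons[factor] = {}
            for metric in METRIC_NAMES:
                a = finite(reps.loc[reps["group"].isin(g_a), metric])
                b = finite(reps.loc[reps["group"].isin(g_b), metric])
                _, p = mann_whitney(a, b)
                comparisons[factor][metric] = p
    else:
        for g_a, g_b in itertools.combinations(usable, 2):
            name = f"{g_a} vs {g_b}"
            comparisons[name] = {}
            for metric in METRIC_NAMES:
                a = finite(reps.loc[reps["group"] == g_a, metric])
                b = finite(reps.loc[reps["group"] == g_b, metric])
                _, p = mann_whitney(a, b)
                comparisons[name][metric] = p

    p_values = pd.DataFrame(comparisons).reindex(METRIC_NAMES)
    summary = reps.groupby("group")[METRIC_NAMES].mean()
    return NetworkComparison(
        replicates=reps,
        p_values=p_values,
        summary=summary,
        params={
            "subsample_fraction": subsample_fraction,
            "n_reps": n_reps,
            "seed": seed,
            "method": method,
            "alpha": alpha,
            "prevalence_filter": prevalence_filter,
        },
    )
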