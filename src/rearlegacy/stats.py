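"""Permutation statistics for community data.

Implements the distance-based tests used to compare gut communities between
treatments from first principles:

* one- and two-way PERMANOVA (pseudo-F on a dissimilarity matrix, p by label
  permutation, with exact enumeration for small two-group designs),
* SIMPER (decomposition of the average between-group Bray-Curtis
  dissimilarity into per-ASV contributions),
* IndVal indicator-species analysis (specificity x fidelity, permutation p),
* DistLM-style marginal tests (dbRDA pseudo-F of a single predictor against
  the Gower-centred distance matrix),
* a Mann-Whitney U wrapper with the conventions used throughout (midranks,
  exact p for small samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .asv import AsvTable

__all__ = [
    "PermanovaResult",
    "permanova",
    "SimperResult",
    "simper",
    "indicator_species",
    "distlm_marginal",
    "pearson_axis_correlation",
    "mann_whitney",
]


# -- helpers --------------------------------------------------------------

def _as_square(dm) -> tuple[np.ndarray, list]:
    if isinstance(dm, DistanceMatrix):
        return np.asarray(dm.data, dtype=float), list(dm.ids)
    arr = np.asarray(dm, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr, list(range(arr.shape[0]))


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Within-group sum of squared interpoint distances, each divided by group size."""
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) == 0:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * len(idx))
    return ss


@dataclass
class PermanovaResult:
    """Per-term pseudo-F, R-squared and permutation p-value."""

    table: pd.DataFrame  # index: term; columns: pseudo_F, R2, p_value, permutations
    method: str = "permanova"

    def __getitem__(self, term):
        return self.table.loc[term]


def _oneway_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within <= 0:
        # all within-group distances zero: F degenerate
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    dm,
    grouping,
    grouping2=None,
    n_perm: Union[int, str] = 9999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    One-way when only ``grouping`` is given; two-way crossed main effects
    when ``grouping2`` is also given (unrestricted permutation of raw
    observations, no interaction term, residual df = n - a - b + 1).

    ``n_perm="exhaustive"`` enumerates every distinct assignment (one-way,
    two groups only) and returns the exact permutation p-value
    ``#{F >= F_obs} / N`` over all N assignments (the identity included).
    For sampled permutations ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.

    ``grouping`` may be a sequence aligned to the matrix order or a pandas
    Series indexed by sample id.
    """
    d, ids = _as_square(dm)
    n = d.shape[0]
    d2 = d ** 2

    def align(g):
        if isinstance(g, pd.Series):
            if set(g.index) == set(ids):
                g = g.reindex(ids)
            else:
                g = g.copy()
                g.index = g.index.map(str)
                g = g.reindex([str(i) for i in ids])
            if g.isna().any():
                raise ValueError("grouping does not cover all samples")
            return np.asarray(g)
        g = np.asarray(g)
        if len(g) != n:
            raise ValueError("grouping length does not match distance matrix")
        return g

    g1 = align(grouping)
    codes1, levels1 = pd.factorize(g1)
    a = len(levels1)
    if a < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes1)
    if (counts < 2).any():
        raise ValueError("each group needs at least 2 samples")

    rng = np.random.default_rng(seed)

    if grouping2 is None:
        f_obs = _oneway_f(d2, codes1, a)
        if n_perm == "exhaustive":
            if a != 2:
                raise ValueError("exhaustive enumeration supports two groups only")
            n1 = counts[0]
            ge = 0
            total = 0
            base = np.ones(n, dtype=int)
            for combo in itertools.combinations(range(n), int(n1)):
                codes = base.copy()
                codes[list(combo)] = 0
                f = _oneway_f(d2, codes, 2)
                total += 1
                if f >= f_obs - 1e-12:
                    ge += 1
            p = ge / total
            used = total
        else:
            n_perm = int(n_perm)
            if n_perm < 1:
                raise ValueError("n_perm must be positive")
            ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                f = _oneway_f(d2, codes1[perm], a)
                if f >= f_obs - 1e-12:
                    ge += 1
            p = (1 + ge) / (1 + n_perm)
            used = n_perm
        ss_total = d2.sum() / (2 * n)
        r2 = 1 - _ss_within(d2, codes1, a) / ss_total if ss_total > 0 else 0.0
        tbl = pd.DataFrame(
            {
                "pseudo_F": [f_obs],
                "R2": [r2],
                "p_value": [p],
                "permutations": [used],
            },
            index=["grouping"],
        )
        return PermanovaResult(table=tbl)

    # two-way crossed main effects
    g2 = align(grouping2)
    codes2, levels2 = pd.factorize(g2)
    b = len(levels2)
    if b < 2:
        raise ValueError("need at least 2 groups in the second factor")
    cross = pd.crosstab(pd.Series(codes1), pd.Series(codes2))
    if (cross.to_numpy() == 0).any():
        raise ValueError(
            "factors are confounded: empty cells in the cross-design"
        )
    if n_perm == "exhaustive":
        raise ValueError("exhaustive enumeration is one-way two-group only")
    n_perm = int(n_perm)

    ss_total = d2.sum() / (2.0 * n)
    df_res = n - a - b + 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom in the two-way design")

    def terms_f(c1, c2):
        ss_a = ss_total - _ss_within(d2, c1, a)
        ss_b = ss_total - _ss_within(d2, c2, b)
        ss_res = ss_total - ss_a - ss_b
        ss_res = max(ss_res, 1e-300)
        fa = (ss_a / (a - 1)) / (ss_res / df_res)
        fb = (ss_b / (b - 1)) / (ss_res / df_res)
        return fa, fb, ss_a, ss_b

    fa_obs, fb_obs, ss_a, ss_b = terms_f(codes1, codes2)
    ge_a = ge_b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fa, fb, _, _ = terms_f(codes1[perm], codes2[perm])
        if fa >= fa_obs - 1e-12:
            ge_a += 1
        if fb >= fb_obs - 1e-12:
            ge_b += 1
    tbl = pd.DataFrame(
        {
            "pseudo_F": [fa_obs, fb_obs],
            "R2": [ss_a / ss_total, ss_b / ss_total],
            "p_value": [(1 + ge_a) / (1 + n_perm), (1 + ge_b) / (1 + n_perm)],
            "permutations": [n_perm, n_perm],
        },
        index=["factor1", "factor2"],
    )
    return PermanovaResult(table=tbl, method="two-way permanova")


# -- SIMPER ---------------------------------------------------------------

@dataclass
class SimperResult:
    """SIMPER decomposition between two groups.

    ``overall`` is the average between-group Bray-Curtis dissimilarity in
    percent; ``contributions`` holds, per ASV, the average contribution (%)
    to that dissimilarity, its share, and the cumulative share, ranked by
    contribution.
    """

    overall: float
    contributions: pd.DataFrame
    groups: tuple


def simper(
    table: AsvTable,
    grouping,
    use_relative: bool = False,
) -> SimperResult:
    """Similarity-percentage analysis between exactly two groups.

    For every between-group sample pair (x, y) the Bray-Curtis dissimilarity
    decomposes additively as sum_k |x_k - y_k| / (sum x + sum y); SIMPER
    averages each ASV's term over all pairs.  The per-ASV contributions sum
    to the overall (mean) between-group dissimilarity exactly.

    ``use_relative=True`` converts samples to proportions first; the default
    operates on the table as given (typically rarefied counts).
    """
    if isinstance(grouping, str):
        grouping = table.grouping(grouping)
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[table.counts.index]
        labels = np.asarray(grouping)
    else:
        labels = np.asarray(grouping)
        if len(labels) != table.n_samples:
            raise ValueError("grouping length mismatch")
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("SIMPER requires exactly two groups")
    data = table.relative_abundance() if use_relative else table.counts.astype(float)
    x = data.loc[labels == levels[0]].to_numpy()
    y = data.loc[labels == levels[1]].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 samples")
    contrib = np.zeros(data.shape[1])
    n_pairs = 0
    for xi in x:
        for yj in y:
            denom = xi.sum() + yj.sum()
            if denom == 0:
                raise ValueError("pair of empty samples")
            contrib += np.abs(xi - yj) / denom
            n_pairs += 1
    contrib = 100.0 * contrib / n_pairs
    overall = float(contrib.sum())
    order = np.argsort(contrib)[::-1]
    df = pd.DataFrame(
        {
            "contribution_pct": contrib[order],
            "share": contrib[order] / overall if overall > 0 else 0.0,
        },
        index=np.asarray(table.asv_ids)[order],
    )
    df["cumulative_share"] = df["share"].cumsum()
    return SimperResult(overall=overall, contributions=df, groups=tuple(levels))


# -- indicator species ----------------------------------------------------

def indicator_species(
    table: AsvTable,
    grouping,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """IndVal indicator-species analysis.

    For each ASV and group: specificity A = mean abundance in the group over
    the sum of group means; fidelity B = fraction of the group's samples in
    which the ASV occurs; the indicator statistic is sqrt(A * B) for the best
    group.  p-values come from ``n_perm`` group-label permutations
    (``p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)``).

    Constant-zero ASVs are excluded.  Returns a DataFrame indexed by ASV with
    columns ``group``, ``stat``, ``p_value``, ``significant``.
    """
    if isinstance(grouping, str):
        grouping = table.grouping(grouping)
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[table.counts.index]
    labels = np.asarray(grouping)
    codes, levels = pd.factorize(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")

    X = table.counts.to_numpy(dtype=float)
    nonzero = X.sum(axis=0) > 0
    asvs = np.asarray(table.asv_ids)[nonzero]
    X = X[:, nonzero]

    def indval_matrix(codes_):
        means = np.vstack([X[codes_ == g].mean(axis=0) for g in range(len(levels))])
        occs = np.vstack([(X[codes_ == g] > 0).mean(axis=0) for g in range(len(levels))])
        denom = means.sum(axis=0)
        denom[denom == 0] = 1.0
        spec = means / denom
        return np.sqrt(spec * occs)

    iv = indval_matrix(codes)
    best_group = iv.argmax(axis=0)
    stat_obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    ge = np.zeros_like(stat_obs)
    for _ in range(int(n_perm)):
        perm_codes = codes[rng.permutation(len(codes))]
        stat_perm = indval_matrix(perm_codes).max(axis=0)
        ge += stat_perm >= stat_obs - 1e-12
    p = (1 + ge) / (1 + n_perm)

    out = pd.DataFrame(
        {
            "group": np.asarray(levels)[best_group],
            "stat": stat_obs,
            "p_value": p,
        },
        index=asvs,
    )
    out["significant"] = out["p_value"] < alpha
    return out.sort_values("p_value")


# -- DistLM ---------------------------------------------------------------

def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def distlm_marginal(
    dm,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Marginal (one predictor at a time) distance-based linear model tests.

    Each predictor is tested alone against the Gower-centred matrix G of the
    squared distances: with hat matrix H of the centred predictor,
    pseudo-F = tr(GH) / [(tr(G) - tr(GH)) / (n - 2)], and the proportion of
    multivariate variation explained is tr(GH) / tr(G).  p-values come from
    permuting the predictor.
    """
    d, ids = _as_square(dm)
    n = d.shape[0]
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    if set(predictors.index) == set(ids):
        predictors = predictors.reindex(ids)
    elif set(predictors.index.map(str)) == set(map(str, ids)):
        predictors = predictors.set_axis(predictors.index.map(str)).reindex(
            [str(i) for i in ids]
        )
    if predictors.isna().any().any():
        raise ValueError("predictors contain missing values")
    if len(predictors) != n:
        raise ValueError("predictors do not align with samples")
    G = _gower_center(d ** 2)
    trG = float(np.trace(G))

    rows = {}
    for name in predictors.columns:
        # fresh generator per predictor: marginal results depend only on the
        # predictor's values and the seed, not on column order
        rng = np.random.default_rng(seed)
        x = predictors[name].to_numpy(dtype=float)
        xc = x - x.mean()
        ssx = xc @ xc
        if ssx <= 0:
            raise ValueError(f"constant predictor {name!r}")

        def explained(xc_):
            gx = G @ xc_
            return float(xc_ @ gx) / (xc_ @ xc_)

        ss_expl = explained(xc)
        ss_res = trG - ss_expl
        f_obs = ss_expl / (ss_res / (n - 2))
        ge = 0
        for _ in range(int(n_perm)):
            xp = xc[rng.permutation(n)]
            ss_p = explained(xp)
            f_p = ss_p / ((trG - ss_p) / (n - 2))
            if f_p >= f_obs - 1e-12:
                ge += 1
        rows[name] = {
            "pseudo_F": f_obs,
            "prop_explained": ss_expl / trG,
            "p_value": (1 + ge) / (1 + n_perm),
            "permutations": int(n_perm),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def pearson_axis_correlation(
    dm, predictors: pd.DataFrame, n_axes: int = 2
) -> pd.DataFrame:
    """Plain Pearson correlation of predictors with leading PCoA axes.

    A simpler companion to :func:`distlm_marginal` for descriptive use.
    """
    from .community import pcoa  # local import to avoid a cycle

    ord_res = pcoa(dm if isinstance(dm, DistanceMatrix) else DistanceMatrix(np.asarray(dm)))
    coords = ord_res.samples.iloc[:, :n_axes]
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    rows = {}
    for name in predictors.columns:
        x = predictors[name].to_numpy(dtype=float)
        for k in range(coords.shape[1]):
            r, p = sps.pearsonr(x, coords.iloc[:, k].to_numpy())
            rows[(name, f"PCo{k + 1}")] = {"r": r, "p_value": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["predictor", "axis"])
    return out


# -- Mann-Whitney ---------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks and tie correction.

    Exact p for small samples without ties, normal approximation otherwise
    (scipy's ``method="auto"``).  Returns ``(U, p)`` where U is the statistic
    of the first sample.  If every value in both samples is identical the
    test carries no information: U = n1*n2/2 and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
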