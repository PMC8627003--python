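"""Community-level processing of ASV tables.

Covers the deterministic/compositional side of the analysis: depth filtering
and rarefaction, alpha diversity (observed richness and Shannon index),
Bray-Curtis dissimilarity, principal coordinate analysis, prevalence-based
core-microbiome membership with Venn-style set arithmetic, and genus-level
relative-abundance summaries.  Hypothesis tests live in
:mod:`rearlegacy.stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .asv import AsvTable

__all__ = [
    "filter_and_rarefy",
    "rarefy",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "CoreSet",
    "core_membership",
    "genus_relative_abundance",
]

log = logging.getLogger(__name__)


# -- rarefaction ----------------------------------------------------------

def rarefy(table: AsvTable, target_depth: int, seed: Optional[int] = None) -> AsvTable:
    """Subsample every sample to exactly ``target_depth`` reads without replacement.

    One multivariate-hypergeometric draw per sample; reproducible under
    ``seed``.  Samples whose depth is below the target are rejected — run
    :func:`filter_and_rarefy` to drop them first.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    depths = table.depths()
    low = depths[depths < target_depth]
    if len(low):
        raise ValueError(
            f"samples below target depth {target_depth}: {list(low.index)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for i, row in enumerate(table.counts.to_numpy()):
        if row.sum() == target_depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target_depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return AsvTable(counts, table.metadata)


def filter_and_rarefy(
    table: AsvTable,
    min_depth: int,
    target_depth: int,
    seed: Optional[int] = None,
) -> AsvTable:
    """Drop samples below ``min_depth`` (logged), then rarefy to ``target_depth``.

    ``target_depth`` must not exceed the depth of any retained sample.
    """
    depths = table.depths()
    keep = depths.index[depths >= min_depth]
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        log.info("dropped %d low-depth samples: %s", len(dropped), dropped)
    if len(keep) == 0:
        raise ValueError("no samples left after depth filtering")
    filtered = table.select_samples(list(keep))
    if target_depth > filtered.depths().min():
        raise ValueError(
            "target_depth exceeds the depth of a retained sample; "
            "raise min_depth or lower target_depth"
        )
    return rarefy(filtered, target_depth, seed=seed)


# -- alpha diversity ------------------------------------------------------

def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Observed richness and Shannon index (natural log) per sample.

    Richness counts ASVs with count > 0; Shannon is -sum p_i ln p_i over the
    positive proportions.  Intended for a rarefied table (equal depths) so
    that richness is comparable across samples.
    """
    depths = table.depths()
    if (depths == 0).any():
        empty = list(depths.index[depths == 0])
        raise ValueError(f"empty samples: {empty}")
    counts = table.counts.to_numpy(dtype=float)
    richness = (counts > 0).sum(axis=1)
    shannon = np.array([entropy(row[row > 0]) for row in counts])
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=table.counts.index
    )


# -- beta diversity -------------------------------------------------------

def bray_curtis(table: AsvTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: d(x,y) = 1 - 2 sum min(x,y) / (sum x + sum y)."""
    depths = table.depths()
    if (depths == 0).any():
        empty = list(depths.index[depths == 0])
        raise ValueError(f"all-zero samples: {empty}")
    mat = squareform(pdist(table.counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(mat, ids=[str(s) for s in table.sample_ids])


def pcoa(dm: DistanceMatrix) -> OrdinationResults:
    """Classical scaling (principal coordinates) of a distance matrix.

    Eigendecomposition of the double-centred squared-distance matrix; axes
    ordered by non-increasing eigenvalue.  Negative eigenvalues (non-Euclidean
    input) are reported as-is, with no Lingoes/Cailliez correction; sample
    coordinates are returned for the positive axes.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(np.asarray(dm))
    if dm.shape[0] < 3:
        raise ValueError("PCoA needs at least 3 samples")
    import warnings

    with warnings.catch_warnings():
        # skbio warns when asked for all axes; all axes is what we want
        warnings.filterwarnings("ignore", message=".*all dimensions will be computed.*")
        return _skbio_pcoa(dm, method="eigh", number_of_dimensions=dm.shape[0])


# -- core microbiome ------------------------------------------------------

@dataclass
class CoreSet:
    """Prevalence-based core membership per group, with Venn-style arithmetic.

    An ASV is core in a group iff it is present (count > 0) in *strictly more*
    than ``threshold`` of that group's samples.
    """

    cores: dict
    threshold: float

    @property
    def groups(self) -> list:
        return list(self.cores)

    def core(self, group) -> frozenset:
        return self.cores[group]

    def shared(self) -> frozenset:
        """Intersection of all groups' cores."""
        sets = list(self.cores.values())
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
        return frozenset(out)

    def unique(self, group) -> frozenset:
        """Core ASVs of ``group`` that are core in no other group."""
        others = set()
        for g, s in self.cores.items():
            if g != group:
                others |= s
        return frozenset(self.cores[group] - others)

    def venn_counts(self) -> dict:
        """Counts per Venn region, keyed by the frozenset of member groups."""
        groups = self.groups
        universe = set()
        for s in self.cores.values():
            universe |= s
        regions: dict = {}
        for asv in universe:
            member = frozenset(g for g in groups if asv in self.cores[g])
            regions[member] = regions.get(member, 0) + 1
        return regions

    def summary(self) -> pd.DataFrame:
        rows = {
            g: {"core_size": len(s), "unique": len(self.unique(g))}
            for g, s in self.cores.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df["shared_all"] = len(self.shared())
        return df


def core_membership(
    table: AsvTable,
    grouping: pd.Series | str,
    prevalence_threshold: float = 1 / 3,
) -> CoreSet:
    """Per-group core-ASV sets at a strict prevalence threshold.

    With the study's default of just over 1/3 and five fish per tank, an ASV
    must occur in at least 2 of 5 samples of a treatment to be core there.
    """
    if not 0.0 < prevalence_threshold < 1.0:
        raise ValueError("prevalence threshold must be in (0, 1)")
    if isinstance(grouping, str):
        grouping = table.grouping(grouping)
    grouping = grouping.loc[table.counts.index]
    cores = {}
    for level in pd.unique(grouping):
        idx = grouping.index[grouping == level]
        if len(idx) == 0:
            raise ValueError(f"empty group {level!r}")
        sub = table.counts.loc[idx]
        prevalence = (sub > 0).mean(axis=0)
        cores[level] = frozenset(prevalence.index[prevalence > prevalence_threshold])
    return CoreSet(cores=cores, threshold=prevalence_threshold)


# -- taxonomy summaries ---------------------------------------------------

def genus_relative_abundance(
    table: AsvTable,
    taxonomy: pd.DataFrame,
    grouping: pd.Series | str,
    top_k: int = 10,
    tracked_asvs: Optional[Sequence] = None,
):
    """Per-group mean relative abundance of the dominant genera.

    ASVs lacking a genus assignment are bucketed as ``unclassified_genus``.
    The ``top_k`` genera by overall mean abundance are reported; the rest are
    pooled into ``Other`` (omitted when every genus fits).  If
    ``tracked_asvs`` is given, their cumulative relative abundance per group
    is returned alongside.

    Returns ``(genus_table, tracked)``: a genera x groups DataFrame of mean
    proportions, and a per-group Series (or None).
    """
    missing = set(table.asv_ids) - set(taxonomy.index)
    if missing:
        raise ValueError(f"taxonomy missing for ASVs: {sorted(missing)[:5]} ...")
    if isinstance(grouping, str):
        grouping = table.grouping(grouping)
    grouping = grouping.loc[table.counts.index]

    genus = taxonomy.loc[table.asv_ids, "genus"].replace("", np.nan)
    genus = genus.fillna("unclassified_genus")
    rel = table.relative_abundance()
    by_genus = rel.T.groupby(genus.values).sum().T  # samples x genera
    group_means = by_genus.groupby(grouping.values).mean().T  # genera x groups

    order = group_means.mean(axis=1).sort_values(ascending=False)
    top = list(order.index[:top_k])
    out = group_means.loc[top]
    rest = group_means.drop(index=top)
    if len(rest):
        out.loc["Other"] = rest.sum(axis=0)

    tracked = None
    if tracked_asvs is not None:
        tracked_asvs = [a for a in tracked_asvs]
        unknown = set(tracked_asvs) - set(table.asv_ids)
        if unknown:
            raise ValueError(f"tracked ASVs not in table: {sorted(unknown)}")
        cumulative = rel[tracked_asvs].sum(axis=1)
        tracked = cumulative.groupby(grouping.values).mean()
    return out, tracked
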