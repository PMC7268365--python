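"""Methylation variability and sample-correlation structure.

Within-group variability is the sample standard deviation of a tile's
methylation fractions across a group's cells; it is summarised over random
tile subsets, stratified by CpG-island methylation class, and related to
distance from transcription start sites. Sample similarity is the pairwise-
complete Pearson correlation over tile methylation values, clustered with
average linkage on ``1 - r``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .tiles import TileMethylMatrix

__all__ = [
    "tile_sd",
    "sample_random_tiles",
    "cgi_strata_sd",
    "strata_medians",
    "top_variable_tss_distance",
    "TSSDistanceResult",
    "CorrelationResult",
    "correlation_clustering",
    "intra_inter_correlation",
]


def tile_sd(matrix: TileMethylMatrix, group: str) -> pd.Series:
    """Per-tile sample SD across one group's non-missing values (ddof=1).

    Tiles with fewer than two observed values are missing.
    """
    members = matrix.group_samples(group)
    sd = matrix.meth[members].std(axis=1, ddof=1)
    n = matrix.meth[members].notna().sum(axis=1)
    return sd.where(n >= 2)


def sample_random_tiles(matrix: TileMethylMatrix, n: int = 10_000, seed: int = 0) -> pd.Index:
    """Uniform seeded sample of tile ids without replacement.

    When ``n`` exceeds the number of tiles, all tiles are returned with a
    warning rather than an error.
    """
    ids = matrix.tiles.index
    if n >= len(ids):
        if n > len(ids):
            warnings.warn(f"requested {n} tiles but only {len(ids)} exist; taking all")
        return ids
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(ids), size=n, replace=False)
    return ids[np.sort(pick)]


def cgi_strata_sd(
    matrix: TileMethylMatrix,
    cgis: pd.DataFrame,
    group: str,
    low: float = 0.2,
    high: float = 0.8,
) -> pd.DataFrame:
    """Within-group SD of CGI-overlapping tiles, stratified by mean level.

    Tiles overlapping any CpG-island interval are assigned to the ``low``
    (group mean < 0.2), ``medium`` or ``high`` (> 0.8) stratum from the
    group's mean methylation. Binomial sampling makes variability largest
    near 50% methylation, so the medium stratum is expected to dominate.
    """
    if cgis is None or len(cgis) == 0:
        raise ValidationError("empty CGI set")
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in cgis.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    overlaps = np.array(
        [
            row.chrom in trees and bool(trees[row.chrom].overlap(row.start, row.end))
            for row in matrix.tiles.itertuples()
        ]
    )
    ids = matrix.tiles.index[overlaps]
    members = matrix.group_samples(group)
    mean = matrix.meth.loc[ids, members].mean(axis=1)
    sd = tile_sd(matrix, group).loc[ids]
    stratum = pd.Series(
        np.where(mean < low, "low", np.where(mean > high, "high", "medium")), index=ids
    ).where(mean.notna())
    out = pd.DataFrame({"group_mean": mean, "sd": sd, "stratum": stratum})
    return out.dropna(subset=["stratum"])


def strata_medians(table: pd.DataFrame) -> pd.Series:
    """Median SD per stratum of a :func:`cgi_strata_sd` table."""
    return table.dropna(subset=["sd"]).groupby("stratum")["sd"].median()


@dataclass
class TSSDistanceResult:
    """Nearest-TSS distances of the most variable tiles."""

    distances: pd.Series  # tile id -> bp
    fraction_beyond: float
    cutoff: int

    def cumulative(self) -> pd.DataFrame:
        """Empirical CDF of the distances (non-decreasing, ends at 1)."""
        d = np.sort(self.distances.to_numpy())
        return pd.DataFrame({"distance": d, "cdf": np.arange(1, d.size + 1) / d.size})


def top_variable_tss_distance(
    matrix: TileMethylMatrix,
    genes: pd.DataFrame,
    group: str,
    n: int = 10_000,
    cutoff: int = 10_000,
) -> TSSDistanceResult:
    """Distances from the ``n`` most variable tiles to the nearest TSS.

    Variability is the within-group SD; distance is measured from the tile
    midpoint, strand-ignored; ``fraction_beyond`` is the share of selected
    tiles farther than ``cutoff`` bp from every TSS.
    """
    from .dmr import annotate_tiles

    sd = tile_sd(matrix, group).dropna().sort_values(ascending=False)
    top = sd.index[: min(n, len(sd))]
    annot = annotate_tiles(matrix.tiles.loc[top], genes, promoters=None)
    distances = annot["tss_distance"]
    frac = float((distances > cutoff).mean()) if len(distances) else float("nan")
    return TSSDistanceResult(distances=distances, fraction_beyond=frac, cutoff=cutoff)


@dataclass
class CorrelationResult:
    """Pairwise-complete Pearson correlations with their clustering."""

    corr: pd.DataFrame
    linkage: np.ndarray | None
    clustered_samples: list[str]
    excluded_samples: list[str]
    groups: pd.Series

    def dendrogram_order(self) -> list[str]:
        from scipy.cluster.hierarchy import leaves_list

        if self.linkage is None:
            return self.clustered_samples
        return [self.clustered_samples[i] for i in leaves_list(self.linkage)]


def correlation_clustering(matrix: TileMethylMatrix, min_periods: int = 3) -> CorrelationResult:
    """Sample-by-sample Pearson correlation and average-linkage clustering.

    Correlations use pairwise-complete observations over tiles and need at
    least ``min_periods`` complete pairs; samples whose correlation to any
    other sample is undefined are excluded from the clustering with a
    warning. Linkage is average on distance ``1 - r``.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("need >= 2 samples")
    corr = matrix.meth.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    included = list(corr.columns)
    while True:
        off = corr.loc[included, included]
        nan_counts = off.isna().sum()
        if nan_counts.max() == 0 or len(included) <= 2:
            break
        worst = nan_counts.idxmax()
        included.remove(worst)
    excluded = [s for s in corr.columns if s not in included]
    if excluded:
        warnings.warn(f"excluding samples with undefined correlations: {excluded}")
    link = None
    if len(included) >= 2 and not corr.loc[included, included].isna().any().any():
        dist = 1.0 - corr.loc[included, included].to_numpy()
        dist = (dist + dist.T) / 2.0
        np.fill_diagonal(dist, 0.0)
        link = linkage(squareform(np.clip(dist, 0.0, None), checks=False), method="average")
    return CorrelationResult(
        corr=corr,
        linkage=link,
        clustered_samples=included,
        excluded_samples=excluded,
        groups=matrix.groups,
    )


def intra_inter_correlation(result: CorrelationResult) -> pd.DataFrame:
    """Off-diagonal correlations labelled intra- or inter-group.

    One row per unordered sample pair with a defined correlation; ``relation``
    is ``intra`` when both samples share a group label.
    """
    samples = list(result.corr.columns)
    rows = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            r = result.corr.loc[a, b]
            if pd.isna(r):
                continue
            ga, gb = result.groups.get(a), result.groups.get(b)
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "group_a": ga,
                    "group_b": gb,
                    "r": float(r),
                    "relation": "intra" if ga == gb else "inter",
                }
            )
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "group_a", "group_b", "r", "relation"])
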