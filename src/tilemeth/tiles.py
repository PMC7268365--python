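"""CpG-count tiling and methylation quantification over tiles and regions.

Because CpGs are unevenly distributed along mammalian genomes, methylation is
quantified in non-overlapping windows containing a fixed number of reference
CpGs (100 by default) rather than fixed base-pair bins. A tile's methylation
level in a cell is the unweighted mean of the per-site methylation fractions
of the CpGs covered in that cell — at near-1x single-cell depth this
coincides with the pooled-read ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ValidationError
from .genome import GenomeCpGMap
from .io import SampleMethylome, validate_regions

__all__ = [
    "make_tiles",
    "TileMethylMatrix",
    "tile_methylation",
    "informative_tiles",
    "RegionMethylTable",
    "region_methylation",
    "promoter_set",
    "metagene_profile",
]


def make_tiles(cpg_map: GenomeCpGMap, window: int = 100) -> pd.DataFrame:
    """Partition every chromosome's CpG list into runs of ``window`` CpGs.

    Returns a DataFrame indexed by tile id (``"<chrom>:<ordinal>"``) with
    columns ``chrom, ordinal, start, end, cpg_count, partial``. Tile extent is
    0-based half-open from the first CpG's C to one past the last CpG's G, so
    adjacent tiles never overlap. A trailing run shorter than ``window``
    becomes one ``partial`` tile. The nominal window is stored in
    ``df.attrs["window"]``.
    """
    if window < 1:
        raise InvalidParameterError(f"window must be >= 1, got {window}")
    rows = []
    for chrom, pos in cpg_map.positions.items():
        n = pos.size
        for ordinal, lo in enumerate(range(0, n, window)):
            hi = min(lo + window, n)
            rows.append(
                (
                    f"{chrom}:{ordinal}",
                    chrom,
                    ordinal,
                    int(pos[lo]) - 1,
                    int(pos[hi - 1]) + 1,
                    hi - lo,
                    hi - lo < window,
                )
            )
    tiles = pd.DataFrame(
        rows, columns=["tile_id", "chrom", "ordinal", "start", "end", "cpg_count", "partial"]
    ).set_index("tile_id")
    tiles.attrs["window"] = window
    return tiles


@dataclass
class TileMethylMatrix:
    """Tiles x samples methylation fractions with coverage side-matrices.

    Attributes
    ----------
    tiles : DataFrame from :func:`make_tiles`.
    meth : tiles x samples methylation fraction; NaN where no CpG covered.
    cov : covered-CpG count per (tile, sample).
    meth_reads, total_reads : pooled read counts per (tile, sample), used by
        the count-based differential tests.
    groups : sample id -> group label.
    """

    tiles: pd.DataFrame
    meth: pd.DataFrame
    cov: pd.DataFrame
    meth_reads: pd.DataFrame
    total_reads: pd.DataFrame
    groups: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    def group_samples(self, group: str) -> list[str]:
        members = list(self.groups.index[self.groups == group])
        if not members:
            raise ValidationError(f"unknown group label {group!r}")
        return members

    def subset(self, tile_ids) -> "TileMethylMatrix":
        return TileMethylMatrix(
            self.tiles.loc[tile_ids],
            self.meth.loc[tile_ids],
            self.cov.loc[tile_ids],
            self.meth_reads.loc[tile_ids],
            self.total_reads.loc[tile_ids],
            self.groups,
        )

    def relabel(self, groups: pd.Series) -> "TileMethylMatrix":
        """Same data under different sample-to-group labels (permutations)."""
        return TileMethylMatrix(
            self.tiles, self.meth, self.cov, self.meth_reads, self.total_reads, groups
        )


def tile_methylation(
    tiles: pd.DataFrame, samples: list[SampleMethylome], cpg_map: GenomeCpGMap
) -> TileMethylMatrix:
    """Aggregate per-site CG fractions into the tiles x samples matrix.

    Only calls at reference CpG positions of ``cpg_map`` contribute; a
    (tile, sample) entry is the mean per-site fraction over the tile's covered
    CpGs and is missing when none are covered.
    """
    window = tiles.attrs.get("window") or int(tiles["cpg_count"].max())
    chroms = list(cpg_map.positions)
    offsets = {}
    off = 0
    for chrom in chroms:
        offsets[chrom] = off
        off += int(np.ceil(cpg_map.positions[chrom].size / window))
    n_tiles = len(tiles)
    if off != n_tiles:
        raise ValidationError("tiles do not match the CpG map they were built from")

    n_samples = len(samples)
    frac_sum = np.zeros((n_tiles, n_samples))
    count = np.zeros((n_tiles, n_samples), dtype=np.int64)
    mreads = np.zeros((n_tiles, n_samples), dtype=np.int64)
    treads = np.zeros((n_tiles, n_samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        cg = sample.calls[sample.calls["context"] == "CG"]
        for chrom, sub in cg.groupby("chrom", sort=False):
            if chrom not in offsets:
                continue
            idx = cpg_map.site_index(chrom, sub["pos"].to_numpy(np.int64))
            keep = idx >= 0
            if not keep.any():
                continue
            rows = offsets[chrom] + idx[keep] // window
            m = sub["meth"].to_numpy(np.int64)[keep]
            u = sub["unmeth"].to_numpy(np.int64)[keep]
            t = m + u
            frac_sum[:, j] += np.bincount(rows, weights=m / t, minlength=n_tiles)
            count[:, j] += np.bincount(rows, minlength=n_tiles)
            mreads[:, j] += np.bincount(rows, weights=m, minlength=n_tiles).astype(np.int64)
            treads[:, j] += np.bincount(rows, weights=t, minlength=n_tiles).astype(np.int64)

    with np.errstate(invalid="ignore"):
        meth = np.where(count > 0, frac_sum / np.maximum(count, 1), np.nan)
    ids = [s.sample_id for s in samples]
    return TileMethylMatrix(
        tiles=tiles,
        meth=pd.DataFrame(meth, index=tiles.index, columns=ids),
        cov=pd.DataFrame(count, index=tiles.index, columns=ids),
        meth_reads=pd.DataFrame(mreads, index=tiles.index, columns=ids),
        total_reads=pd.DataFrame(treads, index=tiles.index, columns=ids),
        groups=pd.Series({s.sample_id: s.group for s in samples}),
    )


def informative_tiles(
    matrix: TileMethylMatrix,
    group_a: str,
    group_b: str,
    min_cpgs: int = 5,
    min_samples: int = 2,
) -> pd.Index:
    """Tiles usable in one pairwise comparison.

    Keeps tiles covering at least ``min_cpgs`` CpGs in at least
    ``min_samples`` samples in *each* group separately; partial trailing tiles
    are excluded so every tested tile carries the same nominal CpG count.
    """
    ok = ~matrix.tiles["partial"]
    for group in (group_a, group_b):
        members = matrix.group_samples(group)
        enough = (matrix.cov[members] >= min_cpgs).sum(axis=1) >= min_samples
        ok &= enough
    return matrix.tiles.index[ok]


@dataclass
class RegionMethylTable:
    """Per (region, sample) mean methylation with covered-CpG counts."""

    regions: pd.DataFrame
    fraction: pd.DataFrame  # regions x samples, NaN where uncovered
    cov: pd.DataFrame

    def class_summary(self) -> pd.DataFrame:
        """Mean methylation per region class per sample (covered regions only)."""
        out = self.fraction.copy()
        out["region_class"] = self.regions["region_class"].to_numpy()
        return out.groupby("region_class").mean()


def region_methylation(
    samples: list[SampleMethylome], regions: pd.DataFrame
) -> RegionMethylTable:
    """Mean per-site CG fraction of covered CpGs inside each interval.

    A region with no covered CpG in a sample is missing (the "uncovered"
    state rendered grey in imprint-control-region heatmaps). Overlapping
    regions are quantified independently.
    """
    regions = validate_regions(regions)
    n_regions, n_samples = len(regions), len(samples)
    frac = np.full((n_regions, n_samples), np.nan)
    cov = np.zeros((n_regions, n_samples), dtype=np.int64)
    by_chrom = {chrom: sub for chrom, sub in regions.groupby("chrom", sort=False)}
    for j, sample in enumerate(samples):
        sites = sample.fractions("CG")
        for chrom, sub in sites.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            pos = sub["pos"].to_numpy(np.int64)
            f = sub["fraction"].to_numpy()
            csum = np.concatenate([[0.0], np.cumsum(f)])
            reg = by_chrom[chrom]
            # position p (1-based) lies in [start, end) iff p in [start+1, end]
            lo = np.searchsorted(pos, reg["start"].to_numpy() + 1)
            hi = np.searchsorted(pos, reg["end"].to_numpy(), side="right")
            n = hi - lo
            has = n > 0
            rows = reg.index.to_numpy()[has]
            cov[rows, j] = n[has]
            frac[rows, j] = (csum[hi[has]] - csum[lo[has]]) / n[has]
    ids = [s.sample_id for s in samples]
    return RegionMethylTable(
        regions=regions,
        fraction=pd.DataFrame(frac, index=regions.index, columns=ids),
        cov=pd.DataFrame(cov, index=regions.index, columns=ids),
    )


def promoter_set(
    genes: pd.DataFrame,
    cpg_map: GenomeCpGMap,
    upstream: int = 1500,
    downstream: int = 500,
    min_cpgs: int = 8,
) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS, CpG-filtered.

    Windows span ``upstream`` bp before to ``downstream`` bp after the TSS
    (reflected for minus-strand genes) and only promoters containing strictly
    more than ``min_cpgs`` reference CpGs are retained.
    """
    genes = validate_regions(genes)
    plus = genes["strand"] != "-"
    start = np.where(plus, genes["start"] - upstream, genes["end"] - downstream)
    end = np.where(plus, genes["start"] + downstream, genes["end"] + upstream)
    start = np.maximum(start, 0)
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": start,
            "end": end,
            "strand": genes["strand"],
            "name": genes["name"],
            "region_class": "promoter",
        }
    )
    counts = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in out.groupby("chrom", sort=False):
        if chrom not in cpg_map.positions:
            continue
        pos = cpg_map.positions[chrom]
        lo = np.searchsorted(pos, sub["start"].to_numpy() + 1)
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        counts[sub.index.to_numpy()] = hi - lo
    return validate_regions(out[counts > min_cpgs])


def metagene_profile(
    samples: list[SampleMethylome],
    genes: pd.DataFrame,
    flank: int = 15000,
    n_body_bins: int = 60,
    n_flank_bins: int = 30,
) -> pd.DataFrame:
    """Mean methylation along a scaled gene-body axis with fixed-bp flanks.

    Each gene body is rescaled into ``n_body_bins`` bins; ``flank`` bp
    upstream of the TSS and downstream of the TES are split into
    ``n_flank_bins`` fixed-width bins each (minus-strand genes are reflected).
    Returns a DataFrame with one row per bin (``zone`` in
    {upstream, body, downstream}) and the mean per-site fraction pooled over
    genes and samples.
    """
    genes = validate_regions(genes)
    if genes.empty:
        raise ValidationError("empty gene set")
    n_bins = 2 * n_flank_bins + n_body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    gene_rows = list(genes.itertuples())
    for sample in samples:
        sites = sample.fractions("CG")
        for chrom, sub in sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy(np.int64) - 1  # 0-based
            f = sub["fraction"].to_numpy()
            for g in gene_rows:
                if g.chrom != chrom:
                    continue
                lo = np.searchsorted(pos, g.start - flank)
                hi = np.searchsorted(pos, g.end + flank)
                if hi == lo:
                    continue
                p = pos[lo:hi]
                v = f[lo:hi]
                rel = np.empty(p.size)
                before = p < g.start
                after = p >= g.end
                body = ~(before | after)
                rel[before] = -1 + (p[before] - (g.start - flank)) / flank
                rel[body] = (p[body] - g.start) / (g.end - g.start)
                rel[after] = 1 + (p[after] - g.end) / flank
                if g.strand == "-":
                    rel = 1 - rel  # reflect so bin 0 is still upstream of TSS
                binno = np.empty(p.size, dtype=np.int64)
                up = rel < 0
                dn = rel >= 1
                mid = ~(up | dn)
                binno[up] = np.clip(((rel[up] + 1) * n_flank_bins).astype(int), 0, n_flank_bins - 1)
                binno[mid] = n_flank_bins + np.clip(
                    (rel[mid] * n_body_bins).astype(int), 0, n_body_bins - 1
                )
                binno[dn] = n_flank_bins + n_body_bins + np.clip(
                    ((rel[dn] - 1) * n_flank_bins).astype(int), 0, n_flank_bins - 1
                )
                np.add.at(sums, binno, v)
                np.add.at(counts, binno, 1)
    zone = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin": np.arange(n_bins), "zone": zone, "mean": mean, "n": counts})
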