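"""Synthetic single-oocyte methylome generator.

Emulates the statistical structure of a sparse single-cell post-bisulfite
(pBAT) methylome experiment: a CpG map with uneven spacing, a bimodal
oocyte-like methylation landscape (hypermethylated gene-body domains over a
hypomethylated intergenic background, with occasional intermediately
methylated blocks), Bernoulli per-CpG capture at near-haploid depth, small
bisulfite conversion error rates, and group-specific planted differentially
methylated tiles whose ground truth is returned for recovery testing.

The default experimental design mirrors an eight-group superovulation study:
a natural-ovulation control, an hCG-only control, and three doses (5/50/200
IU) each of FSH and hMG, with 6 cells per group (7 in the highest hMG dose).
Dose groups of the same hormone share one planted-DMR profile so that true
effects recur across the dose-versus-control comparisons, as the consensus
DMR definition requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .genome import GenomeCpGMap
from .io import SampleMethylome, validate_regions
from .tiles import make_tiles

__all__ = [
    "GroupSpec",
    "SimDesign",
    "SimTruth",
    "generate_genome_cpg_map",
    "generate_gene_annotation",
    "baseline_levels",
    "simulate_methylomes",
    "simulate_lambda_calls",
    "default_design",
]

TILE_WINDOW = 100


@dataclass(frozen=True)
class GroupSpec:
    """One treatment group: name, dose label, cell count, planted-DMR profile.

    Groups sharing a ``dmr_profile`` string receive the same planted tiles
    (e.g. all doses of one hormone); ``None`` marks an unperturbed control.
    """

    name: str
    dose: str = ""
    n_cells: int = 6
    dmr_profile: str | None = None


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the synthetic experiment.

    Methylation levels are probabilities in [0, 1]; ``planted_delta`` is in
    percentage points (0, 100]. ``capture_prob`` is the per-CpG Bernoulli
    probability that a cell observes a site; captured sites get read depth 1
    plus an optional geometric extra depth (``extra_depth_p``; ``None`` keeps
    strict depth 1). ``conversion_failure`` flips truly unmethylated calls to
    methylated-looking; ``over_conversion`` flips methylated calls the other
    way.
    """

    groups: tuple[GroupSpec, ...]
    seed: int
    hyper_level: float = 0.85
    hypo_level: float = 0.10
    intermediate_level: float | None = 0.50
    intermediate_every: int = 5  # every k-th hypomethylated block is intermediate
    domain_block_cpgs: int = 200
    n_planted_per_profile: int = 0
    planted_delta: float = 40.0
    planted_hyper_fraction: float = 0.5
    capture_prob: float = 0.22
    extra_depth_p: float | None = None
    conversion_failure: float = 0.005
    over_conversion: float = 0.002
    noncg_sites_per_cell: int = 0
    noncg_level: float = 0.01

    def __post_init__(self):
        for name in (
            "hyper_level",
            "hypo_level",
            "capture_prob",
            "conversion_failure",
            "over_conversion",
            "planted_hyper_fraction",
            "noncg_level",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.intermediate_level is not None and not 0.0 <= self.intermediate_level <= 1.0:
            raise InvalidParameterError("intermediate_level outside [0, 1]")
        if not 0.0 < self.planted_delta <= 100.0:
            raise InvalidParameterError("planted_delta must be in (0, 100]")
        if any(g.n_cells < 1 for g in self.groups):
            raise InvalidParameterError("every group needs n_cells >= 1")
        if self.domain_block_cpgs < TILE_WINDOW:
            raise InvalidParameterError(
                f"domain_block_cpgs must be >= {TILE_WINDOW} so tiles nest in domains"
            )

    @property
    def profiles(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g.dmr_profile is not None and g.dmr_profile not in seen:
                seen.append(g.dmr_profile)
        return seen


@dataclass
class SimTruth:
    """Ground truth of one simulation run.

    ``planted`` has one row per planted tile: tile id, profile, direction
    (hyper/hypo relative to controls), delta (percentage points) and the
    unperturbed baseline level of the tile's domain.
    """

    planted: pd.DataFrame
    baseline: dict[str, float]
    seed: int

    def tiles_for(self, profile: str) -> pd.Index:
        return pd.Index(self.planted.loc[self.planted["profile"] == profile, "tile_id"])


def generate_genome_cpg_map(
    n_chroms: int, cpgs_per_chrom: int, mean_gap_bp: float, seed: int
) -> GenomeCpGMap:
    """Random CpG map with geometric inter-CpG gaps of the given mean.

    Gaps are ``1 + Geometric(1 / (mean_gap_bp - 1))`` so they are integers
    >= 2 (CpG dyads cannot overlap) with expectation ``mean_gap_bp``.
    """
    if n_chroms < 1 or cpgs_per_chrom < 1:
        raise InvalidParameterError("n_chroms and cpgs_per_chrom must be >= 1")
    if mean_gap_bp < 2:
        raise InvalidParameterError("mean_gap_bp must be >= 2")
    rng = np.random.default_rng(seed)
    positions = {}
    for c in range(n_chroms):
        gaps = 1 + rng.geometric(1.0 / (mean_gap_bp - 1.0), size=cpgs_per_chrom)
        positions[f"chr{c + 1}"] = np.cumsum(gaps)
    return GenomeCpGMap(positions)


def _block_levels(n_blocks: int, design: SimDesign) -> np.ndarray:
    """Methylation level of each domain block on one chromosome.

    Even blocks are hypermethylated (gene-body-like); odd blocks are
    hypomethylated (intergenic-like), except that every
    ``intermediate_every``-th odd block is set to the intermediate level so
    partially methylated domains exist. The layout is deterministic so the
    gene annotation can target hypermethylated blocks independently.
    """
    levels = np.where(np.arange(n_blocks) % 2 == 0, design.hyper_level, design.hypo_level)
    if design.intermediate_level is not None and design.intermediate_every:
        odd = np.flatnonzero(np.arange(n_blocks) % 2 == 1)
        mid = odd[(np.arange(odd.size) % design.intermediate_every) == design.intermediate_every // 2]
        levels[mid] = design.intermediate_level
    return levels


def baseline_levels(cpg_map: GenomeCpGMap, design: SimDesign) -> dict[str, np.ndarray]:
    """Per-CpG baseline methylation probability for each chromosome."""
    out = {}
    B = design.domain_block_cpgs
    for chrom, pos in cpg_map.positions.items():
        n_blocks = int(np.ceil(pos.size / B))
        levels = _block_levels(n_blocks, design)
        out[chrom] = levels[np.arange(pos.size) // B]
    return out


def generate_gene_annotation(
    cpg_map: GenomeCpGMap,
    n_genes: int,
    seed: int,
    domain_block_cpgs: int = 200,
    n_cgis: int | None = None,
    n_icrs: int = 3,
) -> pd.DataFrame:
    """Genes, CpG islands and ICR-like regions consistent with the domains.

    Genes occupy hypermethylated (even) domain blocks, reproducing the
    gene-body-high oocyte methylome; CGIs are the central portions of blocks
    of both kinds, classed ``CGI_met`` on hypermethylated and ``CGI_unmet``
    on hypomethylated blocks; a few hypermethylated blocks are additionally
    labelled ``ICR`` as maternal-imprint stand-ins.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    B = domain_block_cpgs
    blocks = []  # (chrom, block index, lo cpg idx, hi cpg idx)
    for chrom, pos in cpg_map.positions.items():
        for b in range(int(np.ceil(pos.size / B))):
            lo, hi = b * B, min((b + 1) * B, pos.size)
            if hi - lo >= B // 2:
                blocks.append((chrom, b, lo, hi))
    even = [blk for blk in blocks if blk[1] % 2 == 0]
    odd = [blk for blk in blocks if blk[1] % 2 == 1]
    if n_genes > len(even):
        raise InvalidParameterError(
            f"genome too small: {n_genes} genes requested, {len(even)} hypermethylated blocks"
        )

    def span(blk, inset=0):
        chrom, _, lo, hi = blk
        pos = cpg_map.positions[chrom]
        lo2, hi2 = lo + inset, hi - inset
        return chrom, int(pos[lo2]) - 1, int(pos[hi2 - 1]) + 1

    rows = []
    gene_blocks = [even[i] for i in rng.choice(len(even), size=n_genes, replace=False)]
    for i, blk in enumerate(gene_blocks):
        chrom, start, end = span(blk)
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, end, strand, f"gene_{i}", "gene"))
    if n_cgis is None:
        n_cgis = max(2, min(len(blocks) // 2, 2 * n_genes))
    cgi_pool = blocks
    pick = rng.choice(len(cgi_pool), size=min(n_cgis, len(cgi_pool)), replace=False)
    for i, k in enumerate(pick):
        blk = cgi_pool[k]
        chrom, start, end = span(blk, inset=(blk[3] - blk[2]) // 4)
        cls = "CGI_met" if blk[1] % 2 == 0 else "CGI_unmet"
        rows.append((chrom, start, end, ".", f"cgi_{i}", cls))
    icr_pool = [blk for blk in even if blk not in gene_blocks] or even
    pick = rng.choice(len(icr_pool), size=min(n_icrs, len(icr_pool)), replace=False)
    for i, k in enumerate(pick):
        chrom, start, end = span(icr_pool[k], inset=(icr_pool[k][3] - icr_pool[k][2]) // 3)
        rows.append((chrom, start, end, ".", f"icr_{i}", "ICR"))
    return validate_regions(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name", "region_class"])
    )


def _plant_dmrs(cpg_map: GenomeCpGMap, design: SimDesign, rng: np.random.Generator):
    """Choose planted tiles per profile and their direction, disjointly."""
    tiles = make_tiles(cpg_map, TILE_WINDOW)
    base = baseline_levels(cpg_map, design)
    full = tiles[~tiles["partial"]]
    level = np.array(
        [
            base[chrom][ordinal * TILE_WINDOW]
            for chrom, ordinal in zip(full["chrom"], full["ordinal"])
        ]
    )
    hypo_tiles = list(full.index[level == design.hypo_level])  # room to go up
    hyper_tiles = list(full.index[level == design.hyper_level])  # room to go down
    profiles = design.profiles
    n = design.n_planted_per_profile
    rows = []
    if n and profiles:
        n_hyper_dir = int(round(n * design.planted_hyper_fraction))
        need_up = n_hyper_dir * len(profiles)
        need_dn = (n - n_hyper_dir) * len(profiles)
        if need_up > len(hypo_tiles) or need_dn > len(hyper_tiles):
            raise InvalidParameterError(
                "planted-DMR count exceeds available tiles for the requested directions"
            )
        up_pick = rng.choice(len(hypo_tiles), size=need_up, replace=False)
        dn_pick = rng.choice(len(hyper_tiles), size=need_dn, replace=False)
        for k, profile in enumerate(profiles):
            for t in up_pick[k * n_hyper_dir : (k + 1) * n_hyper_dir]:
                rows.append((hypo_tiles[t], profile, "hyper", design.planted_delta, design.hypo_level))
            m = n - n_hyper_dir
            for t in dn_pick[k * m : (k + 1) * m]:
                rows.append((hyper_tiles[t], profile, "hypo", design.planted_delta, design.hyper_level))
    planted = pd.DataFrame(
        rows, columns=["tile_id", "profile", "direction", "delta", "baseline"]
    )
    truth = SimTruth(
        planted=planted,
        baseline={
            "hyper": design.hyper_level,
            "hypo": design.hypo_level,
            "intermediate": design.intermediate_level if design.intermediate_level is not None else float("nan"),
        },
        seed=design.seed,
    )
    return tiles, truth


def _profile_levels(
    cpg_map: GenomeCpGMap,
    design: SimDesign,
    tiles: pd.DataFrame,
    truth: SimTruth,
) -> dict[str | None, dict[str, np.ndarray]]:
    """Per-CpG methylation probabilities for controls and each profile."""
    base = baseline_levels(cpg_map, design)
    out: dict[str | None, dict[str, np.ndarray]] = {None: base}
    for profile in design.profiles:
        levels = {chrom: arr.copy() for chrom, arr in base.items()}
        sub = truth.planted[truth.planted["profile"] == profile]
        for row in sub.itertuples():
            chrom = tiles.loc[row.tile_id, "chrom"]
            ordinal = tiles.loc[row.tile_id, "ordinal"]
            lo = ordinal * TILE_WINDOW
            shift = row.delta / 100.0 if row.direction == "hyper" else -row.delta / 100.0
            seg = levels[chrom][lo : lo + TILE_WINDOW]
            levels[chrom][lo : lo + TILE_WINDOW] = np.clip(seg + shift, 0.0, 1.0)
        out[profile] = levels
    return out


def simulate_methylomes(
    cpg_map: GenomeCpGMap,
    regions: pd.DataFrame | None,
    design: SimDesign,
) -> tuple[list[SampleMethylome], SimTruth]:
    """Draw every cell's sparse methylation calls plus the planted truth.

    Per cell, each reference CpG is captured with ``capture_prob``; a
    captured site gets read depth >= 1 and its methylated count is binomial
    with success probability equal to the group's per-CpG level, perturbed by
    the two conversion error rates. Identical designs (including seed) yield
    identical output.
    """
    if regions is not None and not regions.empty:
        unknown = set(regions["chrom"]) - set(cpg_map.positions)
        if unknown:
            raise InvalidParameterError(f"regions on chromosomes absent from the map: {unknown}")
    rng = np.random.default_rng(design.seed)
    tiles, truth = _plant_dmrs(cpg_map, design, rng)
    levels_by_profile = _profile_levels(cpg_map, design, tiles, truth)
    fail, over = design.conversion_failure, design.over_conversion
    samples = []
    for group in design.groups:
        levels = levels_by_profile[group.dmr_profile]
        for k in range(group.n_cells):
            chroms, poss, meths, unmeths = [], [], [], []
            for chrom, pos in cpg_map.positions.items():
                covered = rng.random(pos.size) < design.capture_prob
                idx = np.flatnonzero(covered)
                if idx.size == 0:
                    continue
                depth = np.ones(idx.size, dtype=np.int64)
                if design.extra_depth_p is not None:
                    depth += rng.geometric(design.extra_depth_p, size=idx.size) - 1
                p = levels[chrom][idx]
                p_obs = p * (1.0 - over) + (1.0 - p) * fail
                m = rng.binomial(depth, p_obs)
                chroms.append(np.repeat(chrom, idx.size))
                poss.append(pos[idx])
                meths.append(m)
                unmeths.append(depth - m)
            calls = pd.DataFrame(
                {
                    "chrom": np.concatenate(chroms) if chroms else np.array([], dtype=str),
                    "pos": np.concatenate(poss) if poss else np.array([], dtype=np.int64),
                    "context": "CG",
                    "meth": np.concatenate(meths) if meths else np.array([], dtype=np.int64),
                    "unmeth": np.concatenate(unmeths) if unmeths else np.array([], dtype=np.int64),
                }
            )
            if design.noncg_sites_per_cell:
                calls = pd.concat(
                    [calls, _noncg_calls(cpg_map, design, rng)], ignore_index=True
                )
            samples.append(
                SampleMethylome(
                    sample_id=f"{group.name}_{k + 1}",
                    calls=calls,
                    group=group.name,
                    dose=group.dose,
                    mapping_efficiency=0.25,
                )
            )
    return samples, truth


def _noncg_calls(cpg_map: GenomeCpGMap, design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    """A small channel of CHG/CHH calls at non-CpG positions."""
    chrom = list(cpg_map.positions)[0]
    _, extent = cpg_map.chrom_extent(chrom)
    cpgs = set(cpg_map.positions[chrom].tolist())
    pos = rng.integers(1, extent, size=design.noncg_sites_per_cell)
    pos = np.unique(pos[[int(p) not in cpgs and int(p) - 1 not in cpgs for p in pos]])
    m = rng.random(pos.size) < design.noncg_level
    ctx = np.where(rng.random(pos.size) < 0.5, "CHG", "CHH")
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "context": ctx,
            "meth": m.astype(np.int64),
            "unmeth": (~m).astype(np.int64),
        }
    )


def simulate_lambda_calls(n_sites: int, conversion_rate: float, seed: int) -> pd.DataFrame:
    """Spike-in calls from the unmethylated lambda genome.

    Every lambda cytosine is truly unmethylated; bisulfite conversion
    succeeds independently with ``conversion_rate``, so the unmethylated-call
    fraction is Binomial(n_sites, rate) / n_sites.
    """
    if n_sites < 1:
        raise InvalidParameterError("n_sites must be >= 1")
    if not 0.0 <= conversion_rate <= 1.0:
        raise InvalidParameterError("conversion_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    converted = rng.random(n_sites) < conversion_rate
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": np.arange(1, 2 * n_sites, 2, dtype=np.int64),
            "context": "CG",
            "meth": (~converted).astype(np.int64),
            "unmeth": converted.astype(np.int64),
        }
    )


def default_design(
    seed: int,
    n_planted_per_profile: int = 50,
    planted_delta: float = 40.0,
    capture_prob: float = 0.22,
) -> SimDesign:
    """The eight-group superovulation design at paper-like group sizes."""
    groups = (
        GroupSpec("natural", "", 6, None),
        GroupSpec("hCG", "", 6, None),
        GroupSpec("FSH5", "5IU", 6, "FSH"),
        GroupSpec("FSH50", "50IU", 6, "FSH"),
        GroupSpec("FSH200", "200IU", 6, "FSH"),
        GroupSpec("hMG5", "5IU", 6, "hMG"),
        GroupSpec("hMG50", "50IU", 6, "hMG"),
        GroupSpec("hMG200", "200IU", 7, "hMG"),
    )
    return SimDesign(
        groups=groups,
        seed=seed,
        n_planted_per_profile=n_planted_per_profile,
        planted_delta=planted_delta,
        capture_prob=capture_prob,
    )
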