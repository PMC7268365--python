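"""Per-tile differential methylation with permutation false-positive control.

The model object :class:`PairwiseDMR` holds one treatment-versus-control
comparison over a :class:`~tilemeth.tiles.TileMethylMatrix`; ``fit()``
restricts to informative tiles (>= 5 covered CpGs in >= 2 samples per
group), tests each tile, corrects p-values by Benjamini–Hochberg and returns
a :class:`PairwiseDMRResults` whose table carries group means (percent),
their difference, p, q, significance and direction. A tile is a DMR when
q < 0.05 and the absolute mean difference exceeds 20 percentage points
(defaults; both configurable).

Two per-tile tests are offered:

* ``fisher_pooled`` (default) — an exact two-sided Fisher test on the 2x2
  table of methylated/unmethylated read counts pooled within each group,
  implemented here on the hypergeometric log-pmf with the conventional
  ``1 + 1e-7`` tie tolerance.
* ``logistic`` — a binomial GLM of per-sample counts on group membership
  with a likelihood-ratio p-value, mirroring multi-sample logistic testing
  in count-based DMR callers.

Because single-comparison calls carry a high false-positive rate at these
sample sizes, two controls are provided: label-shuffled reruns of the whole
procedure (:meth:`PairwiseDMR.randomization`) and a recurrence rule
(:func:`consensus_dmrs`) that keeps only tiles significant with a consistent
direction in at least two of the three dose-versus-control comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError
from .tiles import TileMethylMatrix, informative_tiles

__all__ = [
    "fisher_exact_two_sided",
    "test_tile",
    "PairwiseDMR",
    "PairwiseDMRResults",
    "pairwise_dmr",
    "RandomizationResult",
    "randomized_combinations",
    "ConsensusDMRSet",
    "consensus_dmrs",
    "annotate_tiles",
    "category_fractions",
]

_TIE_REL = 1 + 1e-7  # conventional relative tolerance for two-sided tail ties


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all outcomes no more likely than the
    observed one (point-probability method, as in R's ``fisher.test``).
    """
    n, K, N = a + b, a + c, a + b + c + d
    if N == 0 or n == 0 or n == N or K == 0 or K == N:
        return 1.0
    lo, hi = max(0, n - (N - K)), min(n, K)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(K + 1)
        - gammaln(x + 1)
        - gammaln(K - x + 1)
        + gammaln(N - K + 1)
        - gammaln(n - x + 1)
        - gammaln(N - K - n + x + 1)
        + gammaln(n + 1)
        + gammaln(N - n + 1)
        - gammaln(N + 1)
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_REL].sum()))


def _logistic_lrt(meth_a, tot_a, meth_b, tot_b) -> float:
    """Likelihood-ratio p from a binomial GLM of per-sample counts on group."""
    import statsmodels.api as sm

    meth = np.concatenate([meth_a, meth_b]).astype(float)
    tot = np.concatenate([tot_a, tot_b]).astype(float)
    grp = np.concatenate([np.ones(len(meth_a)), np.zeros(len(meth_b))])
    endog = np.column_stack([meth, tot - meth])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.GLM(endog, sm.add_constant(grp), family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, np.ones((len(tot), 1)), family=sm.families.Binomial()).fit()
        except Exception:
            return fisher_exact_two_sided(
                int(meth_a.sum()), int(tot_a.sum() - meth_a.sum()),
                int(meth_b.sum()), int(tot_b.sum() - meth_b.sum()),
            )
    stat = 2.0 * (full.llf - null.llf)
    if not np.isfinite(stat):
        return 1.0
    from scipy.stats import chi2

    return float(chi2.sf(max(stat, 0.0), df=1))


def test_tile(counts_a, counts_b, method: str = "fisher_pooled") -> tuple[float, float]:
    """(p-value, difference) for one tile from per-sample (meth, total) pairs.

    The difference is ``100 x (mean group-A sample fraction - mean group-B
    sample fraction)``, treating each cell as the biological replicate.
    """
    counts_a = [(int(m), int(t)) for m, t in counts_a if t > 0]
    counts_b = [(int(m), int(t)) for m, t in counts_b if t > 0]
    if len(counts_a) < 2 or len(counts_b) < 2:
        raise InsufficientDataError("each group needs >= 2 samples with reads at the tile")
    fa = np.array([m / t for m, t in counts_a])
    fb = np.array([m / t for m, t in counts_b])
    diff = 100.0 * (fa.mean() - fb.mean())
    ma, ta = np.array([m for m, _ in counts_a]), np.array([t for _, t in counts_a])
    mb, tb = np.array([m for m, _ in counts_b]), np.array([t for _, t in counts_b])
    if method == "fisher_pooled":
        p = fisher_exact_two_sided(
            int(ma.sum()), int(ta.sum() - ma.sum()), int(mb.sum()), int(tb.sum() - mb.sum())
        )
    elif method == "logistic":
        p = _logistic_lrt(ma, ta, mb, tb)
    else:
        raise ValidationError(f"unknown test method {method!r}")
    return p, float(diff)


class PairwiseDMR:
    """One treatment-versus-control differential methylation comparison.

    Parameters
    ----------
    matrix : TileMethylMatrix
    treatment, control : group labels present in ``matrix.groups``
    min_cpgs, min_samples : informative-tile filter (per group)
    tile_subset : optional pre-selected tile ids, replacing the filter
    """

    def __init__(
        self,
        matrix: TileMethylMatrix,
        treatment: str,
        control: str,
        min_cpgs: int = 5,
        min_samples: int = 2,
        tile_subset: pd.Index | None = None,
    ):
        self.matrix = matrix
        self.treatment = treatment
        self.control = control
        self.min_cpgs = min_cpgs
        self.min_samples = min_samples
        self._treat_samples = matrix.group_samples(treatment)
        self._ctrl_samples = matrix.group_samples(control)
        if tile_subset is not None:
            self.informative = pd.Index(tile_subset)
        else:
            self.informative = informative_tiles(
                matrix, treatment, control, min_cpgs=min_cpgs, min_samples=min_samples
            )

    def fit(
        self,
        method: str = "fisher_pooled",
        diff_threshold: float = 20.0,
        q_threshold: float = 0.05,
    ) -> "PairwiseDMRResults":
        """Test every informative tile and apply BH correction."""
        ids = self.informative
        if len(ids) == 0:
            warnings.warn("zero informative tiles for this comparison")
            table = pd.DataFrame(
                columns=[
                    "mean_treatment",
                    "mean_control",
                    "difference",
                    "pvalue",
                    "qvalue",
                    "significant",
                    "direction",
                ]
            )
            return PairwiseDMRResults(self, table, method, diff_threshold, q_threshold)

        tcols, ccols = self._treat_samples, self._ctrl_samples
        mt = self.matrix.meth.loc[ids, tcols].to_numpy()
        mc = self.matrix.meth.loc[ids, ccols].to_numpy()
        mean_t = 100.0 * np.nanmean(mt, axis=1)
        mean_c = 100.0 * np.nanmean(mc, axis=1)
        diff = mean_t - mean_c

        mr_t = self.matrix.meth_reads.loc[ids, tcols].to_numpy().sum(axis=1)
        tr_t = self.matrix.total_reads.loc[ids, tcols].to_numpy().sum(axis=1)
        mr_c = self.matrix.meth_reads.loc[ids, ccols].to_numpy().sum(axis=1)
        tr_c = self.matrix.total_reads.loc[ids, ccols].to_numpy().sum(axis=1)

        if method == "fisher_pooled":
            pvals = np.array(
                [
                    fisher_exact_two_sided(
                        int(mr_t[i]), int(tr_t[i] - mr_t[i]), int(mr_c[i]), int(tr_c[i] - mr_c[i])
                    )
                    for i in range(len(ids))
                ]
            )
        elif method == "logistic":
            mrt = self.matrix.meth_reads.loc[ids, tcols].to_numpy()
            trt = self.matrix.total_reads.loc[ids, tcols].to_numpy()
            mrc = self.matrix.meth_reads.loc[ids, ccols].to_numpy()
            trc = self.matrix.total_reads.loc[ids, ccols].to_numpy()
            pvals = np.empty(len(ids))
            for i in range(len(ids)):
                ka, kb = trt[i] > 0, trc[i] > 0
                pvals[i] = _logistic_lrt(mrt[i][ka], trt[i][ka], mrc[i][kb], trc[i][kb])
        else:
            raise ValidationError(f"unknown test method {method!r}")

        qvals = multipletests(pvals, method="fdr_bh")[1]
        significant = (qvals < q_threshold) & (np.abs(diff) > diff_threshold)
        table = pd.DataFrame(
            {
                "mean_treatment": mean_t,
                "mean_control": mean_c,
                "difference": diff,
                "pvalue": pvals,
                "qvalue": qvals,
                "significant": significant,
                "direction": np.where(diff > 0, "hyper", "hypo"),
            },
            index=ids,
        )
        return PairwiseDMRResults(self, table, method, diff_threshold, q_threshold)

    def randomization(
        self,
        n_perm: int = 20,
        seed: int = 0,
        method: str = "fisher_pooled",
        diff_threshold: float = 20.0,
        q_threshold: float = 0.05,
    ) -> "RandomizationResult":
        """Re-run the full procedure under shuffled sample labels.

        Each permutation reassigns the pooled samples to two pseudo-groups of
        the original sizes (excluding the identity assignment and its
        mirror), reapplies the informative-tile filter and the test, and
        records the DMR count.
        """
        t_samp, c_samp = self._treat_samples, self._ctrl_samples
        pool = t_samp + c_samp
        n_t = len(t_samp)
        if len(pool) < 4:
            raise InsufficientDataError("need >= 4 samples for label randomization")
        observed = self.fit(method, diff_threshold, q_threshold).n_significant

        all_combos = None
        n_total = math.comb(len(pool), n_t)
        identity = frozenset(t_samp)
        mirror = frozenset(c_samp)
        rng = np.random.default_rng(seed)
        counts = []
        if n_total <= 200_000:
            all_combos = [
                frozenset(c)
                for c in itertools.combinations(pool, n_t)
                if frozenset(c) not in (identity, mirror)
            ]
            if not all_combos:
                raise InsufficientDataError("no non-identity label shuffle exists")
            pick = rng.choice(len(all_combos), size=n_perm, replace=n_perm > len(all_combos))
            chosen = [all_combos[i] for i in np.atleast_1d(pick)]
        else:
            chosen = []
            while len(chosen) < n_perm:
                sel = frozenset(rng.choice(pool, size=n_t, replace=False))
                if sel not in (identity, mirror):
                    chosen.append(sel)
        for sel in chosen:
            labels = pd.Series(
                {
                    s: (self.treatment if s in sel else self.control)
                    for s in self.matrix.samples
                }
            )
            # keep samples outside this pair under their real labels
            for s in self.matrix.samples:
                if s not in pool:
                    labels[s] = self.matrix.groups[s]
            perm = PairwiseDMR(
                self.matrix.relabel(labels),
                self.treatment,
                self.control,
                self.min_cpgs,
                self.min_samples,
            )
            counts.append(perm.fit(method, diff_threshold, q_threshold).n_significant)
        counts = np.array(counts)
        med = float(np.median(counts))
        ratio = observed / med if med > 0 else float("nan")
        return RandomizationResult(observed=observed, null_counts=counts, ratio=ratio)


@dataclass
class PairwiseDMRResults:
    """Per-tile test results of one fitted comparison."""

    model: PairwiseDMR
    table: pd.DataFrame
    method: str
    diff_threshold: float
    q_threshold: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum()) if len(self.table) else 0

    @property
    def n_hyper(self) -> int:
        t = self.table
        return int((t["significant"] & (t["direction"] == "hyper")).sum()) if len(t) else 0

    @property
    def n_hypo(self) -> int:
        t = self.table
        return int((t["significant"] & (t["direction"] == "hypo")).sum()) if len(t) else 0

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Pairwise differential methylation",
            "=" * 46,
            f"treatment:        {self.model.treatment}",
            f"control:          {self.model.control}",
            f"test:             {self.method}",
            f"informative tiles {len(self.table)}",
            f"thresholds:       q < {self.q_threshold}, |diff| > {self.diff_threshold} pp",
            f"DMRs:             {self.n_significant} ({self.n_hyper} hyper / {self.n_hypo} hypo)",
        ]
        return "\n".join(lines)


def pairwise_dmr(
    matrix: TileMethylMatrix,
    treatment: str,
    control: str,
    diff_threshold: float = 20.0,
    q_threshold: float = 0.05,
    method: str = "fisher_pooled",
    min_cpgs: int = 5,
    min_samples: int = 2,
) -> PairwiseDMRResults:
    """Convenience wrapper: build the model and fit it in one call."""
    return PairwiseDMR(matrix, treatment, control, min_cpgs, min_samples).fit(
        method=method, diff_threshold=diff_threshold, q_threshold=q_threshold
    )


@dataclass
class RandomizationResult:
    """Observed DMR count against its label-shuffled null distribution."""

    observed: int
    null_counts: np.ndarray
    ratio: float  # observed / median null; NaN when the null median is zero

    def central_interval(self, level: float = 0.90) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.null_counts, alpha)),
            float(np.quantile(self.null_counts, 1.0 - alpha)),
        )

    def observed_within(self, level: float = 0.90) -> bool:
        lo, hi = self.central_interval(level)
        return lo <= self.observed <= hi


def randomized_combinations(
    matrix: TileMethylMatrix,
    treatment: str,
    control: str,
    n_perm: int = 20,
    seed: int = 0,
    diff_threshold: float = 20.0,
    q_threshold: float = 0.05,
    method: str = "fisher_pooled",
    min_cpgs: int = 5,
    min_samples: int = 2,
) -> RandomizationResult:
    """Functional front end for :meth:`PairwiseDMR.randomization`."""
    return PairwiseDMR(matrix, treatment, control, min_cpgs, min_samples).randomization(
        n_perm=n_perm,
        seed=seed,
        method=method,
        diff_threshold=diff_threshold,
        q_threshold=q_threshold,
    )


@dataclass
class ConsensusDMRSet:
    """Tiles recurring as significant, direction-consistent, across doses."""

    table: pd.DataFrame
    min_recurrence: int
    comparisons: list[str]

    @property
    def tile_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())

    def summary(self) -> str:
        return (
            f"Consensus DMRs over {self.comparisons} (recurrence >= {self.min_recurrence}): "
            f"{len(self.table)} tiles ({self.n_hyper} hyper / {self.n_hypo} hypo)"
        )


def consensus_dmrs(
    results: list[PairwiseDMRResults], min_recurrence: int = 2
) -> ConsensusDMRSet:
    """Recurrence-based consensus over dose-versus-control comparisons.

    A tile is a consensus DMR when it is significant *with the same
    direction* in at least ``min_recurrence`` of the supplied comparisons
    (the three doses of one hormone against one control, in the reference
    design). All comparisons must share one tile universe.
    """
    if len(results) < 2:
        raise ValidationError("need >= 2 comparisons for a recurrence rule")
    universe = results[0].table.index
    for r in results[1:]:
        if not universe.equals(r.table.index):
            raise ValidationError("comparisons were made over different tile universes")
    labels = [r.model.treatment for r in results]
    hyper = sum(
        (r.table["significant"] & (r.table["direction"] == "hyper")).astype(int) for r in results
    )
    hypo = sum(
        (r.table["significant"] & (r.table["direction"] == "hypo")).astype(int) for r in results
    )
    keep_hyper = (hyper >= min_recurrence) & (hypo == 0)
    keep_hypo = (hypo >= min_recurrence) & (hyper == 0)
    rows = []
    for tid in universe[keep_hyper | keep_hypo]:
        direction = "hyper" if keep_hyper[tid] else "hypo"
        row = {"direction": direction, "n_recurrent": int(max(hyper[tid], hypo[tid]))}
        for lab, r in zip(labels, results):
            row[f"difference_{lab}"] = float(r.table.loc[tid, "difference"])
        rows.append((tid, row))
    table = pd.DataFrame([r for _, r in rows], index=pd.Index([t for t, _ in rows], name="tile_id"))
    if table.empty:
        table = pd.DataFrame(
            columns=["direction", "n_recurrent"] + [f"difference_{lab}" for lab in labels]
        )
        table.index.name = "tile_id"
    return ConsensusDMRSet(table=table, min_recurrence=min_recurrence, comparisons=labels)


def annotate_tiles(
    tiles: pd.DataFrame, genes: pd.DataFrame, promoters: pd.DataFrame
) -> pd.DataFrame:
    """Assign each tile to promoter / gene body / other and the nearest TSS.

    Category is decided at the tile midpoint with precedence promoter > gene
    body > other; nearest-TSS distance is the minimum absolute distance from
    the midpoint to any TSS, ignoring strand. ``tiles`` needs columns
    ``chrom, start, end`` (e.g. rows of :func:`~tilemeth.tiles.make_tiles`).
    """
    from intervaltree import IntervalTree

    if genes is None or len(genes) == 0:
        raise ValidationError("empty gene set")
    prom_trees: dict[str, IntervalTree] = {}
    gene_trees: dict[str, IntervalTree] = {}
    for regions, trees in ((promoters, prom_trees), (genes, gene_trees)):
        if regions is None:
            continue
        for row in regions.itertuples():
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    tss_pos: dict[str, np.ndarray] = {}
    tss_name: dict[str, np.ndarray] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        tss = np.where(sub["strand"] == "-", sub["end"] - 1, sub["start"]).astype(np.int64)
        order = np.argsort(tss)
        tss_pos[chrom] = tss[order]
        tss_name[chrom] = sub["name"].to_numpy()[order]

    cats, nearest, dist = [], [], []
    for row in tiles.itertuples():
        mid = (row.start + row.end) // 2
        if row.chrom in prom_trees and prom_trees[row.chrom].overlaps_point(mid):
            cats.append("promoter")
        elif row.chrom in gene_trees and gene_trees[row.chrom].overlaps_point(mid):
            cats.append("gene_body")
        else:
            cats.append("other")
        if row.chrom in tss_pos:
            pos = tss_pos[row.chrom]
            i = int(np.searchsorted(pos, mid))
            cand = [j for j in (i - 1, i) if 0 <= j < pos.size]
            j = min(cand, key=lambda j: abs(int(pos[j]) - mid))
            nearest.append(str(tss_name[row.chrom][j]))
            dist.append(float(abs(int(pos[j]) - mid)))
        else:
            # no gene on this chromosome: infinitely far from any TSS
            nearest.append("")
            dist.append(float("inf"))
    return pd.DataFrame(
        {"category": cats, "nearest_gene": nearest, "tss_distance": dist}, index=tiles.index
    )


def category_fractions(annotation: pd.DataFrame) -> pd.Series:
    """Fractions of tiles per category; sums to 1 for any non-empty set."""
    counts = annotation["category"].value_counts()
    return (counts / counts.sum()).reindex(
        ["promoter", "gene_body", "other"], fill_value=0.0
    )
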