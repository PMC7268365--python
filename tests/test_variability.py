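import numpy as np
import pandas as pd
import pytest

import tilemeth as tm
from tilemeth.errors import ValidationError


def two_pass_sd(values):
    """Textbook two-pass sample standard deviation."""
    v = [x for x in values if not np.isnan(x)]
    if len(v) < 2:
        return np.nan
    mean = sum(v) / len(v)
    return (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5


class TestTileSD:
    def test_constant_values(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        members = matrix.group_samples("natural")
        const = matrix.meth.copy()
        const[members] = 0.5
        m2 = tm.TileMethylMatrix(
            matrix.tiles, const, matrix.cov, matrix.meth_reads, matrix.total_reads, matrix.groups
        )
        assert (tm.tile_sd(m2, "natural").dropna() == 0).all()

    def test_closed_form_pair(self):
        assert two_pass_sd([0, 1]) == pytest.approx(0.7071, abs=1e-4)

    def test_matches_two_pass_oracle(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        sd = tm.tile_sd(matrix, "FSH5")
        members = matrix.group_samples("FSH5")
        for tid in matrix.tiles.index[:50]:
            expect = two_pass_sd(matrix.meth.loc[tid, members].to_list())
            if np.isnan(expect):
                assert np.isnan(sd[tid])
            else:
                assert sd[tid] == pytest.approx(expect, abs=1e-12)

    def test_single_value_missing(self):
        tiles = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "ordinal": [0],
                "start": [0],
                "end": [100],
                "cpg_count": [100],
                "partial": [False],
            },
            index=pd.Index(["chr1:0"], name="tile_id"),
        )
        meth = pd.DataFrame([[0.5, np.nan]], index=tiles.index, columns=["a", "b"])
        cov = pd.DataFrame([[10, 0]], index=tiles.index, columns=["a", "b"])
        mat = tm.TileMethylMatrix(tiles, meth, cov, cov, cov, pd.Series({"a": "G", "b": "G"}))
        assert np.isnan(tm.tile_sd(mat, "G").iloc[0])

    def test_unknown_group_rejected(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        with pytest.raises(ValidationError):
            tm.tile_sd(matrix, "nope")


class TestSampleRandomTiles:
    def test_identity_when_n_equals_total(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        assert tm.sample_random_tiles(matrix, len(matrix.tiles), 0).equals(matrix.tiles.index)

    def test_reproducible(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        a = tm.sample_random_tiles(matrix, 10, seed=3)
        b = tm.sample_random_tiles(matrix, 10, seed=3)
        assert list(a) == list(b)

    def test_seeds_differ(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        a = tm.sample_random_tiles(matrix, 10, seed=3)
        b = tm.sample_random_tiles(matrix, 10, seed=4)
        assert list(a) != list(b)

    def test_oversized_request_warns_and_returns_all(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        with pytest.warns(UserWarning):
            got = tm.sample_random_tiles(matrix, len(matrix.tiles) + 5, 0)
        assert got.equals(matrix.tiles.index)


class TestCGIStrata:
    def test_fully_methylated_all_high(self, planted_experiment, annotation):
        _, _, _, matrix = planted_experiment
        cgis = annotation[annotation["region_class"].str.startswith("CGI")]
        ones = matrix.meth.where(matrix.meth.isna(), 1.0)
        m2 = tm.TileMethylMatrix(
            matrix.tiles, ones, matrix.cov, matrix.meth_reads, matrix.total_reads, matrix.groups
        )
        strata = tm.cgi_strata_sd(m2, cgis, "natural")
        assert (strata["stratum"] == "high").all()

    def test_medium_stratum_most_variable(self, annotation, small_map):
        # binomial variance peaks at 50% methylation
        design = tm.SimDesign(
            groups=(tm.GroupSpec("g", n_cells=6),), seed=17, capture_prob=0.4
        )
        samples, _ = tm.simulate_methylomes(small_map, annotation, design)
        matrix = tm.tile_methylation(tm.make_tiles(small_map), samples, small_map)
        cgis = annotation[annotation["region_class"].str.startswith("CGI")]
        med = tm.strata_medians(tm.cgi_strata_sd(matrix, cgis, "g"))
        assert "medium" in med.index
        assert med["medium"] >= med.drop("medium").max()

    def test_empty_cgis_rejected(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        with pytest.raises(ValidationError):
            tm.cgi_strata_sd(matrix, pd.DataFrame(), "natural")


class TestTSSDistance:
    def test_everything_near_tss(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        # one gene per tile midpoint -> every distance is 0
        genes = pd.DataFrame(
            {
                "chrom": matrix.tiles["chrom"],
                "start": (matrix.tiles["start"] + matrix.tiles["end"]) // 2,
                "end": (matrix.tiles["start"] + matrix.tiles["end"]) // 2 + 1000,
                "strand": "+",
                "name": [f"g{i}" for i in range(len(matrix.tiles))],
                "region_class": "gene",
            }
        )
        res = tm.top_variable_tss_distance(matrix, genes, "natural", n=20)
        assert res.fraction_beyond == 0.0

    def test_single_distant_gene(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        genes = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [0],
                "end": [100],
                "strand": ["+"],
                "name": ["g"],
                "region_class": ["gene"],
            }
        )
        res = tm.top_variable_tss_distance(matrix, genes, "natural", n=len(matrix.tiles))
        assert res.fraction_beyond > 0.8

    def test_cumulative_distribution_shape(self, planted_experiment, annotation):
        _, _, _, matrix = planted_experiment
        genes = annotation[annotation["region_class"] == "gene"]
        cdf = tm.top_variable_tss_distance(matrix, genes, "natural", n=30).cumulative()
        assert cdf["cdf"].is_monotonic_increasing
        assert cdf["cdf"].iloc[-1] == pytest.approx(1.0)


class TestCorrelation:
    def test_duplicated_sample_merges_first(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        twin = matrix.meth.copy()
        twin["natural_1_twin"] = twin["natural_1"]
        groups = pd.concat([matrix.groups, pd.Series({"natural_1_twin": "natural"})])
        m2 = tm.TileMethylMatrix(
            matrix.tiles, twin, matrix.cov, matrix.meth_reads, matrix.total_reads, groups
        )
        res = tm.correlation_clustering(m2)
        assert res.corr.loc["natural_1", "natural_1_twin"] == pytest.approx(1.0)
        i, j = int(res.linkage[0, 0]), int(res.linkage[0, 1])
        first_pair = {res.clustered_samples[i], res.clustered_samples[j]}
        assert first_pair == {"natural_1", "natural_1_twin"}

    def test_anticorrelated_pair(self):
        tiles = pd.DataFrame(
            {
                "chrom": "chr1",
                "ordinal": range(10),
                "start": np.arange(10) * 100,
                "end": np.arange(10) * 100 + 90,
                "cpg_count": 100,
                "partial": False,
            },
            index=pd.Index([f"chr1:{i}" for i in range(10)], name="tile_id"),
        )
        x = np.linspace(0, 1, 10)
        meth = pd.DataFrame({"a": x, "b": 1 - x}, index=tiles.index)
        cov = (meth * 0 + 10).astype(int)
        mat = tm.TileMethylMatrix(tiles, meth, cov, cov, cov, pd.Series({"a": "A", "b": "B"}))
        res = tm.correlation_clustering(mat)
        assert res.corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        res = tm.correlation_clustering(matrix)
        c = res.corr.to_numpy()
        assert np.allclose(c, c.T, equal_nan=True)
        assert np.allclose(np.diag(c), 1.0)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_invariant_under_tile_permutation(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        rng = np.random.default_rng(1)
        perm = matrix.tiles.index[rng.permutation(len(matrix.tiles))]
        res1 = tm.correlation_clustering(matrix)
        res2 = tm.correlation_clustering(matrix.subset(perm))
        pd.testing.assert_frame_equal(res1.corr, res2.corr)

    def test_requires_two_samples(self, planted_experiment):
        _, _, _, matrix = planted_experiment
        only = matrix.meth[["natural_1"]]
        m2 = tm.TileMethylMatrix(
            matrix.tiles,
            only,
            matrix.cov[["natural_1"]],
            matrix.meth_reads[["natural_1"]],
            matrix.total_reads[["natural_1"]],
            matrix.groups[["natural_1"]],
        )
        with pytest.raises(ValidationError):
            tm.correlation_clustering(m2)


class TestIntraInter:
    def test_duplicated_groups_intra_one(self):
        tiles = pd.DataFrame(
            {
                "chrom": "chr1",
                "ordinal": range(5),
                "start": np.arange(5) * 100,
                "end": np.arange(5) * 100 + 90,
                "cpg_count": 100,
                "partial": False,
            },
            index=pd.Index([f"chr1:{i}" for i in range(5)], name="tile_id"),
        )
        base = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        meth = pd.DataFrame(
            {"a1": base, "a2": base, "b1": base[::-1], "b2": base[::-1]}, index=tiles.index
        )
        cov = (meth * 0 + 10).astype(int)
        mat = tm.TileMethylMatrix(
            tiles, meth, cov, cov, cov,
            pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}),
        )
        table = tm.intra_inter_correlation(tm.correlation_clustering(mat))
        intra = table[table["relation"] == "intra"]["r"]
        assert np.allclose(intra, 1.0)

    def test_planted_effects_raise_intra_above_inter(self, planted_experiment):
        # only FSH groups carry the planted profile, natural does not
        _, _, _, matrix = planted_experiment
        table = tm.intra_inter_correlation(tm.correlation_clustering(matrix))
        cross_profile = table[
            (table["relation"] == "inter")
            & ((table["group_a"] == "natural") | (table["group_b"] == "natural"))
        ]
        intra = table[table["relation"] == "intra"]
        assert intra["r"].median() > cross_profile["r"].median()

    def test_single_sample_group_empty_intra(self):
        tiles = pd.DataFrame(
            {
                "chrom": "chr1",
                "ordinal": range(5),
                "start": np.arange(5) * 100,
                "end": np.arange(5) * 100 + 90,
                "cpg_count": 100,
                "partial": False,
            },
            index=pd.Index([f"chr1:{i}" for i in range(5)], name="tile_id"),
        )
        meth = pd.DataFrame(
            {"a": [0.1, 0.2, 0.3, 0.4, 0.5], "b": [0.5, 0.4, 0.3, 0.2, 0.1]},
            index=tiles.index,
        )
        cov = (meth * 0 + 10).astype(int)
        mat = tm.TileMethylMatrix(
            tiles, meth, cov, cov, cov, pd.Series({"a": "A", "b": "B"})
        )
        table = tm.intra_inter_correlation(tm.correlation_clustering(mat))
        assert (table["relation"] == "inter").all()
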