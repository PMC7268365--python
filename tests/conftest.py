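import numpy as np
import pandas as pd
import pytest

import tilemeth as tm


@pytest.fixture(scope="session")
def small_map():
    return tm.generate_genome_cpg_map(2, 3000, 100, seed=11)


@pytest.fixture(scope="session")
def annotation(small_map):
    return tm.generate_gene_annotation(small_map, 6, seed=12)


@pytest.fixture(scope="session")
def planted_experiment(small_map, annotation):
    """Control + three FSH doses sharing one planted-DMR profile."""
    design = tm.SimDesign(
        groups=(
            tm.GroupSpec("natural", "", 6, None),
            tm.GroupSpec("FSH5", "5IU", 6, "FSH"),
            tm.GroupSpec("FSH50", "50IU", 6, "FSH"),
            tm.GroupSpec("FSH200", "200IU", 6, "FSH"),
        ),
        seed=13,
        n_planted_per_profile=8,
        capture_prob=0.5,
    )
    samples, truth = tm.simulate_methylomes(small_map, annotation, design)
    tiles = tm.make_tiles(small_map)
    matrix = tm.tile_methylation(tiles, samples, small_map)
    return design, samples, truth, matrix


def random_methylome(rng: np.random.Generator, n_sites: int = 200, sample_id: str = "s"):
    """A random merged single-cell methylome over two chromosomes."""
    chroms = np.where(rng.random(n_sites) < 0.5, "chr1", "chr2")
    pos = {}
    rows = []
    for chrom in ("chr1", "chr2"):
        k = int((chroms == chrom).sum())
        if k == 0:
            continue
        p = np.cumsum(rng.integers(2, 200, size=k))
        total = rng.integers(1, 5, size=k)
        meth = rng.binomial(total, 0.5)
        ctx = rng.choice(["CG", "CG", "CG", "CHH", "CHG"], size=k)
        for i in range(k):
            rows.append((chrom, int(p[i]), str(ctx[i]), int(meth[i]), int(total[i] - meth[i])))
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "context", "meth", "unmeth"])
    return tm.SampleMethylome(sample_id, calls)
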