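import numpy as np
import pandas as pd
import pytest

from slrkit import simdata
from slrkit.variants import GenotypeMatrix

SMALL_LAYOUT = (("PAR1", 120_000), ("IV", 80_000), ("YDR", 60_000), ("PAR2", 40_000))


def small_config(**kw):
    base = dict(
        chrom_length=300_000, region_layout=SMALL_LAYOUT,
        n_te_insertions_x=6, n_te_insertions_y=6,
        min_tip_spacing=3_000, region_edge_buffer=5_000,
        snp_density=0.01, coverage_bin_size=5_000, seed=42,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


@pytest.fixture(scope="session")
def clean_pair():
    """A small X/Y pair without background X-vs-Y SNPs (clean junctions)."""
    cfg = small_config(xy_snp_rate=0.0)
    x, y, truth = simdata.build_reference_pair(cfg)
    return cfg, x, y, truth


@pytest.fixture(scope="session")
def population():
    """Three-group population with planted fully sex-linked sites, no missing."""
    cfg = small_config()
    x, y, truth = simdata.build_reference_pair(cfg)
    m = simdata.simulate_genotypes(truth, cfg)
    return cfg, truth, m


def make_matrix(geno, sexes, groups=None, pos=None, quals=None, chrom="chr1"):
    """Assemble a GenotypeMatrix from a plain genotype array for unit tests."""
    geno = np.asarray(geno, dtype=np.int8)
    n_sites, n_samples = geno.shape
    if groups is None:
        groups = ["g"] * n_samples
    if pos is None:
        pos = np.arange(1, n_sites + 1)
    if quals is None:
        quals = np.full(n_sites, 60.0)
    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos, "ref": "A", "alt": "T",
        "qual": quals, "region_label": None,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samples)],
        "sex": list(sexes), "group": list(groups),
    })
    return GenotypeMatrix(sites, samples, geno)


@pytest.fixture
def matrix_factory():
    return make_matrix
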