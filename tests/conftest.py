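import numpy as np
import pytest

from sweepscan import HaplotypePanel, SiteMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_sites(n, spacing_bp=1000, cm_per_site=0.01, chrom="1"):
    return [
        SiteMeta(
            snp_id=f"s{i}",
            chromosome=chrom,
            position_bp=spacing_bp * (i + 1),
            ancestral_allele="A",
            derived_allele="G",
            genetic_pos_cM=cm_per_site * i,
        )
        for i in range(n)
    ]


def random_panel(rng, n_hap=None, n_sites=None):
    n_hap = n_hap if n_hap is not None else 2 * int(rng.integers(2, 9))
    n_sites = n_sites if n_sites is not None else int(rng.integers(5, 21))
    hap = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.int8)
    return HaplotypePanel(sites=make_sites(n_sites), haplotypes=hap)


@pytest.fixture
def small_panel(rng):
    return random_panel(rng, n_hap=8, n_sites=12)
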