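import numpy as np
import pandas as pd
import pytest

from poolscan.dataio import PoolCountMatrix, PoolSample
from poolscan.intervals import GenomicInterval
from poolscan.simulate import (
    DivergentLocus,
    InversionConfig,
    SimConfig,
    simulate_pool_dataset,
)


def make_pools(n, n_individuals=50, season="fall"):
    seasons = [season] * n if isinstance(season, str) else list(season)
    suffix = {"spring": "S", "fall": "F", "summer": "U", "mixed": "M"}
    return [
        PoolSample(
            id=f"T{i + 1:02d}-{suffix[seasons[i]]}",
            latitude=44.0 + i,
            longitude=-60.0,
            season=seasons[i],
            n_individuals=n_individuals,
        )
        for i in range(n)
    ]


def make_counts(ref, alt, pools=None, positions=None, chrom="Chr1"):
    """Small PoolCountMatrix from explicit count arrays."""
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    n_snps, n_pools = ref.shape
    if pools is None:
        pools = make_pools(n_pools)
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 1000
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "C"}
    )
    return PoolCountMatrix(snps=snps, ref=ref, alt=alt, pools=pools)


@pytest.fixture(scope="session")
def planted_cfg():
    """10 pools (5 spring / 5 fall), one 200-SNP divergent locus, delta 0.6."""
    return SimConfig(
        n_pools=10,
        n_snps=3000,
        chrom_lengths={"Chr1": 25_000_000},
        divergent_loci=[
            DivergentLocus(
                GenomicInterval("Chr1", 10_000_000, 10_500_000),
                delta=0.6,
                n_snps=200,
            )
        ],
        depth_mean=60.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_cfg):
    return simulate_pool_dataset(planted_cfg)


@pytest.fixture(scope="session")
def inversion_cfg():
    """15 pools with an inversion block on a winter-temperature cline."""
    return SimConfig(
        n_snps=1500,
        chrom_lengths={"Chr1": 20_000_000, "Chr2": 20_000_000},
        inversion=InversionConfig.from_gene_flux(
            GenomicInterval("Chr2", 8_000_000, 12_000_000),
            n_sites=300,
            gene_flux=0.8,
            cline_b=2.0,
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def inversion_dataset(inversion_cfg):
    return simulate_pool_dataset(inversion_cfg)
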