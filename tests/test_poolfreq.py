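"""Effective sample size, filters, polarisation, partitions, thinning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolscan import poolfreq
from poolscan.poolfreq import (
    allele_frequencies,
    effective_sample_size,
    filter_snps,
    partition_markers,
    polarize_minor,
    rescale_counts,
    thin_by_distance,
)

from conftest import make_counts, make_pools


class TestEffectiveSampleSize:
    def test_spot_values(self):
        assert effective_sample_size(100, 50) == pytest.approx(4999 / 150)
        assert effective_sample_size(2, 1) == pytest.approx(1 / 3)

    def test_approaches_n_at_high_depth(self):
        assert effective_sample_size(100, 1e6) == pytest.approx(
            99.99, abs=0.005
        )

    def test_zero_depth_is_missing(self):
        assert np.isnan(effective_sample_size(100, 0))

    @given(
        n=st.integers(2, 1000),
        rd1=st.integers(2, 10_000),
        rd2=st.integers(2, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_in_depth(self, n, rd1, rd2):
        ne1 = effective_sample_size(n, rd1)
        assert 0 < ne1 < min(n, rd1)
        if rd2 > rd1:
            assert effective_sample_size(n, rd2) > ne1


def test_rescaling_cancels_in_frequency():
    rng = np.random.default_rng(1)
    counts = make_counts(
        rng.integers(1, 80, (50, 4)), rng.integers(1, 80, (50, 4))
    )
    ref_rs, alt_rs, n_eff = rescale_counts(counts)
    raw = counts.alt / counts.coverage
    rescaled = alt_rs / (ref_rs + alt_rs)
    np.testing.assert_allclose(rescaled, raw, atol=1e-12)
    # rescaled totals equal n_eff
    np.testing.assert_allclose(ref_rs + alt_rs, n_eff, atol=1e-9)


class TestFilterSnps:
    def test_monomorphic_dropped(self):
        ref = np.full((6, 4), 30)
        alt = np.full((6, 4), 30)
        alt[2] = 0  # monomorphic SNP
        counts = make_counts(ref, alt)
        filtered, report = filter_snps(
            counts, coverage_percentiles=(0, 100)
        )
        assert filtered.n_snps == 5
        assert report["dropped_mac"] + report["dropped_monomorphic"] == 1
        assert 3000 not in filtered.snps["pos"].tolist()

    def test_clean_table_untouched(self):
        rng = np.random.default_rng(2)
        counts = make_counts(
            rng.integers(20, 40, (10, 4)), rng.integers(20, 40, (10, 4))
        )
        filtered, report = filter_snps(counts, coverage_percentiles=(0, 100))
        assert filtered.n_snps == 10
        assert report["cells_masked_coverage"] == 0

    def test_coverage_mask_brute_force(self):
        # brute-force application of the stated rules to a 40x4 table
        rng = np.random.default_rng(3)
        ref = rng.integers(10, 30, (40, 4))
        alt = rng.integers(10, 30, (40, 4))
        ref[7, 2], alt[7, 2] = 400, 400  # far above pool 2's 99th pct
        counts = make_counts(ref, alt)
        filtered, report = filter_snps(counts, max_missing=0.5)
        cov = ref + alt
        lo = np.percentile(cov, 5, axis=0)
        hi = np.percentile(cov, 99, axis=0)
        expect_mask = (cov < lo[None, :]) | (cov > hi[None, :])
        assert report["cells_masked_coverage"] == expect_mask.sum()
        # the flagged cell is masked but its SNP survives (missing rate 25%)
        row = filtered.snps.index[filtered.snps["pos"] == 8000][0]
        assert filtered.missing[row, 2]

    def test_missing_rate_rule(self):
        ref = np.full((5, 5), 30)
        alt = np.full((5, 5), 30)
        counts = make_counts(ref, alt)
        counts.missing[0, :2] = True  # 40% missing -> dropped at 20% rule
        filtered, report = filter_snps(counts, coverage_percentiles=(0, 100))
        assert report["dropped_missing_rate"] == 1
        assert filtered.n_snps == 4

    def test_all_removed_fatal(self):
        counts = make_counts(np.full((3, 4), 30), np.zeros((3, 4), int))
        with pytest.raises(RuntimeError, match="all SNPs removed"):
            filter_snps(counts, coverage_percentiles=(0, 100))

    def test_invariant_to_pool_order(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 60, (30, 5))
        alt = rng.integers(0, 60, (30, 5))
        pools = make_pools(5)
        a, _ = filter_snps(make_counts(ref, alt, pools=pools))
        perm = [3, 1, 4, 0, 2]
        b, _ = filter_snps(
            make_counts(ref[:, perm], alt[:, perm],
                        pools=[pools[i] for i in perm])
        )
        assert a.n_snps == b.n_snps
        assert a.snps["pos"].tolist() == b.snps["pos"].tolist()


class TestPolarize:
    def test_flip_and_tie(self):
        freq = np.array([[0.8, 0.8], [0.5, 0.5], [0.2, 0.3]])
        counts = make_counts(
            np.full((3, 2), 10), np.full((3, 2), 10)
        )
        afm = allele_frequencies(counts)
        afm.freq = freq
        pol = polarize_minor(afm)
        np.testing.assert_allclose(pol.freq[0], [0.2, 0.2])
        np.testing.assert_allclose(pol.freq[1], [0.5, 0.5])  # tie kept
        np.testing.assert_allclose(pol.freq[2], [0.2, 0.3])
        assert pol.flipped.tolist() == [True, False, False]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        counts = make_counts(
            rng.integers(1, 60, (20, 4)), rng.integers(1, 60, (20, 4))
        )
        once = polarize_minor(allele_frequencies(counts))
        twice = polarize_minor(once)
        np.testing.assert_array_equal(once.freq, twice.freq)
        np.testing.assert_array_equal(once.flipped, twice.flipped)


class TestPartition:
    def _afm(self, freq):
        n_snps, n_pools = freq.shape
        counts = make_counts(
            np.full((n_snps, n_pools), 10), np.full((n_snps, n_pools), 10)
        )
        afm = allele_frequencies(counts)
        afm.freq = freq
        return afm

    def test_zero_variance_in_neither_set(self):
        afm = self._afm(np.full((3, 6), 0.4))
        part = partition_markers(afm)
        assert len(part.undifferentiated) == 0
        assert len(part.differentiated) == 0

    def test_opposite_fixation_differentiated(self):
        freq = np.tile([0.0, 1.0, 0.0, 1.0, 0.0, 1.0], (2, 1))
        part = partition_markers(self._afm(freq))
        assert set(part.differentiated) == {0, 1}

    def test_sd_boundary_inclusive(self):
        # construct a SNP whose minor-frequency SD is exactly 0.09
        base = np.array([0.2, 0.2, 0.2, 0.2])
        x = base + np.array([-1, 1, -1, 1]) * 0.09
        freq = x[None, :]
        afm = self._afm(freq)
        sd = np.nanstd(freq, ddof=1)
        assert sd == pytest.approx(0.09 * np.sqrt(4 / 3))
        part = partition_markers(afm, sd_band=(0.03, float(sd)))
        assert 0 in part.undifferentiated

    def test_sets_disjoint_and_order_free(self):
        rng = np.random.default_rng(6)
        freq = rng.uniform(0, 1, (100, 8))
        afm = self._afm(freq)
        part = partition_markers(afm)
        assert not set(part.undifferentiated) & set(part.differentiated)
        part2 = partition_markers(self._afm(freq[:, ::-1].copy()))
        np.testing.assert_array_equal(
            part.undifferentiated, part2.undifferentiated
        )


class TestThinning:
    def _snps(self, positions, chrom="Chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_one_per_window(self):
        idx = thin_by_distance(self._snps([100, 500, 1050, 2200]), 1000)
        assert idx.tolist() == [0, 2, 3]

    def test_zero_spacing_keeps_all(self):
        idx = thin_by_distance(self._snps([5, 6, 7]), 0)
        assert idx.tolist() == [0, 1, 2]

    def test_single_snp_kept(self):
        assert thin_by_distance(self._snps([42]), 10_000).tolist() == [0]

    def test_unsorted_fatal(self):
        with pytest.raises(ValueError, match="sorted"):
            thin_by_distance(self._snps([500, 100]), 1000)

    def test_per_chromosome_reset(self):
        snps = pd.DataFrame(
            {"chrom": ["Chr1", "Chr1", "Chr2"], "pos": [100, 200, 150]}
        )
        assert thin_by_distance(snps, 1000).tolist() == [0, 2]


def test_genotype_passthrough_filter():
    from poolscan.dataio import GenotypeMatrix

    snps = pd.DataFrame(
        {"chrom": "Chr1", "pos": [1, 2, 3], "ref": "A", "alt": "C"}
    )
    g = np.array(
        [
            [0, 1, 2, 1, 0, 1],   # maf ~0.42 -> kept
            [0, 0, 0, 0, 0, 1],   # maf ~0.08 -> dropped
            [-1, 1, 2, 1, 0, 1],  # 17% missing -> dropped at 10% rule
        ],
        dtype=np.int8,
    )
    gm = GenotypeMatrix(snps=snps, genotypes=g,
                        individuals=[f"i{k}" for k in range(6)])
    out = poolfreq.filter_genotypes(gm)
    assert out.snps["pos"].tolist() == [1]
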