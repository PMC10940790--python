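"""Karyotype calling, LD windows and allele sharing / gene flux."""

import numpy as np
import pandas as pd
import pytest

from poolscan.dataio import GenotypeMatrix
from poolscan.intervals import GenomicInterval
from poolscan.simulate import (
    InversionConfig,
    SimConfig,
    simulate_individual_genotypes,
)
from poolscan.svtools import (
    KaryotypeCaller,
    allele_sharing,
    call_karyotypes,
    classify_snps,
    gene_flux_summary,
    ld_matrix,
    mean_r2_within,
)

REGION = GenomicInterval("Chr2", 8_000_000, 12_000_000)


def make_genos(genotypes, positions=None, chrom="Chr2"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_snps, n_ind = genotypes.shape
    pos = positions if positions is not None else (
        REGION.start + np.arange(n_snps) * 1000
    )
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": "A", "alt": "C"})
    return GenotypeMatrix(
        snps=snps, genotypes=genotypes,
        individuals=[f"i{k:03d}" for k in range(n_ind)],
    )


def sv_config(gene_flux=0.0, n_sites=200, seed=3, cline_b=0.0, cline_a=0.0):
    return SimConfig(
        n_snps=200,
        chrom_lengths={"Chr2": 20_000_000},
        inversion=InversionConfig.from_gene_flux(
            REGION, n_sites=n_sites, gene_flux=gene_flux,
            cline_a=cline_a, cline_b=cline_b,
        ),
        seed=seed,
    )


class TestKaryotypeCalling:
    def test_recovers_simulated_truth(self):
        genos, truth = simulate_individual_genotypes(sv_config(0.3), 90)
        calls = call_karyotypes(genos, REGION)
        acc = np.mean(
            [c.call == k for c, k in zip(calls, truth.karyotypes)]
        )
        assert acc >= 0.98
        assert not calls[0].low_confidence

    def test_all_heterozygous_individual_called_ab(self):
        rng = np.random.default_rng(0)
        # 30 AA, 30 BB and one fully heterozygous individual
        g = np.hstack(
            [np.zeros((60, 30), int), np.full((60, 30), 2),
             np.ones((60, 1), int)]
        )
        caller = KaryotypeCaller().fit(make_genos(g))
        assert caller.labels_[-1] == "AB"
        assert set(caller.labels_[:30]) == {"AA"}
        assert set(caller.labels_[30:60]) == {"BB"}

    def test_structureless_region_low_confidence(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, (40, 50))
        caller = KaryotypeCaller().fit(make_genos(g))
        assert caller.low_confidence_

    def test_too_few_snps_fatal(self):
        g = np.zeros((5, 20), dtype=np.int8)
        with pytest.raises(ValueError, match="SNPs"):
            KaryotypeCaller().fit(make_genos(g))

    def test_all_one_karyotype_when_frequency_fixed(self):
        # haplotype B fixed in every pool -> everyone BB
        cfg = sv_config(0.0, cline_a=20.0)  # logistic(20) ~ 1
        genos, truth = simulate_individual_genotypes(cfg, 45)
        assert set(truth.karyotypes) == {"BB"}


class TestLd:
    def test_identical_dosage_vectors_r2_one(self):
        rng = np.random.default_rng(2)
        row = rng.binomial(2, 0.5, 30)
        g = np.vstack([row, row, rng.binomial(2, 0.5, 30)])
        ld = ld_matrix(
            make_genos(g, positions=[REGION.start, REGION.start + 1,
                                     REGION.start + 6000]),
            REGION,
        )
        same_bin_pair = ld.table.iloc[0]
        assert same_bin_pair["mean_r2"] == pytest.approx(1.0)

    def test_independent_snps_low_r2(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, rng.uniform(0.2, 0.8, (200, 1)), (200, 50))
        ld = ld_matrix(make_genos(g), REGION)
        overall = (
            ld.table["mean_r2"] * ld.table["n_pairs"]
        ).sum() / ld.table["n_pairs"].sum()
        assert overall < 0.05

    def test_pooled_ld_exceeds_within_homozygote_ld(self):
        genos, truth = simulate_individual_genotypes(sv_config(0.4), 120)
        karyo = dict(zip(genos.individuals, truth.karyotypes))
        ld_all = ld_matrix(genos, REGION, subset="all")
        ld_aa = ld_matrix(genos, REGION, subset="AA", karyotypes=karyo)
        assert mean_r2_within(ld_all, REGION) > mean_r2_within(ld_aa, REGION)

    def test_empty_subset_fatal(self):
        genos, truth = simulate_individual_genotypes(sv_config(0.4), 30)
        with pytest.raises(ValueError, match="karyotype"):
            ld_matrix(genos, REGION, subset="AA",
                      karyotypes={i: "AB" for i in genos.individuals})


class TestSharing:
    def test_threshold_rules(self):
        # group frequencies engineered per column-block of individuals
        n = 10  # per group
        rows = {
            "diagnostic": np.r_[np.repeat(2, 9), [1]],  # 0.95 vs 0.05
            "shared": np.ones(n, dtype=int),            # 0.5 vs 0.5
            "other": np.r_[np.repeat(2, 9), [1]],       # 0.95 vs 0.5
        }
        g = np.vstack(
            [
                np.r_[rows["diagnostic"], 2 - rows["diagnostic"]],
                np.r_[rows["shared"], rows["shared"]],
                np.r_[rows["other"], np.ones(n, dtype=int)],
            ]
        )
        genos = make_genos(g)
        aa = genos.individuals[:n]
        bb = genos.individuals[n:]
        cls = classify_snps(genos, aa, bb)
        assert cls["klass"].tolist() == ["diagnostic", "shared", "other"]

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, rng.uniform(0, 1, (50, 1)), (50, 20))
        genos = make_genos(g)
        aa, bb = genos.individuals[:10], genos.individuals[10:]
        a = classify_snps(genos, aa, bb)["klass"]
        b = classify_snps(genos, bb, aa)["klass"]
        assert (a == b).all()

    def test_identical_groups_no_diagnostic(self):
        rng = np.random.default_rng(5)
        half = rng.binomial(2, 0.5, (40, 10))
        g = np.hstack([half, half])
        genos = make_genos(g)
        cls = classify_snps(genos, genos.individuals[:10],
                            genos.individuals[10:])
        assert (cls["klass"] != "diagnostic").all()

    def test_small_groups_fatal(self):
        genos = make_genos(np.zeros((20, 3), dtype=np.int8))
        with pytest.raises(ValueError, match=">= 2"):
            classify_snps(genos, genos.individuals[:1], genos.individuals[1:])


class TestGeneFlux:
    def _recovered(self, flux, seed=6, n_ind=120, n_sites=500):
        cfg = sv_config(flux, n_sites=n_sites, seed=seed)
        genos, truth = simulate_individual_genotypes(cfg, n_ind)
        karyo = dict(zip(genos.individuals, truth.karyotypes))
        aa = [i for i, c in karyo.items() if c == "AA"]
        bb = [i for i, c in karyo.items() if c == "BB"]
        windows = allele_sharing(genos, aa, bb, REGION)
        return gene_flux_summary(windows)

    def test_zero_flux_all_diagnostic(self):
        out = self._recovered(0.0, n_sites=200)
        assert out["shared_fraction"] == 0.0
        assert out["n_shared"] == 0

    def test_flux_recovered_within_tolerance(self):
        out = self._recovered(0.8)
        assert out["shared_fraction"] == pytest.approx(0.8, abs=0.05)

    def test_flux_ranking_preserved(self):
        lo = self._recovered(0.2, seed=7)
        hi = self._recovered(0.8, seed=8)
        assert hi["shared_fraction"] > lo["shared_fraction"]
        assert lo["shared_fraction"] == pytest.approx(0.2, abs=0.05)

    def test_consistency_small_bias(self):
        out = self._recovered(0.5, n_ind=200, n_sites=500)
        assert abs(out["shared_fraction"] - 0.5) < 0.02

    def test_empty_windows_fatal(self):
        with pytest.raises(ValueError, match="window"):
            gene_flux_summary(pd.DataFrame())

    def test_window_counts_partition_classified_snps(self):
        cfg = sv_config(0.5, n_sites=300, seed=9)
        genos, truth = simulate_individual_genotypes(cfg, 90)
        karyo = dict(zip(genos.individuals, truth.karyotypes))
        aa = [i for i, c in karyo.items() if c == "AA"]
        bb = [i for i, c in karyo.items() if c == "BB"]
        w = allele_sharing(genos, aa, bb, REGION)
        inv = genos.subset_region(REGION)
        cls = classify_snps(inv, aa, bb)
        n_classified = (cls["klass"] != "excluded").sum()
        assert (
            w["n_shared"].sum() + w["n_diagnostic"].sum()
            + w["n_other"].sum() == n_classified
        )
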