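"""Allele-frequency estimation from pooled read counts.

Read counts from a pool of N diploids carry two layers of sampling noise:
the draw of 2N chromosomes into the pool and the draw of reads from the
pool.  The effective number of chromosomes

    n_eff = (n * RD - 1) / (n + RD),      n = 2N, RD = read depth

summarises both (1/n_eff ~ 1/n + 1/RD), and raw counts rescaled by
n_eff/RD behave like counts of n_eff independently sampled chromosomes.
Rescaling cancels in the frequency ratio alt/(ref+alt); it matters through
n_eff in downstream estimators (FST, per-SNP tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import GenotypeMatrix, PoolCountMatrix, PoolSample


def effective_sample_size(n, rd):
    """n_eff = (n*RD - 1)/(n + RD); NaN where RD == 0.

    Monotone increasing in RD, with n_eff -> n as RD -> infinity.
    """
    n = np.asarray(n, dtype=float)
    rd = np.asarray(rd, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = (n * rd - 1.0) / (n + rd)
    return np.where(rd > 0, ne, np.nan)


def rescale_counts(counts: PoolCountMatrix):
    """Rescale raw ref/alt reads to effective-sample-size units.

    Returns (ref_rescaled, alt_rescaled, n_eff), all float arrays of shape
    (n_snps, n_pools) with NaN at missing cells.  Rescaled counts are kept
    real-valued; rounding would bias low-coverage cells.
    """
    rd = counts.coverage.astype(float)
    n = counts.n_chromosomes.astype(float)[None, :]
    n_eff = effective_sample_size(n, rd)
    n_eff = np.where(counts.missing, np.nan, n_eff)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = n_eff / rd
    return counts.ref * scale, counts.alt * scale, n_eff


@dataclass
class AlleleFrequencyMatrix:
    """Pool allele frequencies (SNPs x pools) with per-cell n_eff.

    ``freq`` tracks the VCF alt allele unless ``polarized`` is set, in
    which case it tracks the minor allele and ``flipped`` records the
    orientation applied per SNP.
    """

    snps: pd.DataFrame
    freq: np.ndarray
    n_eff: np.ndarray
    pools: list[PoolSample]
    polarized: bool = False
    flipped: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_ids(self) -> list[str]:
        return [p.id for p in self.pools]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.freq)

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of pools with no usable data."""
        return self.missing.mean(axis=1)

    def take_snps(self, index) -> "AlleleFrequencyMatrix":
        index = np.asarray(index)
        return AlleleFrequencyMatrix(
            snps=self.snps.iloc[index].reset_index(drop=True),
            freq=self.freq[index],
            n_eff=self.n_eff[index],
            pools=list(self.pools),
            polarized=self.polarized,
            flipped=None if self.flipped is None else self.flipped[index],
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.snps.copy()
        for j, pid in enumerate(self.pool_ids):
            out[pid] = self.freq[:, j]
        return out


def allele_frequencies(counts: PoolCountMatrix) -> AlleleFrequencyMatrix:
    """Per-pool alt-allele frequencies alt/(ref+alt), NaN where missing."""
    cov = counts.coverage.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts.alt / cov
    freq = np.where(counts.missing, np.nan, freq)
    _, _, n_eff = rescale_counts(counts)
    return AlleleFrequencyMatrix(
        snps=counts.snps.copy(), freq=freq, n_eff=n_eff,
        pools=list(counts.pools),
    )


def filter_snps(
    counts: PoolCountMatrix,
    max_missing: float = 0.20,
    min_mac: int = 2,
    coverage_percentiles: tuple[float, float] = (5.0, 99.0),
):
    """Apply the pool-seq SNP quality filters.

    Rules, applied in order:

    1. coverage mask — per pool, cells outside that pool's [5th, 99th]
       coverage percentile (computed over all SNPs before any masking,
       linear interpolation) are set missing;
    2. missing rate — SNPs missing in >= *max_missing* of pools dropped;
    3. minor allele count — SNPs whose minor allele has < *min_mac* raw
       reads summed over non-missing pools dropped;
    4. polymorphism — monomorphic SNPs dropped.

    Returns (filtered PoolCountMatrix, report dict).
    """
    if counts.n_snps == 0:
        raise ValueError("empty count matrix")
    lo_q, hi_q = coverage_percentiles
    cov = counts.coverage.astype(float)
    cov_for_q = np.where(counts.missing, np.nan, cov)
    lo = np.nanpercentile(cov_for_q, lo_q, axis=0)
    hi = np.nanpercentile(cov_for_q, hi_q, axis=0)
    out_of_range = (cov < lo[None, :]) | (cov > hi[None, :])
    missing = counts.missing | out_of_range
    n_masked = int((out_of_range & ~counts.missing).sum())

    miss_rate = missing.mean(axis=1)
    keep = miss_rate < max_missing
    n_drop_missing = int((~keep).sum())

    ref_ok = np.where(missing, 0, counts.ref).sum(axis=1)
    alt_ok = np.where(missing, 0, counts.alt).sum(axis=1)
    mac = np.minimum(ref_ok, alt_ok)
    drop_mac = keep & (mac < min_mac)
    n_drop_mac = int(drop_mac.sum())
    keep &= ~drop_mac

    mono = keep & ((alt_ok == 0) | (ref_ok == 0))
    n_drop_mono = int(mono.sum())
    keep &= ~mono

    report = {
        "n_input": counts.n_snps,
        "cells_masked_coverage": n_masked,
        "dropped_missing_rate": n_drop_missing,
        "dropped_mac": n_drop_mac,
        "dropped_monomorphic": n_drop_mono,
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        raise RuntimeError(f"all SNPs removed by filters: {report}")
    idx = np.nonzero(keep)[0]
    filtered = PoolCountMatrix(
        snps=counts.snps.iloc[idx].reset_index(drop=True),
        ref=counts.ref[idx],
        alt=counts.alt[idx],
        pools=list(counts.pools),
        missing=missing[idx],
    )
    return filtered, report


def polarize_minor(freqs: AlleleFrequencyMatrix) -> AlleleFrequencyMatrix:
    """Flip each SNP so the tracked allele is the minor one.

    The tracked allele becomes the one with pooled mean frequency <= 0.5
    across pools (ties keep the current orientation).  Idempotent.
    """
    mean = np.nanmean(freqs.freq, axis=1)
    flip = mean > 0.5
    freq = np.where(flip[:, None], 1.0 - freqs.freq, freqs.freq)
    prev = freqs.flipped if freqs.flipped is not None else np.zeros(
        freqs.n_snps, dtype=bool
    )
    return AlleleFrequencyMatrix(
        snps=freqs.snps.copy(),
        freq=freq,
        n_eff=freqs.n_eff.copy(),
        pools=list(freqs.pools),
        polarized=True,
        flipped=prev ^ flip,
    )


@dataclass
class MarkerPartition:
    """The two SNP sets used for structure analyses.

    *undifferentiated* markers have minor-allele-frequency SD across pools
    in (0.03, 0.09]; *differentiated* markers have SD >= 0.2; everything
    else belongs to neither.  Thinned index lists keep one SNP per 1 kbp
    (undifferentiated) / 10 kbp (differentiated) by default.
    """

    sd: np.ndarray
    undifferentiated: np.ndarray
    differentiated: np.ndarray
    undifferentiated_thinned: np.ndarray = field(default=None)  # type: ignore
    differentiated_thinned: np.ndarray = field(default=None)  # type: ignore


def partition_markers(
    freqs: AlleleFrequencyMatrix,
    sd_band: tuple[float, float] = (0.03, 0.09),
    sd_high: float = 0.2,
    thin_undiff_bp: int = 1_000,
    thin_diff_bp: int = 10_000,
) -> MarkerPartition:
    """Split SNPs into undifferentiated / differentiated sets by the SD of
    minor-allele frequencies across pools (denominator n-1), then thin each
    set by physical distance."""
    if freqs.n_pools < 2:
        raise ValueError("need >= 2 pools")
    pol = freqs if freqs.polarized else polarize_minor(freqs)
    n_obs = (~pol.missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(pol.freq, axis=1, ddof=1)
    sd = np.where(n_obs >= 2, sd, np.nan)

    lo, hi = sd_band
    undiff = np.nonzero((sd > lo) & (sd <= hi))[0]
    diff = np.nonzero(sd >= sd_high)[0]

    part = MarkerPartition(sd=sd, undifferentiated=undiff, differentiated=diff)
    part.undifferentiated_thinned = undiff[
        thin_by_distance(pol.snps.iloc[undiff], thin_undiff_bp)
    ]
    part.differentiated_thinned = diff[
        thin_by_distance(pol.snps.iloc[diff], thin_diff_bp)
    ]
    return part


def thin_by_distance(snps: pd.DataFrame, spacing: int) -> np.ndarray:
    """Thin to one SNP per *spacing*-bp window ("one SNP every 1 kbp").

    Windows are anchored at the chromosome origin; the first SNP by
    position in each window is kept (deterministic and order-free).  The
    first SNP of a chromosome is therefore always kept.  Returns
    positional indices into *snps*; unsorted positions are fatal.
    """
    chrom = snps["chrom"].to_numpy()
    pos = snps["pos"].to_numpy()
    for c in np.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("positions must be sorted within chromosomes")
    if spacing <= 0:
        return np.arange(len(snps), dtype=int)
    kept = []
    last_chrom, last_bin = None, None
    for i in range(len(snps)):
        b = pos[i] // spacing
        if chrom[i] != last_chrom or b != last_bin:
            kept.append(i)
            last_chrom, last_bin = chrom[i], b
    return np.array(kept, dtype=int)


def filter_genotypes(
    genos: GenotypeMatrix, min_maf: float = 0.1, max_missing: float = 0.1
) -> GenotypeMatrix:
    """Pass-through MAF/missingness filter for individual genotypes."""
    g = genos.genotypes
    miss = g < 0
    n_obs = (~miss).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(miss, 0, g).sum(axis=1) / (2.0 * n_obs)
    maf = np.minimum(af, 1 - af)
    keep = (
        (miss.mean(axis=1) < max_missing) & (n_obs > 0) & (maf > min_maf)
    )
    return genos.take_snps(np.nonzero(keep)[0])
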