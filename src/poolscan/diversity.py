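"""Windowed nucleotide diversity and Tajima's D from pooled reads.

Coverage heterogeneity is removed first by subsampling every site without
replacement to a uniform depth C (by default the 5% quantile of the
pool's coverage distribution); the C retained reads are then treated as C
sampled chromosomes — the standard pool-seq approximation — so the
classical Tajima (1989) constants apply at sample size C.

Per segregating site the heterozygosity is

    h = C/(C-1) * (1 - sum_a (c_a/C)^2) = 2 k (C-k) / (C (C-1)),

summed within 10-kbp windows (2-kbp step); pi divides the sum by the
number of covered positions, Tajima's D contrasts the sum with Watterson's
theta = S/a1.  Windows less than half covered are reported missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import PoolCountMatrix


def subsample_coverage(
    ref: np.ndarray,
    alt: np.ndarray,
    target_c: int,
    seed: int | np.random.Generator = 0,
    min_minor: int = 2,
):
    """Subsample each site's reads without replacement to depth *target_c*.

    Returns (alt_sub, masked, is_seg): the alt count among the C retained
    reads (hypergeometric draw), a mask of sites with coverage below C,
    and a flag for sites still segregating (minor count >= *min_minor*)
    after subsampling — the rest are treated as monomorphic.
    """
    if target_c < 4:
        raise ValueError("target coverage must be >= 4")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ref = np.asarray(ref, dtype=np.int64)
    alt = np.asarray(alt, dtype=np.int64)
    cov = ref + alt
    masked = cov < target_c
    alt_sub = np.zeros_like(alt)
    ok = ~masked
    exact = ok & (cov == target_c)
    alt_sub[exact] = alt[exact]
    draw = ok & (cov > target_c)
    if draw.any():
        alt_sub[draw] = rng.hypergeometric(alt[draw], ref[draw], target_c)
    minor = np.minimum(alt_sub, target_c - alt_sub)
    is_seg = ok & (minor >= min_minor)
    return alt_sub, masked, is_seg


def site_heterozygosity(alt_count, c: int):
    """Unbiased per-site heterozygosity at uniform depth *c*."""
    k = np.asarray(alt_count, dtype=float)
    return 2.0 * k * (c - k) / (c * (c - 1.0))


@dataclass(frozen=True)
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajimas_constants(c: int) -> TajimaConstants:
    """Tajima (1989) normalising constants at sample size *c*."""
    if c < 2:
        raise ValueError("sample size must be >= 2")
    i = np.arange(1, c)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (c + 1.0) / (3.0 * (c - 1.0))
    b2 = 2.0 * (c**2 + c + 3.0) / (9.0 * c * (c - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (c + 2.0) / (a1 * c) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(alt_counts, c: int, min_sites: int = 3) -> float:
    """Tajima's D for a window of segregating-site allele counts at
    uniform depth *c*; NaN with fewer than *min_sites* sites or a
    non-positive variance estimate."""
    alt_counts = np.asarray(alt_counts)
    s = len(alt_counts)
    if s < min_sites:
        return np.nan
    k = tajimas_constants(c)
    pi_sum = site_heterozygosity(alt_counts, c).sum()
    theta_w = s / k.a1
    var = k.e1 * s + k.e2 * s * (s - 1.0)
    if var <= 0:
        warnings.warn("non-positive Tajima variance estimate; D missing")
        return np.nan
    return float((pi_sum - theta_w) / np.sqrt(var))


def windowed_stats(
    counts: PoolCountMatrix,
    pool_id: str,
    target_c: int | None = None,
    window: int = 10_000,
    step: int = 2_000,
    min_covered: float = 0.5,
    chrom_lengths: dict[str, int] | None = None,
    coverage_track: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window pi and Tajima's D for one pool.

    If *target_c* is None the 5% quantile of the pool's coverage is used.
    *coverage_track*, when given, maps chromosome -> per-position depth
    (1-based position p at index p-1) and defines the covered fraction of
    each window (positions with depth >= target C); without it the
    fraction of unmasked SNP sites in the window is used as a density
    proxy (1.0 for windows without sites), and pi is normalised by
    window_length * covered_fraction.
    """
    j = counts.pool_index([pool_id])[0]
    ref = counts.ref[:, j].copy()
    alt = counts.alt[:, j].copy()
    ref[counts.missing[:, j]] = 0
    alt[counts.missing[:, j]] = 0
    cov = ref + alt
    if target_c is None:
        target_c = max(4, int(np.percentile(cov[cov > 0], 5)))
    alt_sub, masked, is_seg = subsample_coverage(ref, alt, target_c, seed)

    chrom_arr = counts.snps["chrom"].to_numpy()
    pos_arr = counts.snps["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos = pos_arr[sel]
        sub = alt_sub[sel]
        msk = masked[sel]
        seg = is_seg[sel]
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(pos.max())
        )
        track = coverage_track.get(chrom) if coverage_track else None
        for start in range(1, max(2, length - window + 2), step):
            end = start + window - 1
            in_w = (pos >= start) & (pos <= end)
            if track is not None:
                seg_track = track[start - 1:end]
                covered = float((seg_track >= target_c).mean())
            else:
                n_sites = int(in_w.sum())
                covered = (
                    1.0 - msk[in_w].mean() if n_sites else 1.0
                )
            if covered < min_covered:
                pi = np.nan
                d = np.nan
            else:
                use = in_w & seg & ~msk
                h_sum = site_heterozygosity(sub[use], target_c).sum()
                pi = h_sum / (window * covered)
                d = tajimas_d(sub[use], target_c)
            rows.append((pool_id, chrom, start, end, pi, d, covered))
    return pd.DataFrame(
        rows,
        columns=["pool", "chrom", "start", "end", "pi", "tajimas_d",
                 "covered_frac"],
    )
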