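"""Genome scans of allele-frequency divergence between pool groups.

The divergence statistic is the delta allele frequency,

    dAF = | mean AF(group 1) - mean AF(group 2) |,

with unweighted pool means, complemented by a rolling mean over 100
consecutive SNPs that smooths single-SNP artefacts, a per-SNP chi-square
test on n_eff-rescaled allele counts with a Bonferroni threshold, and a
clustering rule that merges consecutive outlier SNPs into "islands of
divergence".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import PoolCountMatrix
from .intervals import GenomicInterval
from .poolfreq import AlleleFrequencyMatrix, allele_frequencies, rescale_counts


@dataclass(frozen=True)
class GroupContrast:
    """Two disjoint, nonempty groups of pool ids to compare."""

    name: str
    group1: tuple[str, ...]
    group2: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be nonempty")
        if set(self.group1) & set(self.group2):
            raise ValueError("groups must be disjoint")

    @classmethod
    def by_season(cls, pools, name="spring_vs_fall") -> "GroupContrast":
        g1 = tuple(p.id for p in pools if p.season == "spring")
        g2 = tuple(p.id for p in pools if p.season == "fall")
        return cls(name=name, group1=g1, group2=g2)

    def swapped(self) -> "GroupContrast":
        return GroupContrast(self.name, self.group2, self.group1)


@dataclass
class DafTrack:
    """Per-SNP dAF for one contrast, with smoothing and significance."""

    snps: pd.DataFrame
    daf: np.ndarray
    contrast: GroupContrast
    rolling: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    bonferroni_alpha: float | None = None
    bonferroni_flag: np.ndarray | None = None
    outlier_flag: np.ndarray | None = None
    daf_cutoff: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.snps[["chrom", "pos"]].copy()
        out["daf"] = self.daf
        if self.rolling is not None:
            out["rolling"] = self.rolling
        if self.pvalues is not None:
            out["p"] = self.pvalues
            out["bonferroni"] = self.bonferroni_flag
        if self.outlier_flag is not None:
            out["outlier"] = self.outlier_flag
        return out


def _group_cols(freqs: AlleleFrequencyMatrix, contrast: GroupContrast):
    lookup = {p: i for i, p in enumerate(freqs.pool_ids)}
    try:
        g1 = np.array([lookup[i] for i in contrast.group1])
        g2 = np.array([lookup[i] for i in contrast.group2])
    except KeyError as e:
        raise ValueError(f"contrast names unknown pool {e.args[0]!r}")
    return g1, g2


def daf_scan(freqs, contrast: GroupContrast) -> DafTrack:
    """Per-SNP |group-mean difference| of allele frequencies.

    Pool means are unweighted and pairwise-complete: a SNP needs at least
    one pool with data in each group, else its dAF is missing.
    """
    if isinstance(freqs, PoolCountMatrix):
        freqs = allele_frequencies(freqs)
    g1, g2 = _group_cols(freqs, contrast)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(freqs.freq[:, g1], axis=1)
        m2 = np.nanmean(freqs.freq[:, g2], axis=1)
    daf = np.abs(m1 - m2)
    return DafTrack(snps=freqs.snps.copy(), daf=daf, contrast=contrast)


def rolling_daf(
    track: DafTrack, window: int = 100, min_window: int = 50
) -> np.ndarray:
    """Centred rolling mean of dAF over *window* consecutive SNPs.

    Windows never span chromosomes; chromosome ends use shrunken windows
    of at least *min_window* SNPs, shorter stretches are missing.  The
    result is also stored on the track.
    """
    s = pd.Series(track.daf)
    out = np.full(len(s), np.nan)
    for _, idx in track.snps.groupby("chrom", sort=False).indices.items():
        out[idx] = (
            s.iloc[idx]
            .rolling(window, center=True, min_periods=min_window)
            .mean()
            .to_numpy()
        )
    track.rolling = out
    return out


def per_snp_test(
    counts: PoolCountMatrix, contrast: GroupContrast, alpha: float = 0.05
):
    """Two-sided chi-square test of equal group allele frequency per SNP.

    Rescaled (n_eff-unit) ref/alt counts are summed per group into a 2x2
    table and the Pearson chi-square statistic (1 df, no continuity
    correction) gives the p-value.  Returns (pvalues, bonferroni_level,
    min_daf_significant) where the last is the smallest dAF among
    Bonferroni-significant SNPs — the height analogue of a genome-wide
    significance line on a dAF scan.
    """
    freqs = allele_frequencies(counts)
    g1, g2 = _group_cols(freqs, contrast)
    ref_rs, alt_rs, _ = rescale_counts(counts)
    ref_rs = np.nan_to_num(ref_rs)
    alt_rs = np.nan_to_num(alt_rs)
    r1, a1 = ref_rs[:, g1].sum(1), alt_rs[:, g1].sum(1)
    r2, a2 = ref_rs[:, g2].sum(1), alt_rs[:, g2].sum(1)
    n1, n2 = r1 + a1, r2 + a2
    total = n1 + n2
    p_pool = np.where(total > 0, (a1 + a2) / np.where(total > 0, total, 1), np.nan)
    # Pearson chi-square for a 2x2 table, 1 df
    with np.errstate(invalid="ignore", divide="ignore"):
        var = p_pool * (1 - p_pool) * (1 / n1 + 1 / n2)
        chi2 = (a1 / n1 - a2 / n2) ** 2 / var
    ok = (n1 > 0) & (n2 > 0) & (p_pool > 0) & (p_pool < 1)
    pvalues = np.full(counts.n_snps, np.nan)
    pvalues[ok] = stats.chi2.sf(chi2[ok], df=1)
    # identical group frequencies give statistic 0 -> p = 1
    m_tested = int(ok.sum())
    bonf = alpha / m_tested if m_tested else np.nan
    sig = pvalues < bonf
    track = daf_scan(freqs, contrast)
    min_daf_sig = float(np.nanmin(track.daf[sig])) if sig.any() else np.nan
    return pvalues, bonf, min_daf_sig


def flag_outliers(track: DafTrack, daf_cutoff: float = 0.55) -> np.ndarray:
    """Flag SNPs with dAF at or above the cutoff (0.55 for novel outliers,
    0.4 for close-up tracks)."""
    with np.errstate(invalid="ignore"):
        flag = track.daf >= daf_cutoff
    track.outlier_flag = flag
    track.daf_cutoff = daf_cutoff
    return flag


@dataclass
class DivergentRegion:
    """A cluster of outlier SNPs reported as one island of divergence."""

    interval: GenomicInterval
    n_outliers: int
    mean_daf: float
    max_daf: float
    label: str = ""
    member_index: np.ndarray = field(default=None, repr=False)  # type: ignore


def detect_regions(
    track: DafTrack,
    daf_cutoff: float = 0.55,
    max_gap: int = 100_000,
    min_snps: int = 5,
) -> list[DivergentRegion]:
    """Cluster outlier SNPs into divergence islands.

    Consecutive outliers on the same chromosome separated by <= *max_gap*
    bp are merged; clusters with fewer than *min_snps* outliers are
    discarded.  The reported interval runs from the first to the last
    outlier of the cluster.  Regions come out sorted and non-overlapping.
    """
    if track.outlier_flag is None or track.daf_cutoff != daf_cutoff:
        flag_outliers(track, daf_cutoff)
    chrom = track.snps["chrom"].to_numpy()
    pos = track.snps["pos"].to_numpy()
    idx = np.nonzero(track.outlier_flag)[0]
    regions: list[DivergentRegion] = []
    if len(idx) == 0:
        return regions
    cluster = [idx[0]]
    for k in idx[1:]:
        prev = cluster[-1]
        if chrom[k] == chrom[prev] and pos[k] - pos[prev] <= max_gap:
            cluster.append(k)
        else:
            _close_cluster(regions, cluster, chrom, pos, track, min_snps)
            cluster = [k]
    _close_cluster(regions, cluster, chrom, pos, track, min_snps)
    for i, r in enumerate(regions):
        r.label = f"{track.contrast.name}_region{i + 1}"
    return regions


def _close_cluster(regions, cluster, chrom, pos, track, min_snps) -> None:
    if len(cluster) < min_snps:
        return
    members = np.array(cluster)
    vals = track.daf[members]
    regions.append(
        DivergentRegion(
            interval=GenomicInterval(
                chrom[members[0]], int(pos[members[0]]), int(pos[members[-1]])
            ),
            n_outliers=len(members),
            mean_daf=float(vals.mean()),
            max_daf=float(vals.max()),
            member_index=members,
        )
    )


def regions_to_frame(regions: list[DivergentRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "n_outliers": [r.n_outliers for r in regions],
            "mean_daf": [r.mean_daf for r in regions],
            "max_daf": [r.max_daf for r in regions],
            "label": [r.label for r in regions],
        }
    )
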