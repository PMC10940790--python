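"""Structural-variant analysis from individual genotypes.

Given high-coverage individual genotypes around a putative inversion,
this module (i) calls each individual's karyotype (AA/AB/BB) from the
dominant axis of genotypic variation, (ii) computes genotype-correlation
LD (R^2) aggregated in 5-kb windows across the region and +/- 1 Mbp
flanks, for all individuals and within homozygote classes, and (iii)
classifies SNPs as shared (polymorphic within both haplotype classes) or
diagnostic (near-fixed difference), whose ratio measures gene flux
between the arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples, silhouette_score

from .dataio import GenotypeMatrix
from .intervals import GenomicInterval

KARYOTYPES = ("AA", "AB", "BB")


@dataclass
class KaryotypeCall:
    individual: str
    region: GenomicInterval | None
    call: str
    confidence: float
    low_confidence: bool


def _dosage_matrix(genos) -> np.ndarray:
    """Individuals x SNPs float dosages with row-mean imputation."""
    if isinstance(genos, GenotypeMatrix):
        g = genos.genotypes.T.astype(float)
    else:
        g = np.asarray(genos, dtype=float)
    g = g.copy()
    g[g < 0] = np.nan
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.nan_to_num(col_mean)
    nan = np.isnan(g)
    g[nan] = np.take(col_mean, np.nonzero(nan)[1])
    return g


class KaryotypeCaller(BaseEstimator):
    """Cluster individuals into the three karyotypes of a structural
    variant.

    Individuals are projected on the first principal component of the
    region's genotype dosages and clustered with k-means (k=3); the
    middle cluster is labelled AB and orientation is fixed so that AA is
    the cluster with the lower mean alt dosage.  Per-individual
    confidence is the silhouette score on PC1; if three distinguishable
    clusters cannot be formed (an empty cluster, or mean silhouette below
    *min_silhouette* — k-means on unstructured 1-D data plateaus near 0.6,
    true karyotype clusters exceed 0.9) every call is flagged
    low-confidence.
    """

    def __init__(
        self,
        min_snps: int = 10,
        min_silhouette: float = 0.7,
        random_state: int = 0,
    ):
        self.min_snps = min_snps
        self.min_silhouette = min_silhouette
        self.random_state = random_state

    def fit(self, genos, y=None):
        X = _dosage_matrix(genos)
        if X.shape[1] < self.min_snps:
            raise ValueError(
                f"need >= {self.min_snps} SNPs in region, got {X.shape[1]}"
            )
        pc1 = PCA(n_components=1).fit_transform(X)
        km = KMeans(n_clusters=3, n_init=10, random_state=self.random_state)
        raw = km.fit_predict(pc1)
        # orient clusters by mean alt dosage: AA lowest, BB highest
        mean_dose = np.array(
            [
                X[raw == c].mean() if (raw == c).any() else np.nan
                for c in range(3)
            ]
        )
        order = np.argsort(mean_dose)
        relabel = np.empty(3, dtype=int)
        relabel[order] = np.arange(3)
        labels = relabel[raw]
        self.labels_ = np.array(KARYOTYPES, dtype=object)[labels]
        counts = np.bincount(labels, minlength=3)
        degenerate = (counts == 0).any()
        if degenerate:
            self.confidence_ = np.zeros(len(labels))
            self.mean_silhouette_ = 0.0
        else:
            self.confidence_ = silhouette_samples(pc1, labels)
            self.mean_silhouette_ = float(silhouette_score(pc1, labels))
        self.low_confidence_ = bool(
            degenerate or self.mean_silhouette_ < self.min_silhouette
        )
        self.pc1_ = pc1[:, 0]
        return self

    def predict(self, genos=None):
        return self.labels_


def call_karyotypes(
    genos: GenotypeMatrix, region: GenomicInterval, **kwargs
) -> list[KaryotypeCall]:
    """Karyotype every individual for the SV in *region*."""
    sub = genos.subset_region(region)
    caller = KaryotypeCaller(**kwargs).fit(sub)
    return [
        KaryotypeCall(
            individual=ind,
            region=region,
            call=str(caller.labels_[i]),
            confidence=float(caller.confidence_[i]),
            low_confidence=caller.low_confidence_,
        )
        for i, ind in enumerate(genos.individuals)
    ]


@dataclass
class LdWindowMatrix:
    """Mean R^2 between 5-kb windows, long format, for one subset."""

    table: pd.DataFrame  # columns bin_i, bin_j, mean_r2, n_pairs
    subset: str
    bin_size: int


def ld_matrix(
    genos: GenotypeMatrix,
    region: GenomicInterval,
    flank: int = 1_000_000,
    bin_size: int = 5_000,
    subset: str = "all",
    karyotypes: dict[str, str] | None = None,
) -> LdWindowMatrix:
    """Genotype-correlation LD (R^2) binned in *bin_size* windows over the
    region and its flanks.

    *subset* is 'all', 'AA' or 'BB'; homozygote subsets require a
    *karyotypes* mapping individual -> call.  Monomorphic SNPs within the
    subset are excluded.
    """
    if subset not in ("all", "AA", "BB"):
        raise ValueError("subset must be all, AA or BB")
    wide = GenomicInterval(
        region.chrom, max(1, region.start - flank), region.end + flank
    )
    sub = genos.subset_region(wide)
    cols = np.arange(len(genos.individuals))
    if subset != "all":
        if karyotypes is None:
            raise ValueError("homozygote subsets need karyotype calls")
        cols = np.array(
            [
                i
                for i, ind in enumerate(genos.individuals)
                if karyotypes.get(ind) == subset
            ]
        )
        if len(cols) < 2:
            raise ValueError(f"fewer than 2 individuals with karyotype {subset}")
    g = _dosage_matrix(sub)[cols]  # individuals x snps
    poly = g.std(axis=0) > 0
    g = g[:, poly]
    pos = sub.snps["pos"].to_numpy()[poly]
    if g.shape[1] < 2:
        raise ValueError("fewer than 2 polymorphic SNPs in region")
    r = np.corrcoef(g.T)
    r2 = r**2
    bins = pos // bin_size * bin_size
    iu = np.triu_indices(len(pos), k=1)
    df = pd.DataFrame(
        {"bin_i": bins[iu[0]], "bin_j": bins[iu[1]], "r2": r2[iu]}
    )
    agg = (
        df.groupby(["bin_i", "bin_j"])["r2"]
        .agg(mean_r2="mean", n_pairs="size")
        .reset_index()
    )
    return LdWindowMatrix(table=agg, subset=subset, bin_size=bin_size)


def mean_r2_within(ld: LdWindowMatrix, region: GenomicInterval) -> float:
    """Mean R^2 over window pairs lying entirely inside *region*."""
    t = ld.table
    inside = (
        (t["bin_i"] >= region.start)
        & (t["bin_j"] >= region.start)
        & (t["bin_i"] + ld.bin_size - 1 <= region.end)
        & (t["bin_j"] + ld.bin_size - 1 <= region.end)
    )
    sel = t[inside]
    if sel.empty:
        return np.nan
    return float(
        (sel["mean_r2"] * sel["n_pairs"]).sum() / sel["n_pairs"].sum()
    )


def classify_snps(
    genos: GenotypeMatrix,
    aa_individuals: list[str],
    bb_individuals: list[str],
    thresholds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Classify SNPs as shared / diagnostic / other from within-group
    allele frequencies of the two homozygote classes.

    shared: frequency within [lo, hi] in both groups; diagnostic:
    > hi in one group and < lo in the other; other: the rest.  SNPs
    missing in either group are excluded.
    """
    if len(aa_individuals) < 2 or len(bb_individuals) < 2:
        raise ValueError("both homozygote groups need >= 2 individuals")
    lo, hi = thresholds
    idx = {ind: i for i, ind in enumerate(genos.individuals)}
    a_cols = np.array([idx[i] for i in aa_individuals])
    b_cols = np.array([idx[i] for i in bb_individuals])

    def group_freq(cols):
        g = genos.genotypes[:, cols].astype(float)
        g[g < 0] = np.nan
        n = (~np.isnan(g)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.nansum(g, axis=1) / (2.0 * n), n

    fa, na = group_freq(a_cols)
    fb, nb = group_freq(b_cols)
    ok = (na > 0) & (nb > 0)
    shared = ok & (fa >= lo) & (fa <= hi) & (fb >= lo) & (fb <= hi)
    diagnostic = ok & (
        ((fa > hi) & (fb < lo)) | ((fb > hi) & (fa < lo))
    )
    other = ok & ~shared & ~diagnostic
    out = genos.snps[["chrom", "pos"]].copy()
    out["freq_aa"] = fa
    out["freq_bb"] = fb
    out["klass"] = np.select(
        [shared, diagnostic, other], ["shared", "diagnostic", "other"],
        default="excluded",
    )
    return out


def allele_sharing(
    genos: GenotypeMatrix,
    aa_individuals: list[str],
    bb_individuals: list[str],
    region: GenomicInterval,
    window: int = 10_000,
    thresholds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Shared/diagnostic/other SNP counts per *window*-bp window in
    *region* (one row per window containing classified SNPs)."""
    sub = genos.subset_region(region)
    cls = classify_snps(sub, aa_individuals, bb_individuals, thresholds)
    cls = cls[cls["klass"] != "excluded"]
    start = (cls["pos"] - region.start) // window * window + region.start
    tab = (
        cls.assign(win_start=start)
        .groupby("win_start")["klass"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["shared", "diagnostic", "other"], fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    tab = tab.rename(
        columns={
            "shared": "n_shared",
            "diagnostic": "n_diagnostic",
            "other": "n_other",
        }
    )
    tab.insert(0, "chrom", region.chrom)
    tab["win_end"] = tab["win_start"] + window - 1
    return tab[
        ["chrom", "win_start", "win_end", "n_shared", "n_diagnostic", "n_other"]
    ]


def gene_flux_summary(windows: pd.DataFrame) -> dict:
    """Region-level shared fraction shared/(shared+diagnostic), overall
    and per window (NaN where a window classifies no shared or diagnostic
    SNP)."""
    if windows.empty:
        raise ValueError("no sharing windows")
    s = windows["n_shared"].sum()
    d = windows["n_diagnostic"].sum()
    overall = np.nan if (s + d) == 0 else s / (s + d)
    denom = windows["n_shared"] + windows["n_diagnostic"]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_window = np.where(
            denom > 0, windows["n_shared"] / denom, np.nan
        )
    return {
        "shared_fraction": float(overall) if overall == overall else np.nan,
        "n_shared": int(s),
        "n_diagnostic": int(d),
        "per_window": per_window,
    }
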