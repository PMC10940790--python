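"""Population structure from pooled data: pairwise FST and PCA.

The FST estimator is a Weir-Cockerham-type analysis of variance on allele
frequencies with the per-SNP haploid sample size replaced by the
effective sample size n_eff, so that both levels of pool-seq sampling
(chromosomes into the pool, reads from the pool) are charged to the
within-population mean square.  Multi-locus estimates are ratios of sums
of the per-locus variance components, and may legitimately be slightly
negative under no differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .dataio import PoolCountMatrix
from .poolfreq import AlleleFrequencyMatrix, allele_frequencies


def _wc_components(p1, p2, n1, n2):
    """Per-SNP Weir-Cockerham numerator/denominator for two samples of
    haploid-equivalent sizes n1, n2 and frequencies p1, p2."""
    n_sum = n1 + n2
    n_c = n_sum - (n1 * n1 + n2 * n2) / n_sum  # (r-1)=1 divisor folded in
    p_bar = (n1 * p1 + n2 * p2) / n_sum
    msp = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_sum - 2)
    num = msp - msg
    den = msp + (n_c - 1) * msg
    return num, den


def pairwise_fst(counts: PoolCountMatrix, pair) -> float:
    """Multi-locus FST estimate between two pools (ids or column indices).

    SNPs missing in either pool are excluded pairwise; the estimate is the
    ratio of summed numerator and denominator components over the
    remaining SNPs.
    """
    i, j = (
        counts.pool_index(pair)
        if isinstance(pair[0], str)
        else np.asarray(pair, dtype=int)
    )
    freqs = allele_frequencies(counts)
    return _pair_fst_from_freqs(freqs, i, j)


def _pair_fst_from_freqs(freqs: AlleleFrequencyMatrix, i: int, j: int) -> float:
    ok = ~(freqs.missing[:, i] | freqs.missing[:, j])
    if not ok.any():
        raise ValueError(
            f"pools {freqs.pool_ids[i]!r} and {freqs.pool_ids[j]!r} share "
            "no SNPs with data"
        )
    p1, p2 = freqs.freq[ok, i], freqs.freq[ok, j]
    n1, n2 = freqs.n_eff[ok, i], freqs.n_eff[ok, j]
    num, den = _wc_components(p1, p2, n1, n2)
    den_sum = den.sum()
    if den_sum == 0:
        return 0.0
    return float(num.sum() / den_sum)


@dataclass
class FstMatrix:
    """Symmetric pools x pools matrix of pairwise FST with SNP counts."""

    values: np.ndarray
    n_snps: np.ndarray
    pool_ids: list[str]

    def to_frame(self, floor_zero: bool = False) -> pd.DataFrame:
        v = np.maximum(self.values, 0.0) if floor_zero else self.values
        return pd.DataFrame(v, index=self.pool_ids, columns=self.pool_ids)

    def mean_offdiag(self) -> float:
        n = len(self.pool_ids)
        iu = np.triu_indices(n, k=1)
        return float(self.values[iu].mean())


def fst_matrix(counts: PoolCountMatrix) -> FstMatrix:
    """All pairwise FST estimates (diagonal 0)."""
    freqs = allele_frequencies(counts)
    n = freqs.n_pools
    values = np.zeros((n, n))
    n_snps = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(freqs.missing[:, i] | freqs.missing[:, j])
            n_snps[i, j] = n_snps[j, i] = int(ok.sum())
            est = _pair_fst_from_freqs(freqs, i, j)
            values[i, j] = values[j, i] = est
    return FstMatrix(values=values, n_snps=n_snps, pool_ids=freqs.pool_ids)


class PoolPCA(BaseEstimator, TransformerMixin):
    """PCA of pool allele frequencies (pools as observations, SNPs as
    features).

    Missing cells are mean-imputed per SNP; SNPs are centred but not
    scaled to unit variance.  Variance fractions are eigenvalue shares of
    the total variance, reported in percent.

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : (n_pools, k) pool coordinates on the PCs.
    explained_variance_pct_ : per-PC variance fraction in percent.
    loadings_ : (k, n_snps) SNP loadings.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    @staticmethod
    def _as_matrix(freqs) -> np.ndarray:
        if isinstance(freqs, AlleleFrequencyMatrix):
            return freqs.freq.T.copy()  # pools x SNPs
        return np.asarray(freqs, dtype=float).copy()

    def fit(self, freqs, y=None):
        X = self._as_matrix(freqs)
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need >= 2 pools and >= 2 SNPs")
        col_mean = np.nanmean(X, axis=0)
        nan = np.isnan(X)
        X[nan] = np.take(col_mean, np.nonzero(nan)[1])
        k = self.n_components or min(X.shape[0] - 1, 10)
        k = min(k, X.shape[0] - 1, X.shape[1])
        total_var = np.var(X, axis=0, ddof=1).sum()
        if total_var == 0:
            warnings.warn("constant frequency matrix; variance fractions 0")
            self.scores_ = np.zeros((X.shape[0], k))
            self.explained_variance_pct_ = np.zeros(k)
            self.loadings_ = np.zeros((k, X.shape[1]))
            self._pca = None
            return self
        self._pca = PCA(n_components=k, svd_solver="full")
        self.scores_ = self._pca.fit_transform(X)
        self.explained_variance_pct_ = 100.0 * self._pca.explained_variance_ratio_
        self.loadings_ = self._pca.components_
        return self

    def transform(self, freqs):
        X = self._as_matrix(freqs)
        if self._pca is None:
            return np.zeros((X.shape[0], self.loadings_.shape[0]))
        col_mean = self._pca.mean_
        nan = np.isnan(X)
        X[nan] = np.take(col_mean, np.nonzero(nan)[1])
        return self._pca.transform(X)

    def fit_transform(self, freqs, y=None):
        return self.fit(freqs).scores_


def pca(freqs, n_components: int | None = None) -> PoolPCA:
    """Functional wrapper: fit a :class:`PoolPCA` and return it."""
    return PoolPCA(n_components=n_components).fit(freqs)


def group_separation(scores: np.ndarray, labels) -> float:
    """Between/within distance ratio of PC scores for two or more groups.

    Mean pairwise distance between points in different groups divided by
    the mean pairwise distance within groups; larger means cleaner
    separation.
    """
    labels = np.asarray(labels)
    d = np.sqrt(
        ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(-1)
    )
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = d[iu][same[iu]]
    between = d[iu][~same[iu]]
    if len(within) == 0 or within.mean() == 0:
        return np.inf
    return float(between.mean() / within.mean())
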