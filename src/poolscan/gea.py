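"""Genome-environment association by redundancy analysis (RDA).

The response is the pools x SNPs matrix of allele frequencies at outlier
loci; the predictors are standardised environmental variables pruned for
collinearity (pairwise |r| < 0.7 and all VIF < 5).  RDA regresses the
centred response on the predictors and eigen-decomposes the fitted
values: constrained axes order the environmental structure in the
frequencies, and the constrained eigenvalue share of the total variance
measures how much of the genetic variance the environment explains.
Significance is assessed by permuting pools across environments
(pseudo-F; overall and marginal per-variable tests), and variables can be
confirmed by bidirectional stepwise selection with permutation entry/exit
criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from sklearn.base import BaseEstimator
from statsmodels.stats.outliers_influence import variance_inflation_factor


def standardize_env(env: pd.DataFrame) -> pd.DataFrame:
    """Zero-mean, unit-variance (n-1 denominator) scaling per variable;
    zero-variance variables are dropped with a warning."""
    if len(env) < 2:
        raise ValueError("need >= 2 pools")
    out = {}
    for col in env.columns:
        x = env[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            warnings.warn(f"dropping zero-variance variable {col!r}")
            continue
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=env.index)


@dataclass
class EnvPruneReport:
    """Audit trail of collinearity pruning."""

    correlation: pd.DataFrame
    removed: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed)


def _vif_table(X: pd.DataFrame) -> pd.Series:
    Z = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    vals = [
        variance_inflation_factor(Z, j + 1) for j in range(X.shape[1])
    ]
    return pd.Series(vals, index=X.columns)


def prune_collinear(
    env: pd.DataFrame, r_cut: float = 0.7, vif_cut: float = 5.0
) -> EnvPruneReport:
    """Two-stage collinearity pruning of a standardised env table.

    Stage 1: while any pair has |r| >= *r_cut*, remove from the worst pair
    the member with the larger mean |r| to all other variables (ties by
    name order).  Stage 2: iteratively drop the variable with the highest
    VIF until all VIF < *vif_cut*.  Every removal is logged.
    """
    report = EnvPruneReport(correlation=env.corr())
    cols = list(env.columns)
    # stage 1: pairwise correlation
    while len(cols) >= 2:
        corr = env[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.values.max()
        if max_r < r_cut:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        pair = sorted([cols[i], cols[j]])
        mean_r = corr.mean(axis=1)
        # drop the member with larger mean |r|; ties resolved by name order
        if mean_r[pair[0]] > mean_r[pair[1]]:
            drop = pair[0]
        else:
            drop = pair[1]
        report.removed.append(
            {"variable": drop, "stage": "pairwise_r", "value": float(max_r)}
        )
        cols.remove(drop)
    # stage 2: VIF
    while len(cols) >= 2:
        vif = _vif_table(env[cols])
        worst = vif.max()
        if worst < vif_cut:
            break
        drop = sorted(vif.index[vif == worst])[0]
        report.removed.append(
            {"variable": drop, "stage": "vif", "value": float(worst)}
        )
        cols.remove(drop)
    if len(cols) < 2:
        warnings.warn("fewer than 2 variables remain after pruning")
    report.retained = cols
    return report


def _as_xy(X, Y):
    names = (
        list(X.columns)
        if isinstance(X, pd.DataFrame)
        else [f"x{j}" for j in range(np.asarray(X).shape[1])]
    )
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, Y, names


class RDA(BaseEstimator):
    """Redundancy analysis: constrained ordination of allele frequencies
    on environmental predictors.

    Parameters
    ----------
    n_axes : number of constrained axes to keep (default: all).

    Attributes (after :meth:`fit`)
    ------------------------------
    scores_ : (n_pools, k) pool scores on constrained axes.
    axis_variance_pct_ : per-axis share of the *total* variance, percent.
    constrained_pct_ : total constrained share of variance, percent.
    biplot_scores_ : DataFrame, correlation of each predictor with each
        constrained axis (arrow coordinates).
    pseudo_f_ : overall pseudo-F statistic.
    """

    def __init__(self, n_axes: int | None = None):
        self.n_axes = n_axes

    def fit(self, X, Y):
        X, Y, names = _as_xy(X, Y)
        n, q = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if n < q + 2:
            raise ValueError(f"need >= {q + 2} pools for {q} predictors")
        rank = np.linalg.matrix_rank(X - X.mean(0))
        if rank < q:
            _, _, piv = scipy_qr(X - X.mean(0), pivoting=True)
            dep = [names[j] for j in piv[rank:]]
            raise ValueError(f"rank-deficient predictors; dependent: {dep}")
        self.var_names_ = names
        self._Xc = X - X.mean(0)
        self._Yc = Y - Y.mean(0)
        self._Q, _ = np.linalg.qr(self._Xc)
        proj = self._Q.T @ self._Yc
        Yhat = self._Q @ proj

        total_ss = float((self._Yc**2).sum())
        fitted_ss = float((Yhat**2).sum())
        self.total_ss_ = total_ss
        self.constrained_ss_ = fitted_ss
        self.residual_ss_ = total_ss - fitted_ss
        self.constrained_pct_ = (
            100.0 * fitted_ss / total_ss if total_ss > 0 else 0.0
        )
        df_c, df_r = q, n - q - 1
        self.df_ = (df_c, df_r)
        self.pseudo_f_ = (
            (fitted_ss / df_c) / (self.residual_ss_ / df_r)
            if self.residual_ss_ > 0 and df_r > 0
            else np.inf
        )

        u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
        k = self.n_axes or min(q, n - 1)
        k = min(k, (s > 1e-12 * max(s[0], 1)).sum()) or 1
        self.singular_values_ = s[:k]
        self.scores_ = u[:, :k] * s[:k]
        self.snp_loadings_ = vt[:k]
        self.axis_variance_pct_ = 100.0 * s[:k] ** 2 / total_ss
        with np.errstate(invalid="ignore", divide="ignore"):
            bip = np.array(
                [
                    [
                        np.corrcoef(self._Xc[:, j], self.scores_[:, a])[0, 1]
                        if self.scores_[:, a].std() > 0
                        else 0.0
                        for a in range(k)
                    ]
                    for j in range(q)
                ]
            )
        self.biplot_scores_ = pd.DataFrame(
            bip, index=names, columns=[f"RDA{a + 1}" for a in range(k)]
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        # project new predictor rows onto the constrained axes
        B = np.linalg.lstsq(self._Xc, self.scores_, rcond=None)[0]
        return (X - X.mean(0)) @ B


def rda_fit(freqs, env, n_axes: int | None = None) -> RDA:
    """Functional wrapper: fit an :class:`RDA` of pools x SNPs *freqs* on
    *env* and return it."""
    return RDA(n_axes=n_axes).fit(env, freqs)


def _constrained_ss(Q: np.ndarray, Yc: np.ndarray) -> float:
    return float(((Q.T @ Yc) ** 2).sum())


def permutation_anova(
    model: RDA, nperm: int = 9999, seed: int = 0
) -> dict:
    """Permutation ANOVA of a fitted RDA.

    The overall test permutes the rows of the predictor matrix and
    recomputes the pseudo-F; p = (1 + #{F_perm >= F_obs}) / (nperm + 1).
    Per-variable (marginal, type-III-like) tests permute one variable's
    component orthogonal to the others, holding the rest fixed.
    """
    if nperm < 99:
        warnings.warn("nperm < 99 gives a very coarse permutation p-value")
    rng = np.random.default_rng(seed)
    Xc, Yc = model._Xc, model._Yc
    n, q = Xc.shape
    df_c, df_r = model.df_
    total_ss = model.total_ss_

    f_obs = model.pseudo_f_
    count = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        Qp, _ = np.linalg.qr(Xc[perm])
        ss_c = _constrained_ss(Qp, Yc)
        ss_r = total_ss - ss_c
        f = (ss_c / df_c) / (ss_r / df_r) if ss_r > 0 else np.inf
        if f >= f_obs:
            count += 1
    overall_p = (1 + count) / (nperm + 1)

    term_p = {}
    term_f = {}
    for j in range(q):
        f_obs_j, f_perm_j = _marginal_f(Xc, Yc, j, nperm, rng, df_r)
        term_f[model.var_names_[j]] = f_obs_j
        term_p[model.var_names_[j]] = (
            1 + int((f_perm_j >= f_obs_j).sum())
        ) / (nperm + 1)
    return {
        "overall_p": overall_p,
        "overall_f": f_obs,
        "term_p": term_p,
        "term_f": term_f,
        "nperm": nperm,
    }


def _marginal_f(Xc, Yc, j, nperm, rng, df_r):
    """Observed and permuted marginal pseudo-F for predictor *j* given the
    others (residual permutation of x_j, others held fixed)."""
    n, q = Xc.shape
    others = np.delete(np.arange(q), j)
    if len(others):
        Qo, _ = np.linalg.qr(Xc[:, others])
        resid = lambda M: M - Qo @ (Qo.T @ M)
    else:
        resid = lambda M: M - M.mean(0)
    Yr = resid(Yc)
    rss_reduced = float((Yr**2).sum())
    e = resid(Xc[:, [j]])

    def added_ss(evec):
        nrm = float((evec**2).sum())
        if nrm <= 0:
            return 0.0
        return float(((Yr.T @ evec) ** 2).sum() / nrm)

    ss_obs = added_ss(e)
    f_obs = (ss_obs / 1.0) / ((rss_reduced - ss_obs) / df_r)

    perms = np.array([rng.permutation(n) for _ in range(nperm)])
    E = e[perms[:, :], 0].T  # n x nperm
    E = resid(E)
    nrm = (E**2).sum(0)
    C = Yr.T @ E
    ss_perm = np.where(nrm > 0, (C**2).sum(0) / np.where(nrm > 0, nrm, 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ss_perm / ((rss_reduced - ss_perm) / df_r)
    return f_obs, f_perm


def stepwise_select(
    freqs,
    env: pd.DataFrame,
    iterations: int = 1000,
    p_enter: float = 0.05,
    p_exit: float = 0.1,
    seed: int = 0,
    max_steps: int = 50,
) -> list[str]:
    """Bidirectional stepwise selection of environmental variables.

    Forward steps add the candidate with the smallest marginal permutation
    p-value if it is below *p_enter*; backward steps drop the selected
    variable with the largest marginal p-value if it exceeds *p_exit*.
    *iterations* is the number of permutations per test.  Deterministic
    under a fixed seed.
    """
    Y = np.asarray(freqs, dtype=float)
    Yc = Y - Y.mean(0)
    n = Yc.shape[0]
    names = list(env.columns)
    X = env.to_numpy(dtype=float)
    Xc = X - X.mean(0)
    selected: list[str] = []
    rng = np.random.default_rng(seed)
    for _ in range(max_steps):
        changed = False
        # forward
        candidates = [v for v in names if v not in selected]
        best = None
        for v in candidates:
            cols = [names.index(u) for u in selected + [v]]
            Xs = Xc[:, cols]
            df_r = n - Xs.shape[1] - 1
            if df_r < 1:
                continue
            f_obs, f_perm = _marginal_f(
                Xs, Yc, Xs.shape[1] - 1, iterations, rng, df_r
            )
            p = (1 + int((f_perm >= f_obs).sum())) / (iterations + 1)
            if best is None or p < best[1] or (p == best[1] and f_obs > best[2]):
                best = (v, p, f_obs)
        if best is not None and best[1] < p_enter:
            selected.append(best[0])
            changed = True
        # backward
        if len(selected) > 1:
            worst = None
            cols = [names.index(u) for u in selected]
            Xs = Xc[:, cols]
            df_r = n - Xs.shape[1] - 1
            for k, v in enumerate(selected):
                f_obs, f_perm = _marginal_f(Xs, Yc, k, iterations, rng, df_r)
                p = (1 + int((f_perm >= f_obs).sum())) / (iterations + 1)
                if worst is None or p > worst[1]:
                    worst = (v, p)
            if worst is not None and worst[1] > p_exit:
                selected.remove(worst[0])
                changed = True
        if not changed:
            break
    return selected


def rda_to_tables(model: RDA, anova: dict | None = None) -> dict:
    """Serialise an RDA result to plain tables/JSON-able values."""
    out = {
        "axis_variance_pct": [float(v) for v in model.axis_variance_pct_],
        "constrained_pct": float(model.constrained_pct_),
        "pseudo_f": float(model.pseudo_f_),
        "biplot": model.biplot_scores_.to_dict(),
        "scores": pd.DataFrame(
            model.scores_,
            columns=[f"RDA{a + 1}" for a in range(model.scores_.shape[1])],
        ).to_dict(orient="list"),
    }
    if anova:
        out["overall_p"] = anova["overall_p"]
        out["term_p"] = anova["term_p"]
    return out
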