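"""Phylogenetic comparative statistics.

Implements the comparative toolkit used to relate species traits to climate
on a phylogeny:

* Blomberg's K with a tip-shuffling permutation test;
* Pagel's lambda by profile maximum likelihood with a likelihood-ratio test
  against lambda = 0;
* phylogenetic generalized least squares (PGLS) with ML or fixed lambda,
  exposed as a statsmodels-style model (:class:`PGLS`) returning a results
  object with coefficient table, GLS R^2, residuals and Cook's distances on
  the whitened regression;
* climate PCA with fixed orientation conventions, Pearson correlation,
  Bonferroni correction and a loess smoother supporting span > 1.

The phylogenetic covariance convention is ``V(lambda)``: shared root-to-MRCA
path lengths off the diagonal scaled by lambda, root-to-tip depths on the
diagonal (see :func:`hydrophylo.trees.phylo_covariance`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .trees import phylo_covariance, tip_labels

__all__ = [
    "blomberg_k",
    "signal_permutation_test",
    "PagelLambda",
    "PagelLambdaResults",
    "phylo_signal",
    "PhyloSignalResult",
    "PGLS",
    "PGLSResults",
    "cooks_distance",
    "climate_pca",
    "ClimatePCA",
    "pearson_correlation",
    "bonferroni",
    "loess_smooth",
]

CLIMATE_VARS = ["MAT", "MAP", "maxT", "minT", "Pdq"]


# ---------------------------------------------------------------------------
# helpers

def _trait_vector(tree: dendropy.Tree, trait: Mapping[str, float]) -> tuple[np.ndarray, list[str]]:
    labels = tip_labels(tree)
    missing = [t for t in labels if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    y = np.asarray([float(trait[t]) for t in labels])
    if np.ptp(y) == 0:
        raise ValueError("trait is constant across tips; signal statistics undefined")
    return y, labels


def _k_quadratic_forms(V: np.ndarray):
    """Precompute the pieces of Blomberg's K that depend only on the tree."""
    n = V.shape[0]
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    s = ones @ Vinv @ ones
    w = (Vinv @ ones) / s                      # GLS weights for the ancestral mean
    expected = (np.trace(V) - n / s) / (n - 1)  # E[MSE0/MSE] under BM
    return Vinv, w, expected


def _k_from_forms(y: np.ndarray, Vinv: np.ndarray, w: np.ndarray, expected: float) -> float:
    a = w @ y
    r = y - a
    mse0 = r @ r
    mse = r @ Vinv @ r
    return float((mse0 / mse) / expected)


# ---------------------------------------------------------------------------
# Blomberg's K

def blomberg_k(tree: dendropy.Tree, trait: Mapping[str, float]) -> float:
    """Blomberg's K for one continuous trait.

    K = (MSE0/MSE) / E[MSE0/MSE] with the phylogenetically corrected mean
    a = (1'V^-1 1)^-1 1'V^-1 y, MSE0 the tip variance around a, MSE the
    V-weighted mean square, and the expectation term
    (tr V - n / 1'V^-1 1)/(n-1) evaluated at V = V(lambda=1).  K is about 1
    for traits evolved by Brownian motion on the tree and falls toward 0 as
    relatives resemble each other less than BM predicts.
    """
    y, labels = _trait_vector(tree, trait)
    V, _ = phylo_covariance(tree, 1.0, order=labels)
    Vinv, w, expected = _k_quadratic_forms(V)
    return _k_from_forms(y, Vinv, w, expected)


def signal_permutation_test(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test for Blomberg's K by shuffling trait values across tips.

    Returns ``(k_obs, p)`` with ``p = (1 + #{K_perm >= K_obs}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    y, labels = _trait_vector(tree, trait)
    V, _ = phylo_covariance(tree, 1.0, order=labels)
    Vinv, w, expected = _k_quadratic_forms(V)
    k_obs = _k_from_forms(y, Vinv, w, expected)
    rng = np.random.default_rng(seed)
    # vectorised: each column of Y is one permuted trait vector
    perms = np.argsort(rng.random((n_perm, y.size)), axis=1)
    Y = y[perms].T                                # (n_tips, n_perm)
    A = w @ Y
    R = Y - A[None, :]
    mse0 = np.einsum("ij,ij->j", R, R)
    mse = np.einsum("ij,ij->j", R, Vinv @ R)
    k_perm = (mse0 / mse) / expected
    p = (1.0 + np.sum(k_perm >= k_obs)) / (n_perm + 1.0)
    return k_obs, float(p)


# ---------------------------------------------------------------------------
# Pagel's lambda

def _profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """Log-likelihood of single-mean BM with covariance sigma^2 V, with the
    mean and sigma^2 profiled out analytically."""
    n = y.size
    c, low = linalg.cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_y = linalg.cho_solve((c, low), y)
    Vinv_1 = linalg.cho_solve((c, low), np.ones(n))
    a = (np.ones(n) @ Vinv_y) / (np.ones(n) @ Vinv_1)
    r = y - a
    rss = r @ linalg.cho_solve((c, low), r)
    sigma2 = rss / n
    return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n)


@dataclass
class PagelLambdaResults:
    """ML estimate of Pagel's lambda with the LRT against lambda = 0."""
    lambda_: float
    loglik: float
    loglik_zero: float
    lrt_pvalue: float

    def summary(self) -> str:
        return (
            "Pagel's lambda (profile ML)\n"
            f"  lambda_hat   {self.lambda_:.6f}\n"
            f"  logL(lambda) {self.loglik:.4f}\n"
            f"  logL(0)      {self.loglik_zero:.4f}\n"
            f"  LRT p (chi2_1) {self.lrt_pvalue:.4g}\n"
        )


class PagelLambda:
    """Single-trait Pagel's lambda model on a tree.

    ``PagelLambda(tree, trait).fit()`` maximises the profile likelihood of a
    single-mean Brownian model with covariance sigma^2 V(lambda) over
    lambda in [0, 1] (mean and sigma^2 profiled analytically) and reports a
    chi2_1 likelihood-ratio test of lambda_hat against lambda = 0.  The chi2_1
    reference is conservative at the lambda = 0 boundary.
    """

    def __init__(self, tree: dendropy.Tree, trait: Mapping[str, float]):
        self.y, self.labels = _trait_vector(tree, trait)
        self.tree = tree
        self._V1, _ = phylo_covariance(tree, 1.0, order=self.labels)
        self._D = np.diag(np.diag(self._V1))

    def _V(self, lam: float) -> np.ndarray:
        return lam * self._V1 + (1.0 - lam) * self._D

    def loglik(self, lam: float) -> float:
        return _profile_loglik(self.y, self._V(lam))

    def fit(self, xtol: float = 1e-6) -> PagelLambdaResults:
        res = optimize.minimize_scalar(
            lambda lam: -self.loglik(lam), bounds=(0.0, 1.0),
            method="bounded", options={"xatol": xtol})
        if not res.success:
            raise RuntimeError(f"lambda optimisation failed: {res.message}")
        lam = float(res.x)
        ll_hat = -float(res.fun)
        # the bounded optimiser can sit just inside the boundary; check ends
        for cand in (0.0, 1.0):
            ll_c = self.loglik(cand)
            if ll_c > ll_hat:
                lam, ll_hat = cand, ll_c
        ll0 = self.loglik(0.0)
        lrt = max(0.0, 2.0 * (ll_hat - ll0))
        p = float(stats.chi2.sf(lrt, df=1))
        return PagelLambdaResults(lam, ll_hat, ll0, p)


def pagel_lambda_ml(tree: dendropy.Tree, trait: Mapping[str, float]) -> PagelLambdaResults:
    """Functional wrapper around :class:`PagelLambda`."""
    return PagelLambda(tree, trait).fit()


@dataclass
class PhyloSignalResult:
    """Blomberg's K and Pagel's lambda for one trait."""
    k: float
    p_k: float
    lambda_: float
    loglik_lambda: float
    loglik_zero: float
    p_lambda: float

    def to_dict(self) -> dict:
        return {
            "k": self.k, "p_k": self.p_k, "lambda": self.lambda_,
            "loglik_lambda": self.loglik_lambda,
            "loglik_zero": self.loglik_zero, "p_lambda": self.p_lambda,
        }


def phylo_signal(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Phylogenetic signal of one trait by both K and lambda."""
    k, p_k = signal_permutation_test(tree, trait, n_perm=n_perm, seed=seed)
    lam = PagelLambda(tree, trait).fit()
    return PhyloSignalResult(k, p_k, lam.lambda_, lam.loglik,
                             lam.loglik_zero, lam.lrt_pvalue)


# ---------------------------------------------------------------------------
# PGLS

class PGLS:
    """Phylogenetic generalized least squares.

    The residual covariance is sigma^2 V(lambda); lambda is either fixed or
    estimated by maximising the profile likelihood (beta and sigma^2 profiled
    analytically).  ``V(0)`` is diagonal, so on an ultrametric tree the
    lambda = 0 fit coincides with OLS.

    Parameters
    ----------
    endog : response vector, aligned with ``labels``.
    exog : design matrix including the intercept column.
    tree : rooted phylogeny whose tips cover ``labels``.
    labels : species name per row.
    exog_names : column names for the coefficient table.
    """

    def __init__(self, endog, exog, tree: dendropy.Tree,
                 labels: Sequence[str], exog_names: Sequence[str] | None = None):
        self.y = np.asarray(endog, dtype=float)
        self.X = np.atleast_2d(np.asarray(exog, dtype=float))
        self.labels = list(labels)
        n, p = self.X.shape
        if self.y.shape != (n,) or len(self.labels) != n:
            raise ValueError("endog, exog and labels must have matching length")
        if n <= p + 1:
            raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
        rank = np.linalg.matrix_rank(self.X)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(p)]
        if rank < p:
            raise ValueError(
                f"singular design matrix (rank {rank} < {p}); "
                f"columns: {self.exog_names}")
        self.tree = tree
        self._V1, _ = phylo_covariance(tree, 1.0, order=self.labels)
        self._D = np.diag(np.diag(self._V1))

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors: Sequence[str], tree: dendropy.Tree,
                       interactions: Sequence[tuple[str, str]] = ()) -> "PGLS":
        """Build a PGLS model from a species-indexed dataframe.

        Categorical predictors are dummy-coded (first level as reference).
        Species present in only one of tree/table are dropped jointly with a
        warning.  ``interactions`` adds product terms of already-included
        columns.
        """
        tips = set(tip_labels(tree))
        common = [s for s in data.index if s in tips]
        dropped = sorted((set(data.index) | tips) - set(common))
        if dropped:
            warnings.warn(f"dropping species absent from tree or table: {dropped}")
            from .trees import prune_to_taxa
            tree = prune_to_taxa(tree, common)
        sub = data.loc[common]
        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(sub))}
        for name in predictors:
            col = sub[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(col.dropna().unique())
                for lev in levels[1:]:
                    cols[f"{name}[{lev}]"] = (col == lev).to_numpy(dtype=float)
            else:
                cols[name] = col.to_numpy(dtype=float)
        for a, b in interactions:
            ka = [k for k in cols if k == a or k.startswith(f"{a}[")]
            kb = [k for k in cols if k == b or k.startswith(f"{b}[")]
            for i in ka:
                for j in kb:
                    cols[f"{i}:{j}"] = cols[i] * cols[j]
        X = np.column_stack(list(cols.values()))
        mask = np.isfinite(sub[response].to_numpy(dtype=float)) & np.isfinite(X).all(axis=1)
        if not mask.all():
            bad = [s for s, ok in zip(common, mask) if not ok]
            warnings.warn(f"dropping species with missing values: {bad}")
            from .trees import prune_to_taxa
            tree = prune_to_taxa(tree, [s for s, ok in zip(common, mask) if ok])
        y = sub[response].to_numpy(dtype=float)[mask]
        return cls(y, X[mask], tree, [s for s, ok in zip(common, mask) if ok],
                   exog_names=list(cols))

    # -- likelihood machinery -------------------------------------------------

    def _V(self, lam: float) -> np.ndarray:
        return lam * self._V1 + (1.0 - lam) * self._D

    def _gls(self, lam: float):
        V = self._V(lam)
        c, low = linalg.cho_factor(V, lower=True)
        Xw = linalg.cho_solve((c, low), self.X)
        XtVX = self.X.T @ Xw
        beta = np.linalg.solve(XtVX, Xw.T @ self.y)
        r = self.y - self.X @ beta
        rss = float(r @ linalg.cho_solve((c, low), r))
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return beta, r, rss, logdet, XtVX

    def profile_loglik(self, lam: float) -> float:
        n = self.y.size
        _, _, rss, logdet, _ = self._gls(lam)
        sigma2 = rss / n
        return float(-0.5 * n * np.log(2.0 * np.pi * sigma2) - 0.5 * logdet - 0.5 * n)

    def fit(self, lambda_mode: str | float = "ml", xtol: float = 1e-6) -> "PGLSResults":
        """Fit the model.

        ``lambda_mode`` is either ``"ml"`` or a fixed lambda in [0, 1].
        """
        if lambda_mode == "ml":
            res = optimize.minimize_scalar(
                lambda lam: -self.profile_loglik(lam), bounds=(0.0, 1.0),
                method="bounded", options={"xatol": xtol})
            if not res.success:
                raise RuntimeError(f"lambda optimisation failed: {res.message}")
            lam, ll = float(res.x), -float(res.fun)
            for cand in (0.0, 1.0):
                ll_c = self.profile_loglik(cand)
                if ll_c > ll:
                    lam, ll = cand, ll_c
        else:
            lam = float(lambda_mode)
            if not (0.0 <= lam <= 1.0):
                raise ValueError("fixed lambda must be in [0, 1]")
            ll = self.profile_loglik(lam)
        n, p = self.X.shape
        beta, r, rss, _, XtVX = self._gls(lam)
        s2 = rss / (n - p)
        cov = s2 * np.linalg.inv(XtVX)
        bse = np.sqrt(np.diag(cov))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
        # GLS R^2 against the intercept-only GLS fit at the same lambda
        V = self._V(lam)
        c, low = linalg.cho_factor(V, lower=True)
        ones = np.ones(n)
        Vinv_1 = linalg.cho_solve((c, low), ones)
        mu = (ones @ linalg.cho_solve((c, low), self.y)) / (ones @ Vinv_1)
        r0 = self.y - mu
        tss = float(r0 @ linalg.cho_solve((c, low), r0))
        rsq = 1.0 - rss / tss
        # whitened regression for influence diagnostics
        L = np.linalg.cholesky(V)
        yw = linalg.solve_triangular(L, self.y, lower=True)
        Xw = linalg.solve_triangular(L, self.X, lower=True)
        return PGLSResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            lambda_used=lam, loglik=ll, rsquared=float(rsq),
            resid=pd.Series(r, index=self.labels), rss=rss, scale=float(s2),
            nobs=n, df_resid=n - p, _yw=yw, _Xw=Xw)


@dataclass
class PGLSResults:
    """Fitted PGLS model: coefficient table, GLS R^2 and influence."""
    model: PGLS
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    lambda_used: float
    loglik: float
    rsquared: float
    resid: pd.Series
    rss: float
    scale: float
    nobs: int
    df_resid: int
    _yw: np.ndarray = field(repr=False, default=None)
    _Xw: np.ndarray = field(repr=False, default=None)

    def cooks_distance(self) -> pd.Series:
        """Cook's distance per species on the whitened (decorrelated) regression.

        D_i = r_i^2 h_i / (p s^2 (1 - h_i)^2) with leverages h from the
        whitened hat matrix; at lambda = 0 on an ultrametric tree this is the
        textbook OLS Cook's distance.  A leverage of 1 is reported as +inf.
        """
        Xw, yw = self._Xw, self._yw
        p = Xw.shape[1]
        Q, _ = np.linalg.qr(Xw)
        h = np.einsum("ij,ij->i", Q, Q)
        rw = yw - Xw @ np.linalg.lstsq(Xw, yw, rcond=None)[0]
        d = np.full(h.shape, np.inf)
        ok = h < 1.0 - 1e-12
        d[ok] = rw[ok] ** 2 * h[ok] / (p * self.scale * (1.0 - h[ok]) ** 2)
        return pd.Series(d, index=self.model.labels)

    def summary(self) -> str:
        tab = pd.DataFrame({
            "coef": self.params, "std err": self.bse,
            "t": self.tvalues, "P>|t|": self.pvalues})
        lines = [
            "PGLS regression results",
            f"  nobs {self.nobs}  df_resid {self.df_resid}  "
            f"lambda {self.lambda_used:.4f}  R^2 (GLS) {self.rsquared:.4f}",
            f"  logLik {self.loglik:.4f}",
            tab.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)

    def plot_fit(self, x_name: str, ax=None):
        """Scatter of response vs one predictor with the fitted values."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = self.model.X[:, self.model.exog_names.index(x_name)]
        yhat = self.model.X @ self.params.to_numpy()
        ax.scatter(x, self.model.y, label="observed")
        order = np.argsort(x)
        ax.plot(x[order], yhat[order], color="C1", label="PGLS fit")
        ax.set_xlabel(x_name)
        ax.legend()
        return ax


def cooks_distance(fit: PGLSResults) -> pd.Series:
    """Functional wrapper; see :meth:`PGLSResults.cooks_distance`."""
    return fit.cooks_distance()


# ---------------------------------------------------------------------------
# climate PCA

@dataclass
class ClimatePCA:
    """PCA of site climate variables.

    ``loadings`` columns are orthonormal principal axes; ``scores`` rows are
    species; ``variance_explained`` is percent per component and sums to 100.
    PC1 is oriented so its loading on minimum temperature (``minT``) is
    positive: larger PC1 means warmer/drier sites.
    """
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    center: pd.Series
    scale: pd.Series
    standardized: bool

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def climate_pca(table: pd.DataFrame, columns: Sequence[str] | None = None,
                standardize: bool = True) -> ClimatePCA:
    """Principal component analysis of climate columns.

    Columns are centred and (by default) z-scaled — the climate variables mix
    degrees Celsius and millimetres.  Eigendecomposition of the covariance of
    the processed matrix; all components retained, so
    ``scores @ loadings.T`` reproduces the processed matrix exactly.
    """
    if columns is None:
        columns = [c for c in CLIMATE_VARS if c in table.columns]
        if len(columns) < 2:
            columns = list(table.columns)
    X = table[list(columns)].astype(float)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 rows")
    if X.isna().any().any():
        raise ValueError("PCA input contains missing values")
    center = X.mean()
    scale = X.std(ddof=1) if standardize else pd.Series(1.0, index=X.columns)
    if standardize and (scale == 0).any():
        bad = list(scale.index[scale == 0])
        raise ValueError(f"zero-variance column(s) under standardization: {bad}")
    Z = (X - center) / scale
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # deterministic orientation: largest-magnitude loading positive ...
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1.0
    # ... except PC1, which points toward warmer sites (positive minT loading)
    if "minT" in columns:
        i = list(columns).index("minT")
        if evecs[i, 0] < 0:
            evecs[:, 0] *= -1.0
    names = [f"PC{j + 1}" for j in range(len(evals))]
    scores = Z.to_numpy() @ evecs
    var_pct = 100.0 * evals / evals.sum()
    return ClimatePCA(
        loadings=pd.DataFrame(evecs, index=list(columns), columns=names),
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        variance_explained=var_pct, center=center, scale=scale,
        standardized=standardize)


# ---------------------------------------------------------------------------
# small-sample statistics

def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bonferroni(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment min(1, p*m); ``m`` defaults to len(pvals) and
    may be larger (pre-declared test family)."""
    pvals = list(pvals)
    if m is None:
        m = len(pvals)
    if m < len(pvals):
        raise ValueError("family size m must be >= number of tests")
    out = []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append(min(1.0, p * m))
    return out


def loess_smooth(x, y, span: float = 1.5, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Local linear regression with tricube weights (loess, degree 1).

    For span <= 1 each local fit uses the ceil(span*n) nearest points with
    distances scaled by the bandwidth (distance to the furthest point used);
    for span > 1 all points are used and distances are scaled by
    span * max distance, the conventional extension for oversmoothing
    (a span of 1.5 is used to draw the broad trait-climate trend).

    Returns ``(grid, fitted)``; by default the grid is the sorted unique x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("loess needs at least 4 points")
    if span <= 0:
        raise ValueError("span must be positive")
    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        if span <= 1.0:
            q = int(np.ceil(span * n))
            idx = np.argsort(d)[:q]
            h = d[idx].max()
        else:
            idx = np.arange(n)
            h = span * d.max()
        if idx.size < 3:
            raise ValueError("fewer than 3 points in a local window")
        if h == 0:
            fitted[i] = y[idx].mean()
            continue
        u = np.clip(d[idx] / h, 0.0, 1.0)
        w = (1.0 - u ** 3) ** 3
        X = np.column_stack([np.ones(idx.size), x[idx] - x0])
        W = w[:, None]
        beta, *_ = np.linalg.lstsq(X * np.sqrt(W), y[idx] * np.sqrt(w), rcond=None)
        fitted[i] = beta[0]
    return grid, fitted
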