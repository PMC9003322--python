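"""Mixed-effects logistic screening of MMD covariates.

The screening stage of the analysis: each candidate exposure is first fit
one-at-a-time in a logistic regression with a random country intercept
(bivariate screen, entry at p < 0.20), the retained set is checked for
collinearity (Spearman rank correlations and variance inflation factors),
and the survivors enter one multivariable mixed model.

The random-intercept likelihood is integrated by adaptive Gauss-Hermite
quadrature (the integrand is re-centred at its per-cluster mode and scaled
by its curvature before applying the Hermite rule), maximized by
quasi-Newton, with Wald intervals on the fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "ScreenConfig", "GLMMFit", "fit_logistic_random_intercept",
    "bivariate_screen", "collinearity_filter",
]


@dataclass
class ScreenConfig:
    entry_p: float = 0.20
    spearman_cutoff: float = 0.40
    vif_cutoff: float = 10.0
    vif_warn: float = 5.0
    ci_level: float = 0.95
    #: covariates kept when a correlated pair must be broken, most
    #: preferred first (the "biological justification" rule made explicit)
    priority: tuple[str, ...] = ("z_vitamin_c", "z_log_mpo", "female")

    def __post_init__(self):
        if not 0.0 < self.entry_p < 1.0:
            raise ValueError("entry_p must be in (0, 1)")
        if not 0.0 < self.spearman_cutoff < 1.0:
            raise ValueError("spearman_cutoff must be in (0, 1)")
        if not self.vif_cutoff > 1.0:
            raise ValueError("vif_cutoff must exceed 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class GLMMFit:
    """Fixed effects, Wald intervals, and the random-intercept variance of
    one mixed logistic fit."""

    coefficients: dict[str, tuple[float, float, float]]  # est, se, p
    odds_ratios: dict[str, tuple[float, float, float]]   # OR, lo, hi
    random_intercept_variance: float
    converged: bool
    n_used: int
    n_clusters: int
    loglik: float
    separation: bool = False

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]


def _log_sigmoid(z):
    return -np.logaddexp(0.0, -z)


_GH_X, _GH_W = np.polynomial.hermite.hermgauss(15)


def _cluster_loglik(eta, y, theta, nodes_x, nodes_w):
    """Adaptive GH marginal log-likelihood of one cluster.

    eta: fixed-effect linear predictor for cluster members; theta: random
    intercept SD.
    """
    if theta < 1e-8:
        return float(np.sum(y * _log_sigmoid(eta) + (1 - y) * _log_sigmoid(-eta)))

    def h(v):
        z = eta + theta * v
        return np.sum(y * _log_sigmoid(z) + (1 - y) * _log_sigmoid(-z)) - 0.5 * v * v

    # 1-D Newton for the mode of the integrand
    v = 0.0
    for _ in range(50):
        z = eta + theta * v
        p = 1.0 / (1.0 + np.exp(-z))
        g = theta * np.sum(y - p) - v
        hess = -(theta ** 2) * np.sum(p * (1 - p)) - 1.0
        step = g / hess
        v -= step
        if abs(step) < 1e-10:
            break
    tau = 1.0 / np.sqrt(-hess)
    vs = v + np.sqrt(2.0) * tau * nodes_x
    hv = np.array([h(vi) for vi in vs])
    h0 = h(v)
    # integral against the N(0,1) prior: (2 pi)^(-1/2) * sqrt(2) tau *
    # sum_k w_k exp(x_k^2) exp(h(v_k)), evaluated in log space
    log_terms = np.log(nodes_w) + nodes_x ** 2 + hv - h0
    m = log_terms.max()
    return float(h0 + np.log(np.sqrt(2.0) * tau) + m
                 + np.log(np.sum(np.exp(log_terms - m)))
                 - 0.5 * np.log(2.0 * np.pi))


def _marginal_loglik(params, X, y, cluster_idx, n_clusters):
    beta, log_theta = params[:-1], params[-1]
    theta = np.exp(log_theta)
    eta = X @ beta
    total = 0.0
    for c in range(n_clusters):
        sel = cluster_idx == c
        total += _cluster_loglik(eta[sel], y[sel], theta, _GH_X, _GH_W)
    return total


def fit_logistic_random_intercept(y, X, cluster, config: ScreenConfig | None = None,
                                  names: list[str] | None = None,
                                  add_intercept: bool = True) -> GLMMFit:
    """Maximum-likelihood logistic regression with a random cluster
    intercept (adaptive Gauss-Hermite quadrature).

    ``X`` may be a DataFrame (column names kept) or array; a leading
    intercept column is added unless ``add_intercept=False``.  With a
    single cluster the model degrades to ordinary logistic regression.
    Non-convergence and separation are flagged, never silent.
    """
    config = config or ScreenConfig()
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in y or X; complete-case filter first")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + list(names)
    codes, uniques = pd.factorize(np.asarray(cluster))
    n_clusters = len(uniques)

    p = X.shape[1]
    # start from a ridge-stabilized Newton logistic fit
    beta0 = np.zeros(p)
    for _ in range(25):
        z = X @ beta0
        mu = 1.0 / (1.0 + np.exp(-z))
        W = mu * (1 - mu) + 1e-9
        H = X.T @ (X * W[:, None]) + 1e-6 * np.eye(p)
        g = X.T @ (y - mu) - 1e-6 * beta0
        step = np.linalg.solve(H, g)
        beta0 = beta0 + step
        if np.max(np.abs(step)) < 1e-8:
            break

    if n_clusters >= 2:
        x0 = np.concatenate([beta0, [np.log(0.5)]])
        obj = lambda prm: -_marginal_loglik(prm, X, y, codes, n_clusters)
        res = minimize(obj, x0, method="BFGS",
                       options=dict(gtol=1e-6, maxiter=400))
        params = res.x
        beta = params[:-1]
        theta = float(np.exp(params[-1]))
        loglik = -res.fun
        converged = bool(res.success) or np.max(np.abs(res.jac[:-1])) < 1e-3
        # numeric observed information for the fixed effects
        hess = _numeric_hessian(lambda b: -_marginal_loglik(
            np.concatenate([b, [params[-1]]]), X, y, codes, n_clusters), beta)
    else:
        beta = beta0
        theta = 0.0
        z = X @ beta
        loglik = float(np.sum(y * _log_sigmoid(z) + (1 - y) * _log_sigmoid(-z)))
        converged = True
        mu = 1.0 / (1.0 + np.exp(-z))
        hess = X.T @ (X * (mu * (1 - mu))[:, None])

    separation = bool(np.max(np.abs(beta)) > 15.0)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
        converged = False
    zcrit = stats.norm.ppf(0.5 + (config.ci_level) / 2.0)
    coeffs, ors = {}, {}
    for j, name in enumerate(names):
        est, s = float(beta[j]), float(se[j])
        pval = float(2 * stats.norm.sf(abs(est) / s)) if s > 0 else float("nan")
        coeffs[name] = (est, s, pval)
        ors[name] = (float(np.exp(est)),
                     float(np.exp(est - zcrit * s)),
                     float(np.exp(est + zcrit * s)))
    return GLMMFit(
        coefficients=coeffs, odds_ratios=ors,
        random_intercept_variance=float(theta ** 2),
        converged=converged and not separation,
        n_used=len(y), n_clusters=n_clusters, loglik=loglik,
        separation=separation,
    )


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps * eps)
    return H


def bivariate_screen(table: pd.DataFrame, candidates: list[str],
                     config: ScreenConfig | None = None,
                     outcome: str = "mmd", cluster: str = "site"
                     ) -> tuple[list[str], pd.DataFrame]:
    """One-covariate-at-a-time mixed logistic screen.

    Retains covariates with Wald p strictly below ``entry_p``; covariates
    with (near-)zero variance are excluded with a logged reason.  Returns
    the retained list and the full p-value ledger.
    """
    config = config or ScreenConfig()
    rows = []
    retained = []
    y = table[outcome].to_numpy(dtype=float)
    for cov in candidates:
        x = table[cov].to_numpy(dtype=float)
        if np.nanstd(x) < 1e-12:
            rows.append(dict(covariate=cov, estimate=np.nan, se=np.nan,
                             p_value=np.nan, retained=False,
                             reason="zero variance"))
            continue
        fit = fit_logistic_random_intercept(
            y, x[:, None], table[cluster], config, names=[cov])
        est, se, pval = fit.coefficients[cov]
        keep = bool(np.isfinite(pval) and pval < config.entry_p and fit.converged)
        reason = "" if fit.converged else "did not converge"
        rows.append(dict(covariate=cov, estimate=est, se=se, p_value=pval,
                         retained=keep, reason=reason))
        if keep:
            retained.append(cov)
    return retained, pd.DataFrame(rows)


def collinearity_filter(table: pd.DataFrame, covariates: list[str],
                        config: ScreenConfig | None = None
                        ) -> tuple[list[str], pd.DataFrame, pd.Series]:
    """Spearman-rank and VIF collinearity gatekeeping.

    Flags all pairs with \\|rho\\| above the cut-off; within a flagged pair
    the member appearing earlier in the config's priority list is kept
    (unlisted members lose to listed ones; between two unlisted members
    the first in the input ordering is kept).  VIFs (1/(1-R^2) of each
    covariate regressed on the others) are reported for the kept set;
    constant covariates yield missing VIF.
    """
    config = config or ScreenConfig()
    if len(covariates) < 2:
        return list(covariates), pd.DataFrame(
            columns=["a", "b", "rho", "kept"]), _vif_table(table, covariates)
    sub = table[covariates].astype(float)
    if len(covariates) == 2:
        r = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(stats.spearmanr(sub.to_numpy()).statistic)
    flagged = []
    dropped: set[str] = set()

    def rank(name: str) -> int:
        try:
            return config.priority.index(name)
        except ValueError:
            return len(config.priority) + covariates.index(name)

    for i in range(len(covariates)):
        for j in range(i + 1, len(covariates)):
            if abs(rho[i, j]) > config.spearman_cutoff:
                a, b = covariates[i], covariates[j]
                keep = a if rank(a) <= rank(b) else b
                lose = b if keep == a else a
                flagged.append(dict(a=a, b=b, rho=float(rho[i, j]), kept=keep))
                dropped.add(lose)
    kept = [c for c in covariates if c not in dropped]
    return kept, pd.DataFrame(flagged), _vif_table(table, kept)


def _vif_table(table: pd.DataFrame, covariates: list[str]) -> pd.Series:
    vifs = {}
    X = table[covariates].to_numpy(dtype=float) if covariates else None
    for i, cov in enumerate(covariates):
        xi = X[:, i]
        if np.std(xi) < 1e-12:
            vifs[cov] = np.nan
            continue
        others = np.delete(X, i, axis=1)
        A = np.column_stack([np.ones(len(xi)), others])
        coef, *_ = np.linalg.lstsq(A, xi, rcond=None)
        resid = xi - A @ coef
        r2 = 1.0 - resid.var() / xi.var()
        vifs[cov] = float(1.0 / max(1.0 - r2, 1e-12))
    return pd.Series(vifs, name="vif")
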