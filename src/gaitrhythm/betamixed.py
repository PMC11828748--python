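"""Beta mixed-effects regression with a single random intercept.

The response y in (0, 1) is beta-distributed with mean mu and precision
phi, parametrized so that a = mu*phi and b = (1 - mu)*phi. The mean is
modelled on the logit scale,

    logit(mu_ij) = x_ij' beta + u_i,    u_i ~ N(0, sigma^2),

with one Gaussian random intercept per group (here: horse). The marginal
likelihood integrates the random effect out by adaptive Gauss-Hermite
quadrature: per group, the integrand's mode is located by Newton
iterations with analytic first and second derivatives, and the quadrature
nodes are centered and scaled at that mode. Parameters (beta, log phi,
log sigma) are estimated by maximum likelihood; standard errors come
from the observed information (numerical Hessian at the optimum).

The model, likelihood and quadrature are implemented here; the fixed-
effects-only beta regression of statsmodels is used only to seed the
optimizer with starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special
from scipy.special import expit

_SIGMA_FLOOR = 1e-8


@dataclass
class BetaMixedResult:
    """Maximum-likelihood fit of the beta mixed model."""

    params: np.ndarray  # (beta..., log_phi, log_sigma)
    se: np.ndarray
    param_names: list[str]
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    n_quad: int
    design_info: object = None  # patsy DesignInfo when fitted from a formula
    cov_params: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k_params(self) -> int:
        return self.params.size

    @property
    def fe_params(self) -> np.ndarray:
        return self.params[:-2]

    @property
    def fe_cov(self) -> np.ndarray:
        if self.cov_params is None:
            raise ValueError("covariance unavailable (fit did not converge)")
        return self.cov_params[:-2, :-2]

    @property
    def phi(self) -> float:
        return float(np.exp(self.params[-2]))

    @property
    def sigma(self) -> float:
        return float(np.exp(self.params[-1]))

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"estimate": self.params, "se": self.se}, index=self.param_names
        )


class _MarginalLoglik:
    """Negative marginal log-likelihood, vectorized over groups."""

    def __init__(self, y, X, group_idx, n_groups, n_quad):
        order = np.argsort(group_idx, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        gi = np.asarray(group_idx)[order]
        self.n_groups = n_groups
        self.gidx = gi
        # reduceat boundaries for per-group sums (every group non-empty)
        self.starts = np.searchsorted(gi, np.arange(n_groups))
        self.logy = np.log(self.y)
        self.log1my = np.log1p(-self.y)
        self.ystar = self.logy - self.log1my
        self.nodes, self.weights = hermgauss(n_quad)
        self.log_weights = np.log(self.weights)
        self._b_warm = np.zeros(n_groups)  # warm start for the inner Newton

    def _group_sum(self, v):
        return np.add.reduceat(v, self.starts)

    def _obs_loglik(self, eta, phi):
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        return (a - 1.0) * self.logy + (b - 1.0) * self.log1my - special.betaln(a, b)

    def _score_hess_b(self, b_g, eta0, phi, sigma2):
        """First and second derivative of the log-integrand wrt b, per group."""
        eta = eta0 + b_g[self.gidx]
        mu = expit(eta)
        dmu = mu * (1.0 - mu)
        a = mu * phi
        bb = (1.0 - mu) * phi
        mustar = special.digamma(a) - special.digamma(bb)
        resid = self.ystar - mustar
        score_obs = phi * resid * dmu
        trig = special.polygamma(1, a) + special.polygamma(1, bb)
        hess_obs = phi * (-trig * phi * dmu**2 + resid * dmu * (1.0 - 2.0 * mu))
        score = self._group_sum(score_obs) - b_g / sigma2
        hess = self._group_sum(hess_obs) - 1.0 / sigma2
        return score, hess

    def _find_modes(self, eta0, phi, sigma2):
        b = self._b_warm.copy()
        for _ in range(50):
            score, hess = self._score_hess_b(b, eta0, phi, sigma2)
            hess = np.minimum(hess, -1.0 / sigma2 * 1e-3)  # keep steps downhill
            step = np.clip(-score / hess, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-9:
                break
        _, hess = self._score_hess_b(b, eta0, phi, sigma2)
        hess = np.minimum(hess, -_SIGMA_FLOOR)
        self._b_warm = b
        return b, hess

    def loglik(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        phi = float(np.exp(np.clip(theta[p], -20.0, 20.0)))
        sigma = max(float(np.exp(np.clip(theta[p + 1], -20.0, 10.0))), _SIGMA_FLOOR)
        sigma2 = sigma * sigma
        eta0 = self.X @ beta

        b_hat, hess = self._find_modes(eta0, phi, sigma2)
        tau = 1.0 / np.sqrt(-hess)

        # adaptive nodes b_gj = b_hat_g + sqrt(2) tau_g x_j
        bn = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.nodes[None, :]
        # per-node log-integrand: sum_i log f_i(b) + log N(b; 0, sigma^2)
        terms = np.empty((self.n_groups, self.nodes.size))
        for j in range(self.nodes.size):
            eta = eta0 + bn[self.gidx, j]
            ll_obs = self._obs_loglik(eta, phi)
            terms[:, j] = self._group_sum(ll_obs)
        terms += (
            -0.5 * bn**2 / sigma2
            - 0.5 * np.log(2.0 * np.pi * sigma2)
            + self.log_weights[None, :]
            + self.nodes[None, :] ** 2
        )
        m = terms.max(axis=1)
        log_int = m + np.log(np.exp(terms - m[:, None]).sum(axis=1))
        log_int += 0.5 * np.log(2.0) + np.log(tau)
        total = float(log_int.sum())
        if not np.isfinite(total):
            return -1e12
        return total

    def negloglik(self, theta):
        return -self.loglik(theta)


def _starting_values(y, X):
    """Seed (beta, log phi) from a fixed-effects beta regression."""
    try:
        from statsmodels.othermod.betareg import BetaModel

        with np.errstate(all="ignore"):
            res = BetaModel(y, X).fit(disp=False)
        p = X.shape[1]
        return np.asarray(res.params[:p], float), float(res.params[p])
    except Exception:
        p = X.shape[1]
        beta0 = np.zeros(p)
        ybar = float(np.mean(y))
        beta0[0] = np.log(ybar / (1.0 - ybar))
        return beta0, np.log(5.0)


def shrink_to_open_unit(y: np.ndarray) -> np.ndarray:
    """Map boundary responses into (0, 1) by (y*(n-1) + 0.5)/n."""
    y = np.asarray(y, float)
    if np.any((y >= 1.0) | (y <= 0.0)):
        n = y.size
        y = (y * (n - 1) + 0.5) / n
    return y


def fit_beta_mixed(
    y,
    X,
    groups,
    param_names: list[str] | None = None,
    n_quad: int = 11,
    design_info=None,
    meta: dict | None = None,
) -> BetaMixedResult:
    """Fit the beta mixed model by maximum likelihood.

    Parameters
    ----------
    y : array, values strictly in (0, 1)
    X : design matrix (n_obs, p), first column typically the intercept
    groups : array of group labels (the random-intercept factor)
    n_quad : number of Gauss-Hermite nodes (>= 9 recommended)

    Raises on responses outside the open unit interval or fewer than two
    groups; a non-converged optimization is returned flagged, never
    silently replaced by a simpler model.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    bad = np.nonzero((y <= 0.0) | (y >= 1.0))[0]
    if bad.size:
        raise ValueError(
            f"responses must lie strictly in (0, 1); offending rows: {bad.tolist()[:10]}"
        )
    labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if n_quad < 3:
        raise ValueError("n_quad must be >= 3")

    ml = _MarginalLoglik(y, X, gidx, labels.size, n_quad)
    beta0, logphi0 = _starting_values(y, X)
    x0 = np.concatenate([beta0, [logphi0, np.log(0.3)]])

    res = optimize.minimize(
        ml.negloglik, x0, method="BFGS", options={"gtol": 1e-5, "maxiter": 500}
    )
    if not res.success:  # one polish from the best point found
        res2 = optimize.minimize(
            ml.negloglik,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000},
        )
        if res2.fun <= res.fun:
            res = res2

    theta = np.asarray(res.x, float)
    ll = -float(res.fun)
    k = theta.size

    from statsmodels.tools.numdiff import approx_hess1

    se = np.full(k, np.nan)
    cov = None
    converged = bool(np.isfinite(ll))
    try:
        H = approx_hess1(theta, ml.negloglik)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se = np.sqrt(d)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    if param_names is None:
        param_names = [f"b{i}" for i in range(X.shape[1])]
    param_names = list(param_names) + ["log_phi", "log_sigma"]

    return BetaMixedResult(
        params=theta,
        se=se,
        param_names=param_names,
        loglik=ll,
        aic=2.0 * k - 2.0 * ll,
        converged=converged,
        n_obs=y.size,
        n_groups=labels.size,
        n_quad=n_quad,
        design_info=design_info,
        cov_params=cov,
        meta=meta or {},
    )


def fit_beta_mixed_formula(
    data,
    formula: str,
    group_col: str,
    n_quad: int = 11,
    meta: dict | None = None,
) -> BetaMixedResult:
    """Formula interface: ``response ~ fixed effects`` plus a random
    intercept for ``group_col``."""
    import patsy

    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    return fit_beta_mixed(
        y,
        X,
        data[group_col].to_numpy(),
        param_names=list(X_dm.columns),
        n_quad=n_quad,
        design_info=X_dm.design_info,
        meta={**(meta or {}), "formula": formula, "group_col": group_col},
    )
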