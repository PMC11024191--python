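"""Random-intercept generalized linear mixed models with a log link.

Fits Poisson and negative-binomial (NB2) models with a single Gaussian
random intercept by maximising the marginal likelihood.  The per-cluster
integral over the random effect is approximated by adaptive Gauss-Hermite
quadrature centred at the conditional mode (the default single node is the
Laplace approximation, accurate here because clusters hold many
observations).  Standard errors come from the numerical Hessian of the
marginal log-likelihood; tests are Wald z-tests.

Parameterisation: theta = (beta, log sigma_u[, log alpha]) where sigma_u
is the random-intercept standard deviation and alpha the NB2 dispersion
(variance mu + alpha mu^2).

Inference uses Wald statistics against a t reference with between-within
degrees of freedom: a covariate that is constant within every cluster is
tested against the number of clusters (minus the between-cluster model
rank), not the number of observations — a plain z reference is
anticonservative for such terms when clusters are few.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

from .errors import FitConvergenceError, InputError

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GLMMResult:
    """Fitted random-intercept GLMM."""

    names: list[str]
    params: np.ndarray  # fixed effects, log scale
    bse: np.ndarray
    pvalues: np.ndarray
    df: np.ndarray  # between-within denominator degrees of freedom
    sigma_u: float  # random-intercept SD
    sigma_u_se: float
    alpha: float | None  # NB2 dispersion; None for Poisson
    family: str
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    fitted_mean: float  # mean of exp(X beta) over the sample
    random_effects: dict

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        crit = stats.t.ppf(0.5 + level / 2.0, self.df)
        return np.column_stack(
            [self.params - crit * self.bse, self.params + crit * self.bse]
        )

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.params,
                "std_error": self.bse,
                "p_value": self.pvalues,
                "exp_estimate": np.exp(self.params),
            }
        )


class RandomInterceptGLMM:
    """Marginal-likelihood fitter for y ~ X beta + u_group, log link."""

    def __init__(self, y, X, groups, family: str = "negbin", n_quad: int = 1):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if family not in ("poisson", "negbin"):
            raise InputError(f"unknown family {family!r}")
        if y.ndim != 1 or X.ndim != 2 or len(y) != len(X):
            raise InputError("y must be 1-D and aligned with X")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise InputError("responses must be non-negative integers")
        codes, self.group_labels = _factorize(groups)
        order = np.argsort(codes, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.codes = codes[order]
        self.n_groups = len(self.group_labels)
        if self.n_groups < 2:
            raise InputError("need at least 2 groups for a random intercept")
        self.starts = np.searchsorted(self.codes, np.arange(self.n_groups))
        self.family = family
        self.n_quad = int(n_quad)
        self._gammaln_y1 = special.gammaln(self.y + 1.0)
        self._u = np.zeros(self.n_groups)  # warm-started conditional modes
        if self.n_quad > 1:
            self._qz, self._qw = hermgauss(self.n_quad)
        self.k_fixed = X.shape[1]

    # -- per-observation log-likelihood and derivatives in eta --------------
    def _ll_parts(self, eta: np.ndarray, r: float | None):
        # clip the linear predictor itself so the likelihood saturates
        # (clipping only mu would make y*eta grow without bound)
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        if self.family == "poisson":
            ll = self.y * eta - mu - self._gammaln_y1
            d1 = self.y - mu
            d2 = -mu
        else:
            denom = r + mu
            ll = (
                special.gammaln(self.y + r)
                - self._gammaln_r
                - self._gammaln_y1
                + r * (np.log(r) - np.log(denom))
                + self.y * (eta - np.log(denom))
            )
            d1 = self.y - (self.y + r) * mu / denom
            d2 = -(self.y + r) * r * mu / denom**2
        return ll, d1, d2

    def _group_sum(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr, self.starts)

    def _within_cluster_ptp(self, col: np.ndarray) -> float:
        mx = np.maximum.reduceat(col, self.starts)
        mn = np.minimum.reduceat(col, self.starts)
        return float(np.max(mx - mn))

    def _modes(self, eta0: np.ndarray, sigma2: float, r: float | None) -> tuple:
        """Newton iteration for the conditional modes of all clusters."""
        u = self._u.copy()
        for _ in range(50):
            eta = eta0 + u[self.codes]
            _, d1, d2 = self._ll_parts(eta, r)
            score = self._group_sum(d1) - u / sigma2
            hess = self._group_sum(d2) - 1.0 / sigma2  # < 0
            step = -score / hess
            np.clip(step, -5.0, 5.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u = u
        eta = eta0 + u[self.codes]
        ll, _, d2 = self._ll_parts(eta, r)
        h = -(self._group_sum(d2) - 1.0 / sigma2)  # > 0
        g_mode = (
            self._group_sum(ll)
            - u**2 / (2.0 * sigma2)
            - 0.5 * np.log(2.0 * np.pi * sigma2)
        )
        return u, g_mode, h

    def loglike(self, theta: np.ndarray) -> float:
        beta = theta[: self.k_fixed]
        sigma = np.exp(theta[self.k_fixed])
        sigma2 = sigma * sigma
        if self.family == "negbin":
            r = 1.0 / np.exp(theta[self.k_fixed + 1])
            self._gammaln_r = special.gammaln(r)
        else:
            r = None
        eta0 = self.X @ beta
        u, g_mode, h = self._modes(eta0, sigma2, r)
        if self.n_quad <= 1:  # Laplace
            return float(np.sum(g_mode + 0.5 * (_LOG_2PI - np.log(h))))
        scale = np.sqrt(2.0 / h)
        log_terms = np.empty((self.n_quad, self.n_groups))
        for k, (z, w) in enumerate(zip(self._qz, self._qw)):
            uk = u + z * scale
            eta = eta0 + uk[self.codes]
            ll, _, _ = self._ll_parts(eta, r)
            g = (
                self._group_sum(ll)
                - uk**2 / (2.0 * sigma2)
                - 0.5 * np.log(2.0 * np.pi * sigma2)
            )
            log_terms[k] = np.log(w) + g + z * z
        return float(np.sum(np.log(scale) + special.logsumexp(log_terms, axis=0)))

    # -- fitting -------------------------------------------------------------
    def _start_values(self) -> np.ndarray:
        import statsmodels.api as sm

        glm = sm.GLM(self.y, self.X, family=sm.families.Poisson()).fit()
        beta0 = np.asarray(glm.params, dtype=float)
        mu0 = np.clip(glm.fittedvalues, 1e-8, None)
        theta = [*beta0, np.log(0.3)]
        if self.family == "negbin":
            alpha_mm = float(
                np.sum((self.y - mu0) ** 2 - mu0) / max(np.sum(mu0**2), 1e-8)
            )
            theta.append(np.log(np.clip(alpha_mm, 0.02, 10.0)))
        return np.array(theta)

    def fit(self, names: list[str] | None = None, maxiter: int = 200) -> GLMMResult:
        theta0 = self._start_values()
        bounds = [(None, None)] * self.k_fixed + [(-6.0, 3.0)]
        if self.family == "negbin":
            bounds.append((-7.0, 5.0))

        def nll(theta):
            return -self.loglike(theta)

        res = optimize.minimize(
            nll,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        theta = res.x
        ll = -res.fun
        grad_ok = np.max(np.abs(res.jac)) < 1e-2 * max(1.0, abs(ll))
        if not (res.success or grad_ok):
            raise FitConvergenceError(
                f"optimiser failed: {res.message}; |grad|_inf="
                f"{np.max(np.abs(res.jac)):.3g}, loglik={ll:.3f}"
            )
        hess = approx_hess1(theta, nll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        se = np.sqrt(var)
        beta = theta[: self.k_fixed]
        bse = se[: self.k_fixed]
        # between-within degrees of freedom: terms constant within every
        # cluster are judged against the number of clusters
        between = np.array(
            [
                self._within_cluster_ptp(self.X[:, j]) < 1e-12
                for j in range(self.k_fixed)
            ]
        )
        q_between = int(between.sum())
        df_between = max(self.n_groups - q_between, 1)
        df_within = max(
            len(self.y) - self.n_groups - (self.k_fixed - q_between), 1
        )
        df = np.where(between, df_between, df_within).astype(float)
        z = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(z), df)
        sigma_u = float(np.exp(theta[self.k_fixed]))
        sigma_u_se = float(sigma_u * se[self.k_fixed])  # delta method
        alpha = (
            float(np.exp(theta[self.k_fixed + 1])) if self.family == "negbin" else None
        )
        if names is None:
            names = [f"x{i}" for i in range(self.k_fixed)]
        return GLMMResult(
            names=list(names),
            params=beta.copy(),
            bse=bse,
            pvalues=pvals,
            df=df,
            sigma_u=sigma_u,
            sigma_u_se=sigma_u_se,
            alpha=alpha,
            family=self.family,
            loglik=float(ll),
            n_obs=len(self.y),
            n_groups=self.n_groups,
            converged=True,
            fitted_mean=float(np.mean(np.exp(self.X @ beta))),
            random_effects={
                str(lab): float(u) for lab, u in zip(self.group_labels, self._u)
            },
        )


def _factorize(groups) -> tuple[np.ndarray, np.ndarray]:
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    return codes.astype(np.int64), labels


def latent_residual_variance(family: str, mean_mu: float, alpha: float | None) -> float:
    """Observation-level variance on the log-link latent scale.

    Uses the trigamma method: for NB2 the latent residual variance is
    psi_1(nu) with nu = (1/mu + alpha)^(-1); for Poisson, psi_1(mu)
    evaluated at the sample-mean fitted value.
    """
    if mean_mu <= 0:
        raise InputError("mean fitted value must be positive")
    if family == "poisson":
        nu = mean_mu
    elif family == "negbin":
        if alpha is None or alpha <= 0:
            raise InputError("NB latent variance needs alpha > 0")
        nu = 1.0 / (1.0 / mean_mu + alpha)
    else:
        raise InputError(f"unknown family {family!r}")
    return float(special.polygamma(1, nu))
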