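"""Binomial logit mixed models by Laplace approximation.

Random-intercept binomial GLMMs (the model behind every parasitism and
melanization response) are estimated by maximizing the Laplace
approximation to the marginal likelihood, the same approximation lme4's
``glmer`` uses by default:

    log L(beta, theta) ~ log f(y | u*) - u*' D^-1 u* / 2
                         - log det(D H) / 2,
    H = Z' W Z + D^-1,

where u* maximizes the penalized log-likelihood at the current (beta,
theta), D is the diagonal random-effect covariance and W the binomial
IRLS weights.  The criterion is optimized over the fixed effects and
log standard deviations jointly (as glmer does for nAGQ = 1), warm
started from a faster profiled fit.  Standard errors of the fixed
effects are conditional on the variance parameters (the usual GLMM
convention).

Supports any number of crossed random-intercept factors, which is what
the observation-level random effect (OLRE) used to absorb
overdispersion requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = ["BinomialMixedFit", "fit_binomial_mixed"]

_LOG_SD_BOUNDS = (-5.0, 3.0)


@dataclass
class BinomialMixedFit:
    """A fitted random-intercept binomial GLMM."""

    beta: pd.Series                  # fixed-effect coefficients (logit scale)
    vcov: pd.DataFrame               # conditional covariance of beta
    random_sd: dict[str, float]      # SD of each random-intercept factor
    loglik: float                    # Laplace log marginal likelihood
    converged: bool
    n_obs: int
    fitted_probs: np.ndarray         # conditional on the random-effect modes
    random_modes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.beta.index)

    def pearson_ratio(self, successes, trials, n_extra_params: int = 0) -> float:
        """Pearson chi-square / residual df, conditional fitted values.

        Residual df counts observations minus fixed effects minus the
        number of variance parameters (plus ``n_extra_params``).
        """
        successes = np.asarray(successes, dtype=float)
        trials = np.asarray(trials, dtype=float)
        p = self.fitted_probs
        var = np.clip(trials * p * (1.0 - p), 1e-10, None)
        chi2 = float(np.sum((successes - trials * p) ** 2 / var))
        df = self.n_obs - len(self.beta) - len(self.random_sd) - n_extra_params
        return chi2 / max(df, 1)


def _binom_loglik(y: np.ndarray, n: np.ndarray, eta: np.ndarray) -> float:
    # includes the binomial coefficient so log-likelihoods are comparable
    const = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return float(np.sum(const + y * eta - n * np.logaddexp(0.0, eta)))


def _solve_modes(y, n, offset, Z, d_inv, u0, max_iter=100, tol=1e-11):
    """Newton maximization of the penalized log-likelihood over u.

    ``offset`` is X beta.  Returns the modes u*, the penalized objective
    at the optimum and the u-block Hessian H = Z' W Z + D^-1 there.
    """
    q = Z.shape[1]
    u = u0.copy()

    def objective(u):
        eta = offset + Z @ u
        return _binom_loglik(y, n, eta) - 0.5 * float(np.sum(d_inv * u**2))

    obj = objective(u)
    if q == 0:
        return u, obj, np.zeros((0, 0))
    for _ in range(max_iter):
        eta = offset + Z @ u
        pvec = 1.0 / (1.0 + np.exp(-eta))
        mu = n * pvec
        w = n * pvec * (1.0 - pvec)
        grad = Z.T @ (y - mu) - d_inv * u
        if np.abs(grad).max() < tol:
            break
        H = (Z.T * w) @ Z
        H[np.arange(q), np.arange(q)] += d_inv
        try:
            c = np.linalg.cholesky(H)
        except np.linalg.LinAlgError:
            H[np.arange(q), np.arange(q)] += 1e-8
            c = np.linalg.cholesky(H)
        step = np.linalg.solve(c.T, np.linalg.solve(c, grad))
        t = 1.0
        for _ in range(30):
            u_new = u + t * step
            obj_new = objective(u_new)
            if obj_new >= obj - 1e-12:
                break
            t /= 2.0
        if obj_new - obj < tol and np.abs(grad).max() < 1e-6:
            u, obj = u_new, obj_new
            break
        u, obj = u_new, obj_new
    eta = offset + Z @ u
    pvec = 1.0 / (1.0 + np.exp(-eta))
    w = n * pvec * (1.0 - pvec)
    H = (Z.T * w) @ Z
    H[np.arange(q), np.arange(q)] += d_inv
    return u, obj, H


def fit_binomial_mixed(
    successes,
    failures,
    X: pd.DataFrame,
    factors: dict[str, np.ndarray],
) -> BinomialMixedFit:
    """Fit a binomial logit mixed model with random intercepts.

    Parameters
    ----------
    successes, failures
        Per-observation counts.
    X
        Fixed-effect design matrix (columns named).
    factors
        Maps factor name -> per-observation level codes; each factor
        contributes one random intercept per level with its own variance.
    """
    y = np.asarray(successes, dtype=float)
    fcounts = np.asarray(failures, dtype=float)
    n = y + fcounts
    if np.any(n <= 0):
        raise ValueError("every observation needs successes + failures > 0")
    Xv = X.to_numpy(dtype=float)
    n_obs, p = Xv.shape

    factor_names = list(factors)
    Zs, sizes = [], []
    for name in factor_names:
        codes, levels = pd.factorize(np.asarray(factors[name]))
        Zs.append(np.eye(len(levels))[codes])
        sizes.append(len(levels))
    Z = np.hstack(Zs) if Zs else np.zeros((n_obs, 0))
    q = Z.shape[1]
    n_theta = len(sizes)

    def expand_dinv(sds: np.ndarray) -> np.ndarray:
        if not q:
            return np.zeros(0)
        return np.concatenate([
            np.full(sz, 1.0 / sd**2) for sz, sd in zip(sizes, sds)
        ])

    state = {"u": np.zeros(q)}

    def laplace_nll(params: np.ndarray) -> float:
        beta = params[:p]
        sds = np.exp(params[p:])
        d_inv = expand_dinv(sds)
        offset = Xv @ beta
        u, pen_obj, H = _solve_modes(y, n, offset, Z, d_inv, state["u"])
        state["u"] = u
        if q:
            sign, logdet_h = np.linalg.slogdet(H)
            logdet_d = float(np.sum(
                [sz * 2.0 * np.log(sd) for sz, sd in zip(sizes, sds)]))
        else:
            logdet_h = logdet_d = 0.0
        return -(pen_obj - 0.5 * (logdet_d + logdet_h))

    # warm start: a plain GLM for beta, modest SDs for the factors
    from numpy.linalg import lstsq

    p_emp = np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
    eta0 = np.log(p_emp / (1.0 - p_emp))
    beta0 = lstsq(Xv, eta0, rcond=None)[0]
    x0 = np.concatenate([beta0, np.full(n_theta, np.log(0.5))])

    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS] * n_theta
    res = optimize.minimize(
        laplace_nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
    )
    converged = bool(res.success)
    beta = res.x[:p]
    sds = np.exp(res.x[p:])
    loglik = -float(res.fun)

    # final mode solve and conditional covariance of beta
    d_inv = expand_dinv(sds)
    u, _, H_uu = _solve_modes(y, n, Xv @ beta, Z, d_inv, state["u"])
    eta = Xv @ beta + (Z @ u if q else 0.0)
    pvec = 1.0 / (1.0 + np.exp(-eta))
    w = n * pvec * (1.0 - pvec)
    xwx = (Xv.T * w) @ Xv
    if q:
        xwz = (Xv.T * w) @ Z
        schur = xwx - xwz @ np.linalg.solve(H_uu, xwz.T)
    else:
        schur = xwx
    vcov = np.linalg.inv(schur + 1e-12 * np.eye(p))

    modes, start = {}, 0
    sd_out = {}
    for name, sz, sd in zip(factor_names, sizes, sds):
        modes[name] = u[start:start + sz]
        sd_out[name] = float(sd)
        start += sz

    return BinomialMixedFit(
        beta=pd.Series(beta, index=list(X.columns)),
        vcov=pd.DataFrame(vcov, index=list(X.columns), columns=list(X.columns)),
        random_sd=sd_out,
        loglik=loglik,
        converged=converged,
        n_obs=n_obs,
        fitted_probs=pvec,
        random_modes=modes,
    )
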