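"""Maximum-likelihood GLMMs with crossed random intercepts.

Fits y ~ X beta + sum_f Z_f b_f with b_f ~ N(0, sigma_f^2 I), Poisson
(log link) or Gaussian (identity) response. The integrated likelihood is
approximated by the Laplace method: for candidate variance parameters the
joint penalized log-likelihood is maximized over (beta, b) by Newton
iteration with step halving, and the marginal log-likelihood is

    l(theta) = l_joint(beta_hat, b_hat) - 1/2 log det(Z'WZ D + I)

with W the GLM weights at the mode and D the random-effect covariance.
For the Gaussian family the Laplace expression is the exact marginal
likelihood (the joint is quadratic in b), so Gaussian fits are exact ML.
Variance parameters are profiled out by L-BFGS-B on the standard-deviation
scale with a zero lower bound, so boundary (zero-variance) fits are exact
and collapse to the plain GLM.

Fixed-effect covariances are conditional on the estimated variance
parameters (the usual GLMM convention); AICc model comparison counts fixed
effects plus free variance parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

log = logging.getLogger(__name__)

__all__ = ["ModelSpec", "GLMMResult", "fit_glmm", "build_design"]

_SIGMA_FLOOR = 1e-6  # below this an SD is treated as exactly zero


@dataclass(frozen=True)
class ModelSpec:
    """One GLMM: response column, family, fixed predictors, random factors.

    ``fixed`` lists predictor columns (an intercept is always added);
    ``random`` lists grouping-factor columns, each contributing a random
    intercept.
    """

    response: str
    family: str
    fixed: tuple[str, ...] = ()
    random: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class GLMMResult:
    spec: ModelSpec
    beta: pd.Series
    cov_beta: pd.DataFrame
    sigmas: dict[str, float]
    loglik: float
    n_obs: int
    k_params: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.beta.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
        n, k = self.n_obs, self.k_params
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)


def build_design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], list[int]]:
    """Response vector, fixed design (intercept first) and one indicator
    matrix per random factor."""
    y = data[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[c].to_numpy(dtype=float) for c in spec.fixed]
    )
    Zs, q_sizes = [], []
    for factor in spec.random:
        codes, levels = pd.factorize(data[factor])
        if len(levels) < 2:
            raise ValueError(f"grouping factor {factor!r} has < 2 levels")
        Z = np.zeros((len(data), len(levels)))
        Z[np.arange(len(data)), codes] = 1.0
        Zs.append(Z)
        q_sizes.append(len(levels))
    return y, X, Zs, q_sizes


def _poisson_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(y @ eta - np.exp(eta).sum() - gammaln(y + 1.0).sum())


def _inner_mode(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None,
    d_inv: np.ndarray | None,
    family: str,
    sigma_e: float,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Joint Newton optimisation of (beta, b) for fixed variance parameters.

    Returns (beta, b, negative Hessian of the joint at the mode, joint
    log-density at the mode). ``Z`` stacks all random-factor indicator
    columns with free variance; ``d_inv`` the matching prior precisions.
    """
    n, p = X.shape
    q = 0 if Z is None else Z.shape[1]
    C = X if Z is None else np.hstack([X, Z])
    theta = np.zeros(p + q)
    pen = np.zeros(p + q)
    if q:
        pen[p:] = d_inv

    def joint(th: np.ndarray) -> float:
        eta = C @ th
        if family == "poisson":
            ll = _poisson_loglik(y, eta)
        else:
            ll = -0.5 * n * np.log(2 * np.pi * sigma_e**2) - 0.5 * np.sum(
                (y - eta) ** 2
            ) / sigma_e**2
        return ll - 0.5 * np.sum(pen * th**2)

    f0 = joint(theta)
    H = np.empty((p + q, p + q))
    for _ in range(max_iter):
        eta = C @ theta
        if family == "poisson":
            mu = np.exp(np.clip(eta, -30, 30))
            w = mu
            grad = C.T @ (y - mu) - pen * theta
        else:
            w = np.full(n, 1.0 / sigma_e**2)
            grad = C.T @ ((y - eta) / sigma_e**2) - pen * theta
        H[:] = (C * w[:, None]).T @ C
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            f1 = joint(cand)
            if f1 >= f0 - 1e-12:
                break
            scale *= 0.5
        theta, gain = cand, f1 - f0
        f0 = f1
        if abs(gain) < tol * (abs(f0) + 1.0):
            break
    # Hessian at the final mode
    eta = C @ theta
    if family == "poisson":
        w = np.exp(np.clip(eta, -30, 30))
    else:
        w = np.full(n, 1.0 / sigma_e**2)
    H = (C * w[:, None]).T @ C
    H[np.diag_indices_from(H)] += pen
    return theta[:p], theta[p:], H, f0


def _laplace_loglik(
    sds: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Zs: list[np.ndarray],
    q_sizes: list[int],
    family: str,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Marginal log-likelihood for given (sigma_f..., [sigma_e])."""
    n_f = len(Zs)
    sigma_e = sds[n_f] if family == "gaussian" else 1.0
    free = [i for i in range(n_f) if sds[i] > _SIGMA_FLOOR]
    if free:
        Z = np.hstack([Zs[i] for i in free])
        d_inv = np.concatenate(
            [np.full(q_sizes[i], 1.0 / sds[i] ** 2) for i in free]
        )
    else:
        Z, d_inv = None, None
    beta, b, H, f_joint = _inner_mode(y, X, Z, d_inv, family, sigma_e)
    p = X.shape[1]
    if Z is not None:
        # -1/2 log det(Z'WZ D + I), written via the b block of H:
        # H_bb = Z'WZ + D^-1  =>  det(Z'WZ D + I) = det(H_bb) * det(D)
        H_bb = H[p:, p:]
        sign, logdet_hbb = np.linalg.slogdet(H_bb)
        logdet_pen = logdet_hbb + np.sum(np.log(1.0 / d_inv))
    else:
        logdet_pen = 0.0
    ll = f_joint - 0.5 * logdet_pen
    # expand b back to all factors (zeros for pinned-at-zero factors)
    b_full = np.zeros(sum(q_sizes))
    if Z is not None:
        offs_full = np.cumsum([0] + q_sizes)
        pos = 0
        for i in free:
            b_full[offs_full[i] : offs_full[i] + q_sizes[i]] = b[
                pos : pos + q_sizes[i]
            ]
            pos += q_sizes[i]
    return ll, beta, b_full, H


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    fixed_sigmas: dict[str, float] | None = None,
    start_sd: float = 0.5,
) -> GLMMResult:
    """Fit the GLMM by maximum likelihood (Laplace for Poisson, exact for
    Gaussian). ``fixed_sigmas`` pins named variance components (use 0.0 to
    force the plain-GLM limit for that factor). Non-convergence is flagged
    in the result, never silent."""
    y, X, Zs, q_sizes = build_design(data, spec)
    n = len(y)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient")
    family = spec.family
    n_f = len(Zs)
    fixed_sigmas = fixed_sigmas or {}
    fixed_idx = {
        i: fixed_sigmas[f] for i, f in enumerate(spec.random) if f in fixed_sigmas
    }

    n_sd = n_f + (1 if family == "gaussian" else 0)

    def pack(free_vals: np.ndarray) -> np.ndarray:
        sds = np.empty(n_sd)
        it = iter(free_vals)
        for i in range(n_f):
            sds[i] = fixed_idx[i] if i in fixed_idx else next(it)
        if family == "gaussian":
            sds[n_f] = next(it)
        return sds

    free_positions = [i for i in range(n_f) if i not in fixed_idx]
    n_free = len(free_positions) + (1 if family == "gaussian" else 0)

    if n_free:
        x0 = np.full(n_free, start_sd)
        if family == "gaussian":
            x0[-1] = max(np.std(y), 1e-3)
        bounds = [(0.0, None)] * len(free_positions)
        if family == "gaussian":
            bounds.append((1e-8, None))

        def negll(v: np.ndarray) -> float:
            ll, *_ = _laplace_loglik(pack(v), y, X, Zs, q_sizes, family)
            return -ll

        opt = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-11},
        )
        sds = pack(opt.x)
        converged = bool(opt.success)
        if not converged:
            log.warning("fit_glmm: variance optimisation did not converge: %s",
                        opt.message)
    else:
        sds = pack(np.empty(0))
        converged = True

    ll, beta, b, H = _laplace_loglik(sds, y, X, Zs, q_sizes, family)
    p = X.shape[1]
    cov = np.linalg.inv(H)[:p, :p]
    names = ["(Intercept)", *spec.fixed]
    k = p + n_free  # fixed effects + free variance parameters
    sigmas = {f: float(sds[i]) for i, f in enumerate(spec.random)}
    if family == "gaussian":
        sigmas["residual"] = float(sds[n_f])
    return GLMMResult(
        spec=spec,
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        sigmas=sigmas,
        loglik=float(ll),
        n_obs=n,
        k_params=k,
        converged=converged,
        diagnostics={"b_mode": b},
    )
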