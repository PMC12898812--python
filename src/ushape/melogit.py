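"""Random-intercept logistic regression by maximum marginal likelihood.

The model for foot *j* of participant *i* is

    logit P(y_ij = 1) = beta0 + beta1 x_c + beta2 x_c^2 [+ beta3 x_c^3]
                        + gamma_L load_c + gamma_E exp_c + u_i,
    u_i ~ Normal(0, sigma_u^2),

with all continuous predictors mean-centered (subscript ``_c``).  The
marginal likelihood integrates the random intercept out of each cluster's
contribution; the integral is evaluated by adaptive Gauss-Hermite
quadrature centred and scaled at each cluster's posterior mode (one node
reproduces the Laplace approximation exactly).

Two fitting paths are provided and agree closely:

* the default path polishes ``(beta, log sigma_u)`` on the exact adaptive
  quadrature objective with a quasi-Newton optimizer;
* a fast profile path (PIRLS: penalized iteratively reweighted least
  squares jointly in ``(beta, u)``, with a 1-D outer search over
  ``log sigma_u`` of the Laplace objective) used for bootstrap and
  simulation workloads where thousands of refits are needed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datamodel import Dataset
from .errors import ComparisonError, SeparationError

__all__ = [
    "ModelSpec",
    "MixedLogisticFit",
    "FitIndices",
    "fit_mixed_logistic",
    "fit_indices",
    "likelihood_ratio_test",
    "predict_probability",
    "marginal_loglik",
]

_LOG_SIGMA_LO = -5.0  # sigma_u ~ 0.0067: numerically the sigma -> 0 boundary
_LOG_SIGMA_HI = 3.0
_BETA_DIVERGENCE = 30.0


@dataclass(frozen=True)
class ModelSpec:
    """Functional form of the fixed-effects part.

    degree: 1 linear, 2 quadratic, 3 cubic in (centered) SSNDT.
    adjust: include training load and experience covariates.
    center: mean-center all continuous predictors (default on; the stored
        centering constants make raw-scale prediction exact).
    """

    degree: int = 2
    adjust: bool = True
    center: bool = True

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")

    @property
    def term_names(self) -> list[str]:
        names = ["intercept"] + ["ssndt", "ssndt2", "ssndt3"][: self.degree]
        if self.adjust:
            names += ["load", "experience"]
        return names

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (
            self.degree <= other.degree
            and (not self.adjust or other.adjust)
            and self.center == other.center
        )


@dataclass
class MixedLogisticFit:
    """Result of a maximum-marginal-likelihood random-intercept logit fit."""

    beta: np.ndarray
    names: list[str]
    se: np.ndarray
    vcov: np.ndarray
    sigma_u: float
    loglik: float
    n_obs: int
    n_groups: int
    centering: dict[str, float]
    converged: bool
    quadrature_points: int
    spec: ModelSpec
    fingerprint: int = 0
    n_params: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_params = len(self.beta) + 1  # + random-intercept SD

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        z = np.divide(
            self.beta, self.se, out=np.full_like(self.beta, np.nan),
            where=self.se > 0,
        )
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "std_error": self.se,
                "z_value": z,
                "p_value": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.names,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "sigma_u": self.sigma_u,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "centering": self.centering,
            "converged": self.converged,
            "quadrature_points": self.quadrature_points,
            "degree": self.spec.degree,
            "adjust": self.spec.adjust,
        }


@dataclass(frozen=True)
class FitIndices:
    aic: float
    bic: float
    nagelkerke_r2: float
    deviance: float
    cox_snell_r2: float = 0.0


# ---------------------------------------------------------------------------
# design matrices and data preparation
# ---------------------------------------------------------------------------


def build_design(
    data: Dataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, float], list[str]]:
    """Sorted-by-cluster design matrix, outcome, group codes and centering."""
    df = data.to_frame()
    x = df["ssndt_mm"].to_numpy(float)
    load = df["load_h_per_week"].to_numpy(float)
    exp_ = df["experience_years"].to_numpy(float)
    y = df["injured"].to_numpy(float)
    centering = {
        "ssndt_mean": float(x.mean()) if spec.center else 0.0,
        "load_mean": float(load.mean()) if spec.center else 0.0,
        "exp_mean": float(exp_.mean()) if spec.center else 0.0,
    }
    xc = x - centering["ssndt_mean"]
    cols = [np.ones_like(xc)] + [xc**d for d in range(1, spec.degree + 1)]
    if spec.adjust:
        cols += [load - centering["load_mean"], exp_ - centering["exp_mean"]]
    X = np.column_stack(cols)
    codes = pd.factorize(df["participant_id"], sort=False)[0]
    order = np.argsort(codes, kind="stable")
    return X[order], y[order], codes[order], centering, spec.term_names


def _group_starts(codes_sorted: np.ndarray) -> np.ndarray:
    return np.flatnonzero(np.r_[True, np.diff(codes_sorted) != 0])


def _fingerprint(y: np.ndarray, codes: np.ndarray) -> int:
    buf = y.astype(np.int8).tobytes() + codes.astype(np.int32).tobytes()
    return zlib.crc32(buf)


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _bernoulli_ll(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    return y * eta - np.logaddexp(0.0, eta)


def _cluster_mode(
    eta_fix: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    sigma2: float,
    u0: np.ndarray,
    n_iter: int = 30,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and curvature of each cluster's integrand (Newton)."""
    u = u0.copy()
    gidx = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, len(y)]))
    for _ in range(n_iter):
        eta = eta_fix + u[gidx]
        p = special.expit(eta)
        grad = np.add.reduceat(y - p, starts) - u / sigma2
        w = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / sigma2
        step = grad / w
        u += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta_fix + u[gidx]
    p = special.expit(eta)
    curv = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / sigma2
    return u, curv


def marginal_loglik(
    beta: np.ndarray,
    sigma_u: float,
    X: np.ndarray,
    y: np.ndarray,
    codes_sorted: np.ndarray,
    quad_points: int = 15,
) -> float:
    """Marginal log-likelihood with the random intercept integrated out.

    Adaptive Gauss-Hermite with ``quad_points`` nodes; ``quad_points=1``
    is exactly the Laplace approximation.  At ``sigma_u ~ 0`` the model
    collapses to ordinary logistic regression and the Bernoulli
    log-likelihood is returned.
    """
    eta_fix = X @ beta
    if sigma_u < 1e-8:
        return float(_bernoulli_ll(eta_fix, y).sum())
    starts = _group_starts(codes_sorted)
    sigma2 = sigma_u**2
    q = len(starts)
    u_hat, curv = _cluster_mode(eta_fix, y, starts, sigma2, np.zeros(q))
    s = 1.0 / np.sqrt(curv)  # adaptive scale per cluster
    z, w = np.polynomial.hermite.hermgauss(quad_points)
    gidx = np.repeat(np.arange(q), np.diff(np.r_[starts, len(y)]))
    log_terms = np.empty((quad_points, q))
    for k in range(quad_points):
        u_k = u_hat + np.sqrt(2.0) * s * z[k]
        eta = eta_fix + u_k[gidx]
        g = (
            np.add.reduceat(_bernoulli_ll(eta, y), starts)
            - u_k**2 / (2.0 * sigma2)
            - 0.5 * np.log(2.0 * np.pi * sigma2)
        )
        log_terms[k] = np.log(w[k]) + z[k] ** 2 + g
    ll = special.logsumexp(log_terms, axis=0) + 0.5 * np.log(2.0 * s**2)
    return float(ll.sum())


def _plain_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> np.ndarray:
    """Newton/IRLS ordinary logistic fit (deterministic initialisation)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-10)
        H = X.T @ (X * w[:, None])
        g = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular information matrix: {e}") from e
        beta += step
        if np.max(np.abs(beta)) > _BETA_DIVERGENCE:
            raise SeparationError(
                "coefficients diverging in the ordinary logistic fit "
                "(perfect or quasi separation)"
            )
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    gidx: np.ndarray,
    sigma2: float,
    beta: np.ndarray,
    u: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Jointly maximize the penalized log-likelihood over (beta, u).

    Block-Newton with the u-block solved in closed form (diagonal), the
    beta-step via the Schur complement.  Returns (beta, u, h) with h the
    penalized log-likelihood including the Gaussian prior terms.
    """
    q = len(starts)

    def _h(beta_, u_):
        eta = X @ beta_ + u_[gidx]
        return (
            _bernoulli_ll(eta, y).sum()
            - (u_**2).sum() / (2.0 * sigma2)
            - 0.5 * q * np.log(2.0 * np.pi * sigma2)
        )

    h = _h(beta, u)
    for _ in range(max_iter):
        eta = X @ beta + u[gidx]
        p = special.expit(eta)
        w = np.maximum(p * (1.0 - p), 1e-12)
        resid = y - p
        sb = X.T @ resid
        su = np.add.reduceat(resid, starts) - u / sigma2
        D = np.add.reduceat(w, starts) + 1.0 / sigma2
        Xw = X * w[:, None]
        C = np.add.reduceat(Xw, starts, axis=0).T  # (p, q)
        H_bb = X.T @ Xw
        CD = C / D
        S = H_bb - CD @ C.T
        rhs = sb - CD @ su
        try:
            db = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError as e:
            raise SeparationError(f"singular PIRLS system: {e}") from e
        du = (su - C.T @ db) / D
        # step-halving keeps the joint objective monotone
        scale = 1.0
        for _half in range(20):
            h_new = _h(beta + scale * db, u + scale * du)
            if h_new >= h - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * db
        u = u + scale * du
        if np.max(np.abs(beta)) > _BETA_DIVERGENCE:
            raise SeparationError("coefficients diverging (separation)")
        if abs(h_new - h) < tol * (1.0 + abs(h)):
            h = h_new
            break
        h = h_new
    return beta, u, h


def _laplace_profile(
    X: np.ndarray,
    y: np.ndarray,
    codes_sorted: np.ndarray,
    beta0: np.ndarray,
    log_sigma_bounds: tuple[float, float] = (_LOG_SIGMA_LO, 2.5),
    xatol: float = 1e-5,
) -> tuple[np.ndarray, float, float, bool]:
    """Fast path: profile the Laplace objective over log sigma_u.

    For each candidate sigma, PIRLS maximizes the joint penalized
    log-likelihood over (beta, u); the Laplace marginal log-likelihood
    adds the half-log-curvature correction per cluster.  Warm starts carry
    (beta, u) across sigma evaluations.
    """
    starts = _group_starts(codes_sorted)
    q = len(starts)
    gidx = np.repeat(np.arange(q), np.diff(np.r_[starts, len(y)]))
    state = {"beta": beta0.copy(), "u": np.zeros(q)}

    def neg_ll(t: float) -> float:
        sigma2 = np.exp(2.0 * t)
        beta, u, h = _pirls(
            X, y, starts, gidx, sigma2, state["beta"], state["u"]
        )
        state["beta"], state["u"] = beta, u
        eta = X @ beta + u[gidx]
        p = special.expit(eta)
        D = np.add.reduceat(p * (1.0 - p), starts) + 1.0 / sigma2
        ll = h + 0.5 * np.sum(np.log(2.0 * np.pi / D))
        return -ll

    res = optimize.minimize_scalar(
        neg_ll,
        bounds=log_sigma_bounds,
        method="bounded",
        options={"xatol": xatol},
    )
    t_hat = float(res.x)
    neg = neg_ll(t_hat)  # leaves state at the optimum
    return state["beta"].copy(), float(np.exp(t_hat)), -neg, bool(res.success)


def _numerical_hessian(f, x0: np.ndarray, h: np.ndarray) -> np.ndarray:
    n = len(x0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x0 + ei + ej) - f(x0 + ei - ej)
                - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


@dataclass
class CoreFit:
    beta: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    vcov: np.ndarray | None = None


def fit_core(
    X: np.ndarray,
    y: np.ndarray,
    codes_sorted: np.ndarray,
    quad_points: int = 15,
    tol: float = 1e-8,
    fast: bool = False,
    compute_vcov: bool = True,
    beta_init: np.ndarray | None = None,
) -> CoreFit:
    """Shared estimation engine for polynomial and segmented designs.

    ``fast=True`` stops after the PIRLS/Laplace profile stage (the
    bootstrap/simulation workhorse); otherwise the exact adaptive-quadrature
    objective is polished by L-BFGS-B in ``(beta, log sigma_u)``.
    """
    y = np.asarray(y, float)
    if y.min() == y.max():
        raise SeparationError("outcome has a single class")
    if len(np.unique(codes_sorted)) < 2:
        raise ValueError("need at least 2 clusters")
    if quad_points < 1:
        raise ValueError("quad_points must be >= 1")

    beta0 = beta_init if beta_init is not None else _plain_logistic(X, y)
    beta_f, sigma_f, ll_f, ok = _laplace_profile(X, y, codes_sorted, beta0)

    if fast and quad_points == 1:
        if np.max(np.abs(beta_f)) > _BETA_DIVERGENCE:
            raise SeparationError("coefficients diverging (separation)")
        vc = None
        if compute_vcov:
            vc = _vcov_at(X, y, codes_sorted, beta_f, sigma_f, 1)
        return CoreFit(beta_f, sigma_f, ll_f, ok, vc)

    p = X.shape[1]
    t0 = np.log(max(sigma_f, np.exp(_LOG_SIGMA_LO)))

    def neg(theta: np.ndarray) -> float:
        return -marginal_loglik(
            theta[:p], float(np.exp(theta[p])), X, y, codes_sorted,
            quad_points,
        )

    x0 = np.r_[beta_f, t0]
    bounds = [(None, None)] * p + [(_LOG_SIGMA_LO, _LOG_SIGMA_HI)]
    res = optimize.minimize(
        neg, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": tol, "gtol": 1e-7},
    )
    beta_hat = res.x[:p]
    sigma_hat = float(np.exp(res.x[p]))
    if np.max(np.abs(beta_hat)) > _BETA_DIVERGENCE:
        raise SeparationError("coefficients diverging (separation)")
    ll = -float(res.fun)
    converged = bool(res.success)
    vc = None
    if compute_vcov:
        vc = _vcov_at(X, y, codes_sorted, beta_hat, sigma_hat, quad_points)
    return CoreFit(beta_hat, sigma_hat, ll, converged, vc)


def _vcov_at(
    X: np.ndarray,
    y: np.ndarray,
    codes_sorted: np.ndarray,
    beta: np.ndarray,
    sigma_u: float,
    quad_points: int,
) -> np.ndarray:
    """Fixed-effect covariance from the observed information matrix."""
    p = X.shape[1]
    at_boundary = sigma_u < 2 * np.exp(_LOG_SIGMA_LO)
    if at_boundary:
        # sigma is pinned at ~0: condition on it, invert the beta block
        def f(b):
            return -marginal_loglik(b, sigma_u, X, y, codes_sorted, 1)

        h = 1e-4 * (1.0 + np.abs(beta))
        H = _numerical_hessian(f, beta, h)
        return _psd_inverse(H)

    def f(theta):
        return -marginal_loglik(
            theta[:p], float(np.exp(theta[p])), X, y, codes_sorted,
            quad_points,
        )

    x0 = np.r_[beta, np.log(sigma_u)]
    h = 1e-4 * (1.0 + np.abs(x0))
    H = _numerical_hessian(f, x0, h)
    return _psd_inverse(H)[:p, :p]


def _psd_inverse(H: np.ndarray) -> np.ndarray:
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.linalg.pinv(H)
    V = 0.5 * (V + V.T)
    # clip tiny negative eigenvalues from finite differencing
    w, Q = np.linalg.eigh(V)
    return (Q * np.maximum(w, 0.0)) @ Q.T


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit_mixed_logistic(
    data: Dataset,
    spec: ModelSpec | None = None,
    quad_points: int = 15,
    tol: float = 1e-8,
    fast: bool = False,
    compute_vcov: bool = True,
) -> MixedLogisticFit:
    """Fit the participant-random-intercept logistic model to foot data.

    Parameters
    ----------
    data
        Validated foot-level dataset (two feet per participant cluster).
    spec
        Functional form; default is the adjusted, centered quadratic.
    quad_points
        Adaptive Gauss-Hermite nodes for the marginal likelihood
        (1 = Laplace).
    fast
        Use the PIRLS/Laplace profile path only (bootstrap workhorse);
        implies ``quad_points=1`` for the returned objective value.
    """
    spec = spec or ModelSpec()
    X, y, codes, centering, names = build_design(data, spec)
    core = fit_core(
        X, y, codes, quad_points=1 if fast else quad_points, tol=tol,
        fast=fast, compute_vcov=compute_vcov,
    )
    vcov = (
        core.vcov if core.vcov is not None
        else np.full((len(names), len(names)), np.nan)
    )
    fit = MixedLogisticFit(
        beta=core.beta,
        names=names,
        se=np.sqrt(np.clip(np.diag(vcov), 0.0, None)),
        vcov=vcov,
        sigma_u=core.sigma_u,
        loglik=core.loglik,
        n_obs=len(y),
        n_groups=len(np.unique(codes)),
        centering=centering,
        converged=core.converged,
        quadrature_points=1 if fast else quad_points,
        spec=spec,
        fingerprint=_fingerprint(y, codes),
    )
    if not fit.converged:
        import warnings

        warnings.warn(
            "mixed-logit optimizer did not report convergence",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


def fit_null_model(
    data: Dataset, quad_points: int = 15, tol: float = 1e-8
) -> MixedLogisticFit:
    """Intercept-plus-random-intercept model: the null for pseudo-R^2."""
    spec = ModelSpec(degree=1, adjust=False)
    X, y, codes, _, _ = build_design(data, spec)
    core = fit_core(X[:, :1], y, codes, quad_points=quad_points, tol=tol,
                    compute_vcov=False)
    vcov = np.full((1, 1), np.nan)
    return MixedLogisticFit(
        beta=core.beta,
        names=["intercept"],
        se=np.full(1, np.nan),
        vcov=vcov,
        sigma_u=core.sigma_u,
        loglik=core.loglik,
        n_obs=len(y),
        n_groups=len(np.unique(codes)),
        centering={"ssndt_mean": 0.0, "load_mean": 0.0, "exp_mean": 0.0},
        converged=core.converged,
        quadrature_points=quad_points,
        spec=spec,
        fingerprint=_fingerprint(y, codes),
    )


def fit_indices(
    fit: MixedLogisticFit, null_fit: MixedLogisticFit
) -> FitIndices:
    """AIC/BIC/deviance and Nagelkerke pseudo-R^2 for a fitted model.

    The null model is the intercept-plus-random-intercept fit on the same
    rows; Cox-Snell R^2 = 1 - exp((2/n)(ll0 - ll1)) is rescaled by its
    maximum 1 - exp((2/n) ll0) to give Nagelkerke's index.
    """
    if fit.fingerprint != null_fit.fingerprint or fit.n_obs != null_fit.n_obs:
        raise ComparisonError("fits were not estimated on the same rows")
    n = fit.n_obs
    k = fit.n_params
    ll1, ll0 = fit.loglik, null_fit.loglik
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_cs = 1.0 - np.exp((2.0 / n) * ll0)
    return FitIndices(
        aic=-2.0 * ll1 + 2.0 * k,
        bic=-2.0 * ll1 + k * np.log(n),
        nagelkerke_r2=float(cox_snell / max_cs),
        deviance=-2.0 * ll1,
        cox_snell_r2=float(cox_snell),
    )


def likelihood_ratio_test(
    fit_small: MixedLogisticFit, fit_big: MixedLogisticFit
) -> tuple[float, int, float]:
    """LRT of nested fixed-effect specifications on identical rows."""
    if not fit_small.spec.is_nested_in(fit_big.spec):
        raise ValueError(
            f"{fit_small.spec} is not nested in {fit_big.spec}"
        )
    if fit_small.fingerprint != fit_big.fingerprint:
        raise ComparisonError("fits were not estimated on the same rows")
    stat = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    df = len(fit_big.beta) - len(fit_small.beta)
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def predict_probability(
    fit: MixedLogisticFit,
    ssndt_mm: float | np.ndarray,
    load: float | None = None,
    experience: float | None = None,
    conditional_u: float = 0.0,
) -> float | np.ndarray:
    """Predicted injury probability at a raw-scale SSNDT value.

    Covariates default to their stored sample means, where their centered
    contributions vanish; ``conditional_u`` evaluates at a given random
    intercept (0 = the median participant).
    """
    c = fit.centering
    x = np.asarray(ssndt_mm, float)
    xc = x - c["ssndt_mean"]
    eta = np.full_like(xc, fit.coef("intercept"), dtype=float)
    for d, name in enumerate(["ssndt", "ssndt2", "ssndt3"][: fit.spec.degree],
                             start=1):
        eta = eta + fit.coef(name) * xc**d
    if fit.spec.adjust:
        load_c = (load if load is not None else c["load_mean"]) - c["load_mean"]
        exp_c = (
            (experience if experience is not None else c["exp_mean"])
            - c["exp_mean"]
        )
        eta = eta + fit.coef("load") * load_c + fit.coef("experience") * exp_c
    out = special.expit(eta + conditional_u)
    return float(out) if np.isscalar(ssndt_mm) else out
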