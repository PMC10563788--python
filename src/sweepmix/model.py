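"""Two-component Gaussian mixture density regression (MDR) for selection scans.

The response ``Y`` (z-scored log of the window mean \\|iHS\\|) is modelled as a
mixture of two Gaussians: a background component ``N(mu0, sigma0)`` dominated
by drift, and a selection-enriched component ``N(mu1, sigma1)`` with
``mu1 > mu0``.  The mixing probability of the enriched component depends on
standardized genomic covariates through a logistic link::

    p = sigmoid(a + sum_i b_i * x_i)
    P(y | x) = p * N(y | mu1, sigma1) + (1 - p) * N(y | mu0, sigma0)

Parameters are estimated by direct maximum likelihood (L-BFGS-B with an
analytic gradient, multi-start).  Each covariate's slope is tested with a
likelihood-ratio test against the nested model without that covariate,
referred to the chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MDRParameters:
    """Full parameter set of the mixture density regression.

    ``intercept`` is the baseline logit of the selection-enriched component;
    ``slopes`` holds one coefficient per (standardized) covariate.  The
    ordering constraint ``mu1 >= mu0`` resolves label switching: component 1
    is always the high-mean, selection-enriched component.
    """

    intercept: float
    slopes: np.ndarray
    mu0: float
    sigma0: float
    mu1: float
    sigma1: float

    def __post_init__(self) -> None:
        slopes = np.atleast_1d(np.asarray(self.slopes, dtype=float))
        object.__setattr__(self, "slopes", slopes)
        for name in ("intercept", "mu0", "sigma0", "mu1", "sigma1"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("intercept", "mu0", "sigma0", "mu1", "sigma1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not np.all(np.isfinite(slopes)):
            raise ValueError("slopes must be finite")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigma0 and sigma1 must be > 0")
        if self.mu1 < self.mu0:
            raise ValueError(
                "mu1 must be >= mu0 (component 1 is the high-mean, "
                "selection-enriched component)"
            )

    @property
    def n_covariates(self) -> int:
        return self.slopes.shape[0]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_mdr`.

    ``restarts`` counts optimizer starts: the first uses a deterministic
    quantile-based initialization, the rest jitter it with an RNG seeded by
    ``seed``.  Tolerances map onto scipy's L-BFGS-B ``ftol``/``gtol``.
    """

    restarts: int = 5
    seed: int = 0
    max_iter: int = 2000
    ftol: float = 1e-9
    gtol: float = 1e-6
    jitter_scale: float = 0.3
    init_intercept_p: float = 0.25  # baseline enriched-component probability

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not 0 < self.init_intercept_p < 1:
            raise ValueError("init_intercept_p must be in (0, 1)")


@dataclass
class MDRFit:
    """Result of a maximum-likelihood fit."""

    params: MDRParameters
    loglik: float
    converged: bool
    n_restarts_used: int
    per_window_p: np.ndarray
    covariate_names: list[str]
    degenerate: bool = False
    n_windows: int = 0


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a single covariate's slope (chi2, 1 df)."""

    covariate_name: str
    slope: float
    lr_statistic: float
    pvalue: float
    loglik_full: float
    loglik_null: float


# ---------------------------------------------------------------------------
# Input coercion
# ---------------------------------------------------------------------------

def _as_design(X) -> tuple[np.ndarray, list[str]]:
    """Coerce a DataFrame or 2-D array to (matrix, column names)."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i + 1}" for i in range(mat.shape[1])]
    if mat.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    if not np.all(np.isfinite(mat)):
        raise ValueError("design matrix contains non-finite values; "
                         "apply complete-case filtering first")
    return mat, names


def _as_response(Y, n_rows: int) -> np.ndarray:
    y = np.asarray(Y, dtype=float).ravel()
    if y.shape[0] != n_rows:
        raise ValueError(
            f"response length {y.shape[0]} does not match design rows {n_rows}"
        )
    if y.shape[0] == 0:
        raise ValueError("empty dataset: zero windows")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    return y


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def mixing_probability(params: MDRParameters, x) -> float | np.ndarray:
    """Probability of the selection-enriched component, ``sigmoid(a + b.x)``.

    ``x`` may be a single covariate row or an ``n x k`` matrix; the return
    matches (scalar or length-n vector).  Computed through
    ``scipy.special.expit`` so it is stable for arbitrarily large linear
    predictors, and clipped to the open interval (0, 1) at the closest
    representable doubles.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    mat = x[None, :] if scalar else x
    k = params.n_covariates
    if mat.shape[1] != k:
        raise ValueError(
            f"covariate row has length {mat.shape[1]}, expected {k} "
            f"(one value per slope)"
        )
    eta = params.intercept + mat @ params.slopes
    p = special.expit(eta)
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return float(p[0]) if scalar else p


def _norm_logpdf(y: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (y - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI


def _log_terms(params: MDRParameters, X: np.ndarray, y: np.ndarray):
    """Per-window log densities of both weighted components (log-space)."""
    eta = params.intercept + X @ params.slopes
    log_p = -np.logaddexp(0.0, -eta)      # log sigmoid(eta)
    log_1mp = -np.logaddexp(0.0, eta)     # log (1 - sigmoid(eta))
    l1 = log_p + _norm_logpdf(y, params.mu1, params.sigma1)
    l0 = log_1mp + _norm_logpdf(y, params.mu0, params.sigma0)
    return l0, l1


def log_likelihood(params: MDRParameters, X, Y) -> float:
    """Total mixture log-likelihood, summed over windows.

    Uses log-sum-exp per window, so observations far in one component's tail
    do not underflow.
    """
    mat, _ = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    l0, l1 = _log_terms(params, mat, y)
    return float(np.logaddexp(l0, l1).sum())


def responsibilities(params: MDRParameters, X, Y) -> np.ndarray:
    """Posterior probability per window of the selection-enriched component.

    ``r = p N1 / (p N1 + (1-p) N0)``, evaluated in log-space so degenerate
    tail observations never produce NaN.
    """
    mat, _ = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    l0, l1 = _log_terms(params, mat, y)
    return np.exp(l1 - np.logaddexp(l0, l1))


def component_magnitude(fit: MDRFit) -> float:
    """Mean over windows of the enriched-component probability p.

    Used as the overall magnitude of the selection-enriched component.
    """
    p = np.asarray(fit.per_window_p, dtype=float)
    if p.size == 0:
        raise ValueError("fit has no per-window probabilities")
    return float(p.mean())


def single_gaussian_loglik(Y) -> float:
    """Log-likelihood of the single-Gaussian MLE (mean, population SD)."""
    y = np.asarray(Y, dtype=float).ravel()
    n = y.shape[0]
    var = float(np.var(y))
    if var <= 0:
        raise ValueError("degenerate response: zero variance")
    return -0.5 * n * (_LOG_2PI + math.log(var) + 1.0)


# ---------------------------------------------------------------------------
# Unconstrained reparameterization
#   theta = (a, b_1..b_k, mu0, log sigma0, delta, log sigma1),
#   mu1 = mu0 + exp(delta)  => sigma > 0 and mu1 > mu0 by construction.
# ---------------------------------------------------------------------------

def _pack(params: MDRParameters) -> np.ndarray:
    gap = params.mu1 - params.mu0
    if gap <= 0:
        raise ValueError("cannot pack parameters with mu1 <= mu0")
    return np.concatenate([
        [params.intercept],
        params.slopes,
        [params.mu0, math.log(params.sigma0), math.log(gap),
         math.log(params.sigma1)],
    ])


def _unpack(theta: np.ndarray, k: int) -> MDRParameters:
    a = theta[0]
    b = theta[1:k + 1]
    mu0 = theta[k + 1]
    sigma0 = math.exp(theta[k + 2])
    mu1 = mu0 + math.exp(theta[k + 3])
    sigma1 = math.exp(theta[k + 4])
    return MDRParameters(a, b, mu0, sigma0, mu1, sigma1)


def _nll_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    k = X.shape[1]
    a = theta[0]
    b = theta[1:k + 1]
    mu0 = theta[k + 1]
    s0 = math.exp(theta[k + 2])
    gap = math.exp(theta[k + 3])
    mu1 = mu0 + gap
    s1 = math.exp(theta[k + 4])

    eta = a + X @ b
    log_p = -np.logaddexp(0.0, -eta)
    log_1mp = -np.logaddexp(0.0, eta)
    z0 = (y - mu0) / s0
    z1 = (y - mu1) / s1
    l1 = log_p - 0.5 * z1 * z1 - math.log(s1) - 0.5 * _LOG_2PI
    l0 = log_1mp - 0.5 * z0 * z0 - math.log(s0) - 0.5 * _LOG_2PI
    ll_i = np.logaddexp(l0, l1)
    r = np.exp(l1 - ll_i)           # responsibility of enriched component
    p = np.exp(log_p)

    g_eta = r - p                    # d loglik / d eta per window
    grad = np.empty(k + 5)
    grad[0] = g_eta.sum()
    grad[1:k + 1] = X.T @ g_eta
    w0 = (1.0 - r) * z0 / s0
    w1 = r * z1 / s1
    grad[k + 1] = w0.sum() + w1.sum()
    grad[k + 2] = ((1.0 - r) * (z0 * z0 - 1.0)).sum()
    grad[k + 3] = gap * w1.sum()
    grad[k + 4] = (r * (z1 * z1 - 1.0)).sum()
    return -float(ll_i.sum()), -grad


def _default_init(y: np.ndarray, k: int, config: FitConfig) -> np.ndarray:
    sd = float(np.std(y, ddof=1)) if y.size > 1 else 1.0
    sd = max(sd, 1e-8)
    mu0 = float(np.quantile(y, 0.40))
    mu1 = float(np.quantile(y, 0.90))
    gap = max(mu1 - mu0, 0.05 * sd)
    a0 = float(special.logit(config.init_intercept_p))
    theta0 = np.zeros(k + 5)
    theta0[0] = a0
    theta0[k + 1] = mu0
    theta0[k + 2] = math.log(sd)
    theta0[k + 3] = math.log(gap)
    theta0[k + 4] = math.log(sd)
    return theta0


def fit_mdr(X, Y, config: FitConfig | None = None,
            init: MDRParameters | None = None) -> MDRFit:
    """Maximum-likelihood fit of the mixture density regression.

    Multi-start L-BFGS-B on the unconstrained reparameterization; the best
    log-likelihood wins (ties: first occurrence).  ``init`` overrides the
    deterministic first start (used internally to warm-start nested refits).
    """
    config = config or FitConfig()
    mat, names = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    n, k = mat.shape
    if n < 10 * (k + 5):
        warnings.warn(
            f"only {n} windows for {k + 5} free parameters; "
            f"recommend n >= {10 * (k + 5)}",
            stacklevel=2,
        )

    theta0 = _pack(init) if init is not None else _default_init(y, k, config)
    rng = np.random.default_rng(config.seed)
    options = {"maxiter": config.max_iter, "ftol": config.ftol,
               "gtol": config.gtol, "maxfun": 10 * config.max_iter}
    # box-bound the log-scale parameters so exp() cannot overflow; the box
    # (e^-20, e^20) is far wider than any standardized-response fit visits
    bounds = [(None, None)] * (k + 2) + [(-20.0, 20.0)] * 3

    best = None
    best_nll = np.inf
    any_success = False
    for start in range(config.restarts):
        t0 = theta0 if start == 0 else theta0 + rng.normal(
            scale=config.jitter_scale, size=theta0.shape)
        res = optimize.minimize(_nll_and_grad, t0, args=(mat, y),
                                method="L-BFGS-B", jac=True, bounds=bounds,
                                options=options)
        any_success = any_success or bool(res.success)
        if res.fun < best_nll:
            best_nll = res.fun
            best = res
    if best is None:  # pragma: no cover - minimize always returns
        raise RuntimeError("optimization produced no result")
    if not any_success:
        warnings.warn("L-BFGS-B did not report convergence on any restart",
                      stacklevel=2)

    params = _unpack(best.x, k)
    loglik = -best_nll
    p = mixing_probability(params, mat)
    fit = MDRFit(params=params, loglik=loglik, converged=any_success,
                 n_restarts_used=config.restarts, per_window_p=p,
                 covariate_names=names, n_windows=n)
    fit.degenerate = _is_degenerate(fit, y)
    if fit.degenerate:
        logger.warning(
            "degenerate mixture fit: components are not separated "
            "(mu1-mu0=%.4g, mean p=%.4g); slopes are unidentifiable",
            params.mu1 - params.mu0, float(p.mean()))
    return fit


def _is_degenerate(fit: MDRFit, y: np.ndarray) -> bool:
    """Detect a collapsed mixture (single-Gaussian-equivalent fit).

    Under collapse the mixing weights — hence intercept and slopes — are
    unidentifiable, so the fit is flagged rather than reported as a genuine
    two-component solution.  Triggers on any of: effective separation
    (mu1 - mu0) / pooled sigma below 0.5; mean p outside [0.01, 0.99] (one
    component carries almost no weight); log-likelihood gain over the
    single-Gaussian MLE below the number of extra parameters (k + 3), the
    scale on which a flexible but unneeded mixture overfits pure noise.
    """
    p = fit.params
    pooled = math.sqrt((p.sigma0 ** 2 + p.sigma1 ** 2) / 2.0)
    if (p.mu1 - p.mu0) / pooled < 0.5:
        return True
    mean_p = float(np.mean(fit.per_window_p))
    if mean_p < 0.01 or mean_p > 0.99:
        return True
    try:
        gain = fit.loglik - single_gaussian_loglik(y)
    except ValueError:
        return True
    return gain < p.n_covariates + 3


# ---------------------------------------------------------------------------
# Likelihood-ratio tests
# ---------------------------------------------------------------------------

def _drop_column(params: MDRParameters, idx: int) -> MDRParameters:
    return replace(params, slopes=np.delete(params.slopes, idx))


def lrt_covariate(X, Y, covariate: str, config: FitConfig | None = None,
                  full_fit: MDRFit | None = None) -> LRTResult:
    """LRT of one covariate: full model vs nested model without that column.

    The nested model re-optimizes every remaining parameter, warm-started
    from the full-model solution.  The statistic ``2 (llf - lln)`` is clipped
    at 0 (it is nonnegative up to numerical noise) and referred to chi2(1).
    """
    config = config or FitConfig()
    mat, names = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    if covariate not in names:
        raise KeyError(
            f"covariate {covariate!r} not found; available: {names}")
    idx = names.index(covariate)

    if full_fit is None:
        full_fit = fit_mdr(pd.DataFrame(mat, columns=names), y, config)
    null_X = np.delete(mat, idx, axis=1)
    null_names = [nm for nm in names if nm != covariate]
    warm = _drop_column(full_fit.params, idx)
    null_fit = fit_mdr(pd.DataFrame(null_X, columns=null_names), y, config,
                       init=warm)

    lr = max(0.0, 2.0 * (full_fit.loglik - null_fit.loglik))
    pval = float(stats.chi2.sf(lr, df=1))
    return LRTResult(covariate_name=covariate,
                     slope=float(full_fit.params.slopes[idx]),
                     lr_statistic=lr, pvalue=pval,
                     loglik_full=full_fit.loglik,
                     loglik_null=null_fit.loglik)


def _fit_without_intercept(X, Y, config: FitConfig,
                           full_fit: MDRFit) -> float:
    """Loglik of the nested model with the intercept fixed at 0."""
    mat, _ = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    k = mat.shape[1]

    def nll(theta_red):
        theta = np.concatenate([[0.0], theta_red])
        f, g = _nll_and_grad(theta, mat, y)
        return f, g[1:]

    warm = _pack(full_fit.params)[1:]
    bounds = [(None, None)] * (k + 1) + [(-20.0, 20.0)] * 3
    res = optimize.minimize(nll, warm, method="L-BFGS-B", jac=True,
                            bounds=bounds,
                            options={"maxiter": config.max_iter,
                                     "ftol": config.ftol,
                                     "gtol": config.gtol})
    return -float(res.fun)


def lrt_all_covariates(X, Y, config: FitConfig | None = None,
                       bh_correction: bool = False,
                       test_intercept: bool = False) -> tuple[MDRFit, pd.DataFrame]:
    """Full fit plus one LRT row per covariate (optionally the intercept).

    Returns the full fit and a table with columns covariate, slope,
    lr_statistic, pvalue (and qvalue when ``bh_correction``); raw p-values
    are reported by default.
    """
    config = config or FitConfig()
    mat, names = _as_design(X)
    y = _as_response(Y, mat.shape[0])
    Xdf = pd.DataFrame(mat, columns=names)
    full = fit_mdr(Xdf, y, config)

    rows = []
    if test_intercept:
        ll_null = _fit_without_intercept(Xdf, y, config, full)
        lr = max(0.0, 2.0 * (full.loglik - ll_null))
        rows.append({"covariate": "intercept",
                     "slope": full.params.intercept,
                     "lr_statistic": lr,
                     "pvalue": float(stats.chi2.sf(lr, df=1))})
    for name in names:
        res = lrt_covariate(Xdf, y, name, config, full_fit=full)
        rows.append({"covariate": name, "slope": res.slope,
                     "lr_statistic": res.lr_statistic,
                     "pvalue": res.pvalue})
    table = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests
        table["qvalue"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    return full, table
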