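"""Zero-inflated Conway-Maxwell-Poisson (ZICMP) mixed-effects regression.

The model for a pain score y_it of patient i at time t (s = t/96 scaled):

  P(y = 0)     = pi(s) + (1 - pi(s)) / Z(lam, nu)
  P(y = k > 0) = (1 - pi(s)) * lam^k / ((k!)^nu * Z(lam, nu))

with logit pi(s) = gamma0 + gamma1 s + gamma2 s^2 (zero-inflation sub-model:
the structural probability of *not* experiencing pain), and
log lam = beta0 + beta1 s + beta2 s^2 + b_i (count sub-model: intensity of
pain when experienced), b_i ~ Normal(0, sigma_b^2) a patient random
intercept. nu is the CMP dispersion: nu = 1 is Poisson, nu < 1
over-dispersed, nu -> 0 geometric (requires lam < 1).

The per-patient random intercept is integrated out of the likelihood by a
Laplace approximation at the per-patient conditional mode (adaptive
Gauss-Hermite quadrature available as a higher-accuracy alternative and as
a cross-check). Estimation is by quasi-Newton maximum likelihood with
multiple documented starting points; standard errors come from the inverse
observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

logger = logging.getLogger(__name__)

# Normalizing-constant truncation: relative tolerance and hard term cap.
_Z_RTOL = 1e-12
_Z_MAX_TERMS = 10_000
_CHUNK = 64


@dataclass(frozen=True)
class CmpParams:
    """Conway-Maxwell-Poisson parameters (rate-like lam > 0, dispersion nu >= 0)."""

    lam: float
    nu: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if self.nu == 0 and self.lam >= 1:
            raise ValueError("nu = 0 requires lam < 1 for a finite normalizing constant")


def _cmp_sums(log_lam: np.ndarray, nu: float):
    """log Z, mean and variance of CMP(lam, nu), vectorized over log_lam.

    The series Z = sum_j lam^j / (j!)^nu is accumulated in log space
    (streaming log-sum-exp) together with sum j * term and sum j^2 * term,
    truncated once the current term falls below 1e-12 of the running sum
    past the series mode, with a hard cap of 10^4 terms.
    """
    log_lam = np.atleast_1d(np.asarray(log_lam, dtype=float))
    if nu == 0 and np.any(log_lam >= 0):
        raise ValueError("nu = 0 requires lam < 1")
    # series mode ~ lam^(1/nu); terms decrease beyond it
    mode = float(np.exp(np.max(log_lam) / nu)) if nu > 0 else 0.0
    n_terms = int(min(mode + 12.0 * np.sqrt(mode + 1.0) + 40.0, _Z_MAX_TERMS))
    while True:
        j = np.arange(n_terms, dtype=float)
        t = np.multiply.outer(j, log_lam)
        t -= (nu * special.gammaln(j + 1.0))[:, None]
        peak = t.max(axis=0)
        t -= peak
        w = np.exp(t, out=t)  # scaled so the largest term is 1; no overflow
        s0 = w.sum(axis=0)
        s1 = j @ w
        s2 = (j * j) @ w
        converged = np.all(w[-1] < _Z_RTOL * s0)
        if converged or n_terms >= _Z_MAX_TERMS:
            break
        n_terms = min(n_terms * 2, _Z_MAX_TERMS)
    if not converged:
        raise FloatingPointError(
            f"CMP normalizing constant did not converge within {_Z_MAX_TERMS} terms "
            f"(max log lam = {np.max(log_lam):.3f}, nu = {nu:.4f})"
        )
    m0 = peak + np.log(s0)
    mean = s1 / s0
    var = np.maximum(s2 / s0 - mean**2, 0.0)
    return m0, mean, var


def cmp_log_pmf(y, params: CmpParams):
    """Log pmf of CMP: y log(lam) - nu log(y!) - log Z(lam, nu)."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be non-negative integers")
    log_z, _, _ = _cmp_sums(np.log(params.lam), params.nu)
    out = y * np.log(params.lam) - params.nu * special.gammaln(y + 1.0) - log_z[0]
    return out if out.shape else float(out)


def cmp_mean(params: CmpParams) -> float:
    """E[Y] for CMP(lam, nu), by the same truncated summation as the pmf."""
    _, mean, _ = _cmp_sums(np.log(params.lam), params.nu)
    return float(mean[0])


def cmp_var(params: CmpParams) -> float:
    """Var[Y] for CMP(lam, nu)."""
    _, _, var = _cmp_sums(np.log(params.lam), params.nu)
    return float(var[0])


def cmp_pmf_vector(params: CmpParams, y_max: int) -> np.ndarray:
    """pmf over 0..y_max (used by the synthetic generator's sampler)."""
    return np.exp(cmp_log_pmf(np.arange(y_max + 1), params))


@dataclass
class ZicmpSpec:
    """Model specification: polynomial time degree per sub-model, time scaling.

    Time enters as s = t / window_h so coefficients stay O(1). Degree 2
    (linear + quadratic time) in both sub-models is the default.
    """

    count_degree: int = 2
    zi_degree: int = 2
    window_h: float = 96.0
    random_intercept: bool = True

    def count_design(self, time_h: np.ndarray) -> np.ndarray:
        s = np.asarray(time_h, float) / self.window_h
        return np.column_stack([s**d for d in range(self.count_degree + 1)])

    def zi_design(self, time_h: np.ndarray) -> np.ndarray:
        s = np.asarray(time_h, float) / self.window_h
        return np.column_stack([s**d for d in range(self.zi_degree + 1)])


@dataclass
class ZicmpFit:
    """Maximum-likelihood ZICMP fit: coefficients, dispersion, random-intercept SD."""

    beta: np.ndarray
    gamma: np.ndarray
    nu: float
    sigma_b: float
    loglik: float
    converged: bool
    spec: ZicmpSpec
    n_patients: int
    n_obs: int
    se: Optional[dict] = None
    cov: Optional[np.ndarray] = None
    b_modes: Optional[np.ndarray] = None
    patient_ids: Optional[list] = None
    n_starts: int = 1
    message: str = ""

    def coefficient_table(self):
        import pandas as pd

        rows = []
        for i, b in enumerate(self.beta):
            rows.append(("count", f"s^{i}", b, None if self.se is None else self.se["beta"][i]))
        for i, g in enumerate(self.gamma):
            rows.append(("zero_inflation", f"s^{i}", g, None if self.se is None else self.se["gamma"][i]))
        rows.append(("dispersion", "nu", self.nu, None if self.se is None else self.se["nu"]))
        rows.append(("random_intercept", "sigma_b", self.sigma_b,
                     None if self.se is None else self.se["sigma_b"]))
        return pd.DataFrame(rows, columns=["submodel", "term", "estimate", "se"])


class _ZicmpData:
    """Flattened observation arrays with per-patient indexing."""

    def __init__(self, series, spec: ZicmpSpec):
        ids, times, scores = [], [], []
        self.patient_ids = []
        for s in series:
            self.patient_ids.append(s.patient_id)
            for o in s.observations:
                ids.append(len(self.patient_ids) - 1)
                times.append(o.time_h)
                scores.append(o.score)
        self.pid = np.asarray(ids, dtype=np.intp)
        self.y = np.asarray(scores, dtype=float)
        self.time_h = np.asarray(times, dtype=float)
        self.Xc = spec.count_design(self.time_h)
        self.Xz = spec.zi_design(self.time_h)
        self.n_patients = len(self.patient_ids)
        self.n_obs = len(self.y)
        self.is_zero = self.y == 0
        self.lgamma_y = special.gammaln(self.y + 1.0)


def _conditional_parts(data: _ZicmpData, eta, log1mpi, logpi, nu, b):
    """Per-observation loglik and first/second b-derivatives at offsets b.

    eta is the count linear predictor without b; b is per-patient, expanded
    to observations. Returns (ll, d1, d2) as per-observation arrays.
    """
    log_lam = eta + b[data.pid]
    log_z, m, v = _cmp_sums(log_lam, nu)
    ll = np.empty(data.n_obs)
    d1 = np.empty(data.n_obs)
    d2 = np.empty(data.n_obs)

    pos = ~data.is_zero
    ll[pos] = log1mpi[pos] + data.y[pos] * log_lam[pos] - nu * data.lgamma_y[pos] - log_z[pos]
    d1[pos] = data.y[pos] - m[pos]
    d2[pos] = -v[pos]

    z = data.is_zero
    log_p0 = np.logaddexp(logpi[z], log1mpi[z] - log_z[z])
    ll[z] = log_p0
    # q = share of the zero mass coming from the count component
    q = np.exp(log1mpi[z] - log_z[z] - log_p0)
    d1[z] = -q * m[z]
    d2[z] = q * m[z] ** 2 * (1.0 - q) - q * v[z]
    return ll, d1, d2


def _patient_mode(data: _ZicmpData, eta, log1mpi, logpi, nu, sigma_b,
                  b0=None, max_iter=40, tol=1e-8):
    """Newton (damped) per-patient modes of the joint log-density in b, vectorized."""
    n = data.n_patients
    b = np.zeros(n) if b0 is None else np.array(b0, dtype=float)
    inv_s2 = 1.0 / sigma_b**2
    for _ in range(max_iter):
        ll, d1, d2 = _conditional_parts(data, eta, log1mpi, logpi, nu, b)
        g = np.bincount(data.pid, weights=d1, minlength=n) - b * inv_s2
        h = np.bincount(data.pid, weights=d2, minlength=n) - inv_s2
        h = np.minimum(h, -1e-8)  # safeguard non-concave patches
        if np.max(np.abs(g)) < tol:
            break
        step = g / (-h)
        np.clip(step, -2.0, 2.0, out=step)
        b += step
    return b, g, h, ll


_LOG_2PI = np.log(2.0 * np.pi)


def _loglik_arrays(data: _ZicmpData, beta, gamma, nu, sigma_b,
                   method="laplace", agq_nodes=20, return_modes=False, b0=None):
    eta = data.Xc @ beta
    zi_eta = data.Xz @ gamma
    # stable log pi / log(1 - pi)
    logpi = -np.logaddexp(0.0, -zi_eta)
    log1mpi = -np.logaddexp(0.0, zi_eta)

    if sigma_b < 1e-8:
        ll, _, _ = _conditional_parts(data, eta, log1mpi, logpi, nu,
                                      np.zeros(data.n_patients))
        per_patient = np.bincount(data.pid, weights=ll, minlength=data.n_patients)
        return (per_patient, np.zeros(data.n_patients)) if return_modes else per_patient

    b_hat, _, h, ll = _patient_mode(data, eta, log1mpi, logpi, nu, sigma_b, b0=b0)
    # joint log-density at the mode: sum_t ll + log phi(b; 0, sigma^2)
    log_prior = -0.5 * (b_hat / sigma_b) ** 2 - np.log(sigma_b) - 0.5 * _LOG_2PI
    g_at_mode = np.bincount(data.pid, weights=ll, minlength=data.n_patients) + log_prior

    if method == "laplace":
        per_patient = g_at_mode + 0.5 * _LOG_2PI - 0.5 * np.log(-h)
    elif method == "agq":
        x, w = hermgauss(agq_nodes)
        tau = 1.0 / np.sqrt(-h)
        acc = np.full(data.n_patients, -np.inf)
        for xk, wk in zip(x, w):
            bk = b_hat + np.sqrt(2.0) * tau * xk
            llk, _, _ = _conditional_parts(data, eta, log1mpi, logpi, nu, bk)
            gk = (np.bincount(data.pid, weights=llk, minlength=data.n_patients)
                  - 0.5 * (bk / sigma_b) ** 2 - np.log(sigma_b) - 0.5 * _LOG_2PI)
            acc = np.logaddexp(acc, np.log(wk) + xk**2 + gk)
        per_patient = acc + 0.5 * np.log(2.0) + np.log(tau)
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return (per_patient, b_hat) if return_modes else per_patient


def zicmp_loglik(params, series_or_data, spec: Optional[ZicmpSpec] = None,
                 method: str = "laplace", agq_nodes: int = 20) -> float:
    """Marginal log-likelihood of a ZICMP mixed model.

    ``params`` is a dict with keys beta, gamma, nu, sigma_b. The patient
    random intercept is integrated out by Laplace approximation at the
    conditional mode (``method='laplace'``) or by adaptive Gauss-Hermite
    quadrature centred and scaled at that mode (``method='agq'``).
    """
    spec = spec or ZicmpSpec()
    data = series_or_data if isinstance(series_or_data, _ZicmpData) else _ZicmpData(series_or_data, spec)
    per_patient = _loglik_arrays(
        data, np.asarray(params["beta"], float), np.asarray(params["gamma"], float),
        float(params["nu"]), float(params["sigma_b"]), method=method, agq_nodes=agq_nodes,
    )
    return float(np.sum(per_patient))


def _pack(beta, gamma, log_nu, log_sigma, fix_nu, fix_sigma_b, zero_inflation):
    v = list(beta)
    if zero_inflation:
        v += list(gamma)
    if fix_nu is None:
        v.append(log_nu)
    if fix_sigma_b is None:
        v.append(log_sigma)
    return np.asarray(v, float)


def _unpack(theta, p_c, p_z, fix_nu, fix_sigma_b, zero_inflation):
    i = 0
    beta = theta[i:i + p_c]; i += p_c
    if zero_inflation:
        gamma = theta[i:i + p_z]; i += p_z
    else:
        gamma = np.full(p_z, -30.0)  # pi ~ 0
    nu = np.exp(theta[i]) if fix_nu is None else fix_nu
    if fix_nu is None:
        i += 1
    sigma = np.exp(theta[i]) if fix_sigma_b is None else fix_sigma_b
    return beta, gamma, nu, sigma


def _poisson_warm_start(data: _ZicmpData, zero_inflation: bool):
    """Poisson GLM on the count design; empirical zero share for the ZI intercept."""
    import statsmodels.api as sm

    res = sm.GLM(data.y, data.Xc, family=sm.families.Poisson()).fit()
    beta = np.asarray(res.params)
    p0 = np.clip(np.mean(data.is_zero), 0.02, 0.9)
    gamma = np.zeros(data.Xz.shape[1])
    gamma[0] = np.log(p0 / (1 - p0))
    return beta, gamma


def fit_zicmp(
    series,
    spec: Optional[ZicmpSpec] = None,
    init: Optional[dict] = None,
    starts: str = "default",
    fix_nu: Optional[float] = None,
    fix_sigma_b: Optional[float] = None,
    zero_inflation: bool = True,
    method: str = "laplace",
    maxiter: int = 400,
    gtol: float = 1e-3,
    ftol: float = 1e-8,
    seed: int = 0,
    compute_se: bool = True,
) -> ZicmpFit:
    """Fit the ZICMP mixed model by maximum likelihood.

    Starting points (``starts='default'``): the zero vector, a Poisson-GLM
    warm start, and three small random perturbations of the warm start; the
    best log-likelihood wins (ties -> first). ``starts='warm'`` uses the
    warm start only (useful in large simulation studies). An explicit
    ``init`` dict overrides the strategy. ``fix_nu``/``fix_sigma_b`` pin the
    dispersion or random-intercept SD (e.g. ``fix_nu=1, fix_sigma_b=0,
    zero_inflation=False`` reduces the model to a Poisson regression).
    """
    spec = spec or ZicmpSpec()
    data = _ZicmpData(series, spec)
    p_c, p_z = data.Xc.shape[1], data.Xz.shape[1]

    mode_cache = {"b": None}  # warm-starts the inner Newton across evaluations

    def negll(theta):
        beta, gamma, nu, sigma = _unpack(theta, p_c, p_z, fix_nu, fix_sigma_b, zero_inflation)
        if nu > 50 or sigma > 50:
            return 1e10
        try:
            out = _loglik_arrays(data, beta, gamma, nu, sigma, method=method,
                                 return_modes=True, b0=mode_cache["b"])
        except FloatingPointError:
            return 1e10
        per_patient, modes = out
        mode_cache["b"] = modes
        val = -float(np.sum(per_patient))
        return val if np.isfinite(val) else 1e10

    warm_beta, warm_gamma = _poisson_warm_start(data, zero_inflation)
    start_points = []
    if init is not None:
        start_points.append(_pack(
            init.get("beta", warm_beta), init.get("gamma", warm_gamma),
            np.log(init.get("nu", 1.0)), np.log(max(init.get("sigma_b", 0.3), 1e-3)),
            fix_nu, fix_sigma_b, zero_inflation))
    elif starts == "warm":
        start_points.append(_pack(warm_beta, warm_gamma, 0.0, np.log(0.3),
                                  fix_nu, fix_sigma_b, zero_inflation))
    else:
        start_points.append(_pack(np.zeros(p_c), np.zeros(p_z), 0.0, np.log(0.3),
                                  fix_nu, fix_sigma_b, zero_inflation))
        warm = _pack(warm_beta, warm_gamma, 0.0, np.log(0.3),
                     fix_nu, fix_sigma_b, zero_inflation)
        start_points.append(warm)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            start_points.append(warm + rng.normal(0.0, 0.1, size=warm.shape))

    best = None
    for x0 in start_points:
        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "gtol": gtol, "ftol": ftol})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta = best.x
    beta, gamma, nu, sigma = _unpack(theta, p_c, p_z, fix_nu, fix_sigma_b, zero_inflation)
    grad_norm = float(np.max(np.abs(
        optimize.approx_fprime(theta, negll, 1e-6 * np.maximum(np.abs(theta), 1.0)))))
    converged = bool(best.success) and grad_norm < 1e-2 * (1 + abs(best.fun))
    # gradient norm threshold scaled by |loglik| because finite differences on
    # large sums cannot reach machine-level gradients

    se = cov = None
    if compute_se:
        try:
            H = _numerical_hessian(negll, theta)
            cov = np.linalg.inv(H)
            d = np.sqrt(np.maximum(np.diag(cov), 0.0))
            se = _se_dict(d, p_c, p_z, fix_nu, fix_sigma_b, zero_inflation, nu, sigma)
        except np.linalg.LinAlgError:
            logger.warning("observed information not invertible; SEs unavailable")

    per_patient, b_modes = _loglik_arrays(data, beta, gamma, nu, sigma,
                                          method=method, return_modes=True)
    return ZicmpFit(
        beta=beta, gamma=gamma, nu=float(nu), sigma_b=float(sigma),
        loglik=float(np.sum(per_patient)), converged=converged, spec=spec,
        n_patients=data.n_patients, n_obs=data.n_obs, se=se, cov=cov,
        b_modes=b_modes, patient_ids=list(data.patient_ids),
        n_starts=len(start_points), message=str(best.message),
    )


def _numerical_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def _se_dict(d, p_c, p_z, fix_nu, fix_sigma_b, zero_inflation, nu, sigma):
    i = 0
    out = {"beta": d[i:i + p_c]}; i += p_c
    if zero_inflation:
        out["gamma"] = d[i:i + p_z]; i += p_z
    else:
        out["gamma"] = np.full(p_z, np.nan)
    if fix_nu is None:
        out["log_nu"] = d[i]; out["nu"] = d[i] * nu; i += 1  # delta method
    else:
        out["log_nu"] = out["nu"] = np.nan
    if fix_sigma_b is None:
        out["log_sigma_b"] = d[i]; out["sigma_b"] = d[i] * sigma
    else:
        out["log_sigma_b"] = out["sigma_b"] = np.nan
    return out


def _curves_at(spec: ZicmpSpec, beta, gamma, nu, grid, b=0.0):
    Xc = spec.count_design(grid)
    Xz = spec.zi_design(grid)
    log_lam = Xc @ beta + b
    zi_eta = Xz @ gamma
    pi = special.expit(zi_eta)
    log_z, m, _ = _cmp_sums(log_lam, nu)
    p_zero_count = np.exp(-log_z)  # P(Y=0) under the count component
    p_pain = (1.0 - pi) * (1.0 - p_zero_count)
    mean_y = (1.0 - pi) * m
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(p_pain > 0, mean_y / p_pain, np.nan)
    return pi, p_pain, mean_y, cond


def predict_decomposition(fit: ZicmpFit, grid=None, mode: str = "population",
                          force: bool = False):
    """Fitted trajectory decomposition on a time grid.

    Returns a DataFrame with, per grid time: the structural-zero probability
    ``pi``; the likelihood of experiencing pain ``p_pain`` = (1-pi)(1-1/Z);
    the unconditional mean ``mean_pain``; and the conditional intensity
    ``cond_intensity`` = mean_pain / p_pain (missing where p_pain = 0).

    ``mode='population'`` sets the random intercept to zero (the fixed-
    effects curve); ``mode='marginal'`` integrates the curves over the
    estimated random-intercept distribution by Gauss-Hermite quadrature and
    is labelled distinctly in the output.
    """
    import pandas as pd

    if not fit.converged and not force:
        raise RuntimeError("refusing to predict from an unconverged fit (pass force=True)")
    grid = np.arange(0.0, fit.spec.window_h + 1e-9, 1.0) if grid is None else np.asarray(grid, float)

    if mode == "population":
        pi, p_pain, mean_y, cond = _curves_at(fit.spec, fit.beta, fit.gamma, fit.nu, grid)
    elif mode == "marginal":
        x, w = hermgauss(20)
        w = w / np.sqrt(np.pi)
        pi = p_pain = mean_y = None
        acc_p = np.zeros_like(grid); acc_m = np.zeros_like(grid); acc_pi = np.zeros_like(grid)
        for xk, wk in zip(x, w):
            b = np.sqrt(2.0) * fit.sigma_b * xk
            pik, pk, mk, _ = _curves_at(fit.spec, fit.beta, fit.gamma, fit.nu, grid, b=b)
            acc_pi += wk * pik; acc_p += wk * pk; acc_m += wk * mk
        pi, p_pain, mean_y = acc_pi, acc_p, acc_m
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(p_pain > 0, mean_y / p_pain, np.nan)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return pd.DataFrame({
        "time_h": grid, "pi": pi, "p_pain": p_pain,
        "mean_pain": mean_y, "cond_intensity": cond, "mode": mode,
    })


def predict_subject_curves(fit: ZicmpFit, grid=None):
    """Per-patient curves at the estimated conditional modes b_i.

    Returns (grid, p_pain matrix, mean_pain matrix) with one row per
    patient; used for subject-level AUC profiling and for the
    conditional-prediction curve (the average of the per-patient
    conditional intensities).
    """
    if fit.b_modes is None:
        raise ValueError("fit carries no per-patient modes")
    grid = np.arange(0.0, fit.spec.window_h + 1e-9, 1.0) if grid is None else np.asarray(grid, float)
    p_rows, m_rows = [], []
    for b in fit.b_modes:
        _, p_pain, mean_y, _ = _curves_at(fit.spec, fit.beta, fit.gamma, fit.nu, grid, b=float(b))
        p_rows.append(p_pain); m_rows.append(mean_y)
    return grid, np.vstack(p_rows), np.vstack(m_rows)
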