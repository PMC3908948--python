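"""Gaussian-process drift model for analysis-order normalization.

Per-feature model: intensities x(t) observed at analysis orders t are one
realization of a Gaussian process

    x(t) ~ GP( mu0 + mu1 * t,  sigma^2 * R_nu(|t - t'|; ell) + sigma_eps^2 * delta )

with a Matern correlation R_nu of smoothness nu in {1/2, 3/2, 5/2}. The
linear mean absorbs the monotone component of instrument drift; the Matern
term captures the smooth nonlinear component; sigma_eps is white measurement
noise. The five parameters theta = [ell, sigma, sigma_eps, mu0, mu1] are
estimated by maximum likelihood on the quality-control (QC) runs, optionally
with the smoothness constraint ell_QC >= ell_S, where ell_S is the scale
fitted to experimental samples — QC drift may not vary faster than the
biological samples, which guards against overfitting the few QC points.

The API follows the statsmodels convention: build a :class:`GPDriftModel`
from data, call :meth:`~GPDriftModel.fit` to get a :class:`GPDriftResults`
carrying estimates, standard errors, diagnostics, prediction and plotting.
Module-level functions (:func:`fit_gprm`, :func:`predict_drift`,
:func:`gprm_normalize`, ...) are thin wrappers for pipeline use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve

from .data import MIN_QC_FIT, FeatureMatrix, SampleTable
from .exceptions import ConvergenceError, DegenerateDataError, ValidationError
from .results import NormalizationResult

logger = logging.getLogger(__name__)

VALID_NU = (0.5, 1.5, 2.5)

# ---------------------------------------------------------------------------
# Matern correlation
# ---------------------------------------------------------------------------


def matern_correlation(tau, ell: float, nu: float = 1.5, method: str = "closed"):
    """Matern correlation R(tau) for smoothness nu in {1/2, 3/2, 5/2}.

    ``method="closed"`` uses the half-integer closed forms; ``method="bessel"``
    evaluates the general expression
    ``2^(1-nu)/Gamma(nu) * (sqrt(2 nu) tau / ell)^nu * K_nu(sqrt(2 nu) tau / ell)``
    directly through the modified Bessel function — numerically independent of
    the closed forms, hence useful as a cross-check.
    """
    if ell <= 0:
        raise ValidationError(f"Matern scale ell must be > 0, got {ell}")
    if nu not in VALID_NU:
        raise ValidationError(f"nu must be one of {VALID_NU}, got {nu}")
    tau = np.abs(np.asarray(tau, dtype=float))
    if method == "bessel":
        u = np.sqrt(2.0 * nu) * tau / ell
        with np.errstate(invalid="ignore"):
            r = (2.0 ** (1.0 - nu) / special.gamma(nu)) * u**nu * special.kv(nu, u)
        return np.where(u == 0.0, 1.0, r)
    if method != "closed":
        raise ValidationError(f"unknown method {method!r}")
    if nu == 0.5:
        return np.exp(-tau / ell)
    if nu == 1.5:
        a = np.sqrt(3.0) * tau / ell
        return (1.0 + a) * np.exp(-a)
    a = np.sqrt(5.0) * tau / ell
    return (1.0 + a + a * a / 3.0) * np.exp(-a)


def _matern_dR_dell(tau, ell: float, nu: float):
    """d R(tau; ell, nu) / d ell (closed forms)."""
    tau = np.abs(np.asarray(tau, dtype=float))
    if nu == 0.5:
        a = tau / ell
        return a * np.exp(-a) / ell
    if nu == 1.5:
        a = np.sqrt(3.0) * tau / ell
        return a * a * np.exp(-a) / ell
    a = np.sqrt(5.0) * tau / ell
    return a * a * (1.0 + a) * np.exp(-a) / (3.0 * ell)


# ---------------------------------------------------------------------------
# Covariance and likelihood
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Matern smoothness and the diagonal jitter used for positive definiteness."""

    nu: float = 1.5
    jitter: float = 1e-8

    def __post_init__(self):
        if self.nu not in VALID_NU:
            raise ValidationError(f"nu must be one of {VALID_NU}, got {self.nu}")
        if self.jitter <= 0:
            raise ValidationError("jitter must be positive")


@dataclass
class FitConfig:
    """Optimizer settings for maximum-likelihood GP fitting.

    Bounds on (ell, sigma, sigma_eps) are enforced through a log
    parameterization, so the positivity constraints are strict. ``restarts``
    additional starts jitter the moment-based initial values multiplicatively
    (seeded). ``working_space`` selects whether matrix-level normalization
    models raw intensities or log(1 + x).
    """

    restarts: int = 5
    seed: int = 0
    maxiter: int = 200
    gtol: float = 1e-8
    working_space: str = "log"
    regularize: bool = True
    ell_max_factor: float = 100.0  # upper bound on ell as multiple of the order span
    # cross-feature noise moderation: measurement noise is an instrument
    # property shared across features, so per-feature sigma_eps estimates are
    # re-fitted within [lo, hi] x (ensemble median) when they fall outside —
    # the small-n guard against a noise-free fit interpolating the QC points
    moderate_noise: bool = True
    moderation_band: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self):
        if self.working_space not in ("log", "raw"):
            raise ValidationError("working_space must be 'log' or 'raw'")


@dataclass
class GPFit:
    """Fitted parameter vector and training data of a 1-D drift GP."""

    theta: np.ndarray  # [ell, sigma, sigma_eps, mu0, mu1]
    nu: float
    t_train: np.ndarray
    x_train: np.ndarray
    nll: float
    jitter: float = 1e-8
    constrained: bool = False  # ell floor (ell_QC >= ell_S) active at optimum

    @property
    def ell(self) -> float:
        return float(self.theta[0])

    @property
    def sigma(self) -> float:
        return float(self.theta[1])

    @property
    def sigma_eps(self) -> float:
        return float(self.theta[2])

    @property
    def mu0(self) -> float:
        return float(self.theta[3])

    @property
    def mu1(self) -> float:
        return float(self.theta[4])


def build_covariance(t, theta, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Covariance sigma^2 R(|t_i - t_j|) + (sigma_eps^2 + jitter) I at orders t."""
    t = np.asarray(t, dtype=float)
    if len(np.unique(t)) != len(t):
        raise ValidationError("duplicate analysis orders: Kronecker-delta noise is ambiguous")
    ell, sigma, sigma_eps = float(theta[0]), float(theta[1]), float(theta[2])
    if sigma < 0 or sigma_eps < 0:
        raise ValidationError("sigma and sigma_eps must be >= 0")
    tau = np.abs(t[:, None] - t[None, :])
    K = sigma**2 * matern_correlation(tau, ell, kernel.nu)
    K[np.diag_indices_from(K)] += sigma_eps**2 + _jitter_value(kernel, sigma, sigma_eps)
    return K


def _jitter_value(kernel: KernelSpec, sigma: float, sigma_eps: float) -> float:
    return kernel.jitter * max(sigma**2 + sigma_eps**2, 1e-12)


def _mean(theta, t):
    return theta[3] + theta[4] * t


def negative_log_likelihood(x, t, theta, kernel: KernelSpec = KernelSpec()) -> float:
    """Exact Gaussian negative log-likelihood of intensities x at orders t."""
    return _nll_grad(np.asarray(x, float), np.asarray(t, float), np.asarray(theta, float), kernel)[0]


def nll_gradient(x, t, theta, kernel: KernelSpec = KernelSpec()) -> np.ndarray:
    """Analytic gradient of the NLL w.r.t. [ell, sigma, sigma_eps, mu0, mu1]."""
    return _nll_grad(np.asarray(x, float), np.asarray(t, float), np.asarray(theta, float), kernel)[1]


def _nll_grad(x, t, theta, kernel: KernelSpec):
    n = len(x)
    if n < 2 or len(t) != n:
        raise ValidationError("need len(x) == len(t) >= 2")
    ell, sigma, sigma_eps = theta[0], theta[1], theta[2]
    tau = np.abs(t[:, None] - t[None, :])
    R = matern_correlation(tau, ell, kernel.nu)
    K = sigma**2 * R
    K[np.diag_indices_from(K)] += sigma_eps**2 + _jitter_value(kernel, sigma, sigma_eps)
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - jitter normally suffices
        raise DegenerateDataError(f"covariance not positive definite: {exc}") from None
    r = x - _mean(theta, t)
    alpha = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * float(r @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2.0 * np.pi)

    Kinv = cho_solve((c, low), np.eye(n))
    A = Kinv - np.outer(alpha, alpha)  # dL/dp = 0.5 * tr(A @ dK/dp)

    dK_ell = sigma**2 * _matern_dR_dell(tau, ell, kernel.nu)
    g_ell = 0.5 * np.sum(A * dK_ell)
    g_sigma = 0.5 * np.sum(A * (2.0 * sigma * R))
    g_eps = 0.5 * np.trace(A) * 2.0 * sigma_eps
    g_mu0 = -float(np.sum(alpha))
    g_mu1 = -float(t @ alpha)
    return nll, np.array([g_ell, g_sigma, g_eps, g_mu0, g_mu1])


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class GPDriftModel:
    """Per-feature drift GP on intensities versus analysis order.

    Parameters
    ----------
    endog
        Observed intensities (in the working space chosen by the caller).
    order
        Analysis orders, one per observation; duplicates are rejected.
    nu
        Matern smoothness, one of {1/2, 3/2, 5/2}.
    ell_floor
        Optional lower bound on the fitted scale (the ell_QC >= ell_S
        smoothness constraint when fitting QC runs).
    ell_min
        Identifiability floor on the scale. The default "spacing" uses the
        mean gap between training orders: drift structure finer than the
        sampling interval of the reference runs cannot be distinguished from
        noise, and letting the scale go below it makes the posterior mean
        interpolate measurement noise. Pass a number (or 0) to override.
    """

    def __init__(self, endog, order, nu: float = 1.5, ell_floor: float | None = None,
                 jitter: float = 1e-8, ell_min: float | str = "spacing",
                 sigma_eps_bounds: tuple[float, float] | None = None,
                 sigma_bounds: tuple[float, float] | None = None):
        self.endog = np.asarray(endog, dtype=float)
        self.order = np.asarray(order, dtype=float)
        if self.endog.ndim != 1 or self.endog.shape != self.order.shape:
            raise ValidationError("endog and order must be 1-D and of equal length")
        if len(self.endog) < MIN_QC_FIT:
            raise ValidationError(f"need at least {MIN_QC_FIT} observations for a drift fit")
        if np.any(~np.isfinite(self.endog)) or np.any(~np.isfinite(self.order)):
            raise ValidationError("endog and order must be finite")
        if len(np.unique(self.order)) != len(self.order):
            raise ValidationError("duplicate analysis orders")
        self.kernel = KernelSpec(nu=nu, jitter=jitter)
        self.ell_floor = None if ell_floor is None else float(ell_floor)
        if ell_min == "spacing":
            self.ell_min = float(np.mean(np.diff(np.sort(self.order))))
        else:
            self.ell_min = float(ell_min)
        self.sigma_eps_bounds = sigma_eps_bounds
        self.sigma_bounds = sigma_bounds

    # -- initial values -----------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Moment-based start: OLS mean, detrended variance split half/half,
        ell at a quarter of the order span."""
        t, x = self.order, self.endog
        span = float(t.max() - t.min())
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
        v = float(np.var(resid))
        v = max(v, 1e-12 * max(1.0, float(np.mean(x**2))))
        ell0 = max(span / 4.0, 1e-2)
        if self.ell_floor is not None:
            ell0 = max(ell0, self.ell_floor)
        return np.array([ell0, np.sqrt(v / 2.0), np.sqrt(v / 2.0), beta[0], beta[1]])

    def loglike(self, params) -> float:
        return -negative_log_likelihood(self.endog, self.order, params, self.kernel)

    # -- fitting ------------------------------------------------------------
    def fit(self, restarts: int = 5, seed: int = 0, maxiter: int = 200,
            gtol: float = 1e-8) -> "GPDriftResults":
        """Maximize the likelihood by bounded L-BFGS-B on log(ell, sigma,
        sigma_eps) and free (mu0, mu1), with ``restarts`` jittered restarts."""
        t, x = self.order, self.endog
        if np.allclose(x, x[0]):
            warnings.warn("constant intensities: degenerate drift fit", stacklevel=2)
            theta = np.array([max(self.ell_floor or 1.0, 1.0), 0.0, 1e-8, float(x[0]), 0.0])
            fit = GPFit(theta, self.kernel.nu, t.copy(), x.copy(),
                        negative_log_likelihood(x, t, theta, self.kernel),
                        self.kernel.jitter, constrained=False)
            return GPDriftResults(self, fit, start_nll=fit.nll)

        span = float(t.max() - t.min())
        scale = max(float(np.std(x)), 1e-8)
        lo_ell = np.log(max(self.ell_floor or 0.0, self.ell_min, span * 1e-3, 1e-3))
        hi_ell = np.log(max(span * 100.0, np.exp(lo_ell) * 10.0))
        lo_s, hi_s = np.log(scale * 1e-6), np.log(scale * 1e3)
        def _band(b):
            if b is None:
                return lo_s, hi_s
            return (np.log(max(b[0], scale * 1e-6)), np.log(max(b[1], b[0] * 1.01)))

        lo_sg, hi_sg = _band(self.sigma_bounds)
        lo_se, hi_se = _band(self.sigma_eps_bounds)
        bounds = [(lo_ell, hi_ell), (lo_sg, hi_sg), (lo_se, hi_se), (None, None), (None, None)]

        def pack(theta):
            return np.array([np.log(theta[0]), np.log(max(theta[1], np.exp(lo_s))),
                             np.log(max(theta[2], np.exp(lo_s))), theta[3], theta[4]])

        def unpack(z):
            return np.array([np.exp(z[0]), np.exp(z[1]), np.exp(z[2]), z[3], z[4]])

        def objective(z):
            theta = unpack(z)
            nll, g = _nll_grad(x, t, theta, self.kernel)
            # chain rule for the log-parameterized block
            g = g.copy()
            g[:3] *= theta[:3]
            return nll, g

        theta0 = self.start_params()
        theta0[0] = np.clip(theta0[0], np.exp(lo_ell), np.exp(hi_ell))
        theta0[1] = np.clip(theta0[1], np.exp(lo_sg), np.exp(hi_sg))
        theta0[2] = np.clip(theta0[2], np.exp(lo_se), np.exp(hi_se))
        start_nll = negative_log_likelihood(x, t, theta0, self.kernel)
        rng = np.random.default_rng(seed)
        starts = [pack(theta0)]
        # deterministic portfolio: drift-dominant and noise-dominant starts
        # bracket the two competing explanations of the detrended variance
        v_tot = theta0[1] ** 2 + theta0[2] ** 2
        for w in (0.9, 0.1):
            alt = theta0.copy()
            alt[1] = np.sqrt(w * v_tot)
            alt[2] = np.sqrt((1.0 - w) * v_tot)
            starts.append(pack(alt))
        for _ in range(max(restarts - 1, 0)):
            jit = theta0.copy()
            jit[:3] *= np.exp(rng.normal(0.0, 0.7, size=3))
            jit[0] = np.clip(jit[0], np.exp(lo_ell), np.exp(hi_ell))
            jit[1] = np.clip(jit[1], np.exp(lo_sg), np.exp(hi_sg))
            jit[2] = np.clip(jit[2], np.exp(lo_se), np.exp(hi_se))
            starts.append(pack(jit))

        best = None
        failures = []
        for z0 in starts:
            try:
                res = optimize.minimize(
                    objective, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                    options={"maxiter": maxiter, "gtol": gtol},
                )
            except (np.linalg.LinAlgError, DegenerateDataError) as exc:
                failures.append(str(exc))
                continue
            if not np.isfinite(res.fun):
                failures.append("non-finite objective")
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise ConvergenceError(
                f"all {len(starts)} restarts failed: {failures[-3:]}"
            )
        theta_hat = unpack(best.x)
        nll_hat = float(best.fun)
        if nll_hat > start_nll + 1e-9:  # never worse than the start
            theta_hat, nll_hat = theta0, start_nll
        constrained = bool(
            self.ell_floor is not None and theta_hat[0] <= self.ell_floor * (1.0 + 1e-6)
        )
        fit = GPFit(theta_hat, self.kernel.nu, t.copy(), x.copy(), nll_hat,
                    self.kernel.jitter, constrained=constrained)
        return GPDriftResults(self, fit, start_nll=start_nll)


class GPDriftResults:
    """Maximum-likelihood fit of a :class:`GPDriftModel`.

    Exposes the parameter estimates (``params``, named accessors), approximate
    standard errors from the observed information (``bse``), the optimized
    negative log-likelihood (``nll``), posterior drift prediction
    (:meth:`predict`) and a text :meth:`summary`.
    """

    PARAM_NAMES = ("ell", "sigma", "sigma_eps", "mu0", "mu1")

    def __init__(self, model: GPDriftModel, fit: GPFit, start_nll: float = np.nan):
        self.model = model
        self.gpfit = fit
        self.start_nll = start_nll
        self._bse = None

    @property
    def params(self) -> np.ndarray:
        return self.gpfit.theta

    @property
    def nll(self) -> float:
        return self.gpfit.nll

    @property
    def llf(self) -> float:
        return -self.gpfit.nll

    def __getattr__(self, name):
        if name in self.PARAM_NAMES:
            return getattr(self.gpfit, name)
        raise AttributeError(name)

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the finite-difference observed information.

        NaN where the information matrix is singular (e.g. parameters at a
        bound), which is common for sigma -> 0 fits on undrifted data.
        """
        if self._bse is None:
            theta = self.params
            n = len(theta)
            H = np.zeros((n, n))
            h = np.maximum(1e-5 * np.abs(theta), 1e-7)
            for j in range(n):
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h[j]
                tm[j] = max(tm[j] - h[j], 1e-12) if j < 3 else tm[j] - h[j]
                try:
                    gp = nll_gradient(self.model.endog, self.model.order, tp, self.model.kernel)
                    gm = nll_gradient(self.model.endog, self.model.order, tm, self.model.kernel)
                    H[:, j] = (gp - gm) / (tp[j] - tm[j])
                except (DegenerateDataError, np.linalg.LinAlgError):
                    H[:, j] = np.nan
            H = 0.5 * (H + H.T)
            with np.errstate(invalid="ignore"):
                try:
                    cov = np.linalg.pinv(H)
                    se = np.sqrt(np.diag(cov))
                except np.linalg.LinAlgError:
                    se = np.full(n, np.nan)
            self._bse = np.where(np.isfinite(se), se, np.nan)
        return self._bse

    # -- prediction ---------------------------------------------------------
    def predict(self, t_query, return_var: bool = False):
        """Posterior mean (and latent variance) of the drift at new orders."""
        return predict_drift(self.gpfit, t_query, return_var=return_var)

    def correction(self, t_query) -> np.ndarray:
        """Additive correction: posterior mean minus its average over t_query."""
        m = self.predict(t_query)
        return m - float(np.mean(m))

    def summary(self) -> str:
        f = self.gpfit
        lines = [
            "GP drift model (Matern nu=%g), n=%d QC points" % (f.nu, len(f.t_train)),
            "-" * 58,
            "%-10s %12s %12s" % ("param", "estimate", "std err"),
        ]
        bse = self.bse
        for name, val, se in zip(self.PARAM_NAMES, f.theta, bse):
            lines.append("%-10s %12.5g %12.5g" % (name, val, se))
        lines.append("-" * 58)
        lines.append("NLL at optimum: %.6g" % f.nll)
        if f.constrained:
            lines.append("scale constraint ell_QC >= ell_S active")
        return "\n".join(lines)

    def plot_drift(self, t_query=None, ax=None):  # pragma: no cover - cosmetic
        """Plot training points and the posterior drift curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.gpfit
        if t_query is None:
            t_query = np.arange(f.t_train.min(), f.t_train.max() + 1)
        m, v = self.predict(t_query, return_var=True)
        sd = np.sqrt(np.maximum(v, 0.0))
        ax.plot(t_query, m, label="posterior drift")
        ax.fill_between(t_query, m - 2 * sd, m + 2 * sd, alpha=0.2)
        ax.scatter(f.t_train, f.x_train, marker="o", label="QC runs")
        ax.set_xlabel("analysis order")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


def predict_drift(fit: GPFit, t_query, return_var: bool = False):
    """Standard GP posterior of the drift curve at queried orders."""
    t_query = np.atleast_1d(np.asarray(t_query, dtype=float))
    kernel = KernelSpec(nu=fit.nu, jitter=fit.jitter)
    K = build_covariance(fit.t_train, fit.theta, kernel)
    c, low = cho_factor(K, lower=True)
    r = fit.x_train - _mean(fit.theta, fit.t_train)
    alpha = cho_solve((c, low), r)
    tau_q = np.abs(t_query[:, None] - fit.t_train[None, :])
    k_star = fit.sigma**2 * matern_correlation(tau_q, fit.ell, fit.nu)
    mean = _mean(fit.theta, t_query) + k_star @ alpha
    if not return_var:
        return mean
    v = cho_solve((c, low), k_star.T)
    var = fit.sigma**2 - np.einsum("ij,ji->i", k_star, v)
    return mean, np.maximum(var, 0.0)


# ---------------------------------------------------------------------------
# Pipeline wrappers
# ---------------------------------------------------------------------------


def fit_gprm(x_qc, t_qc, kernel: KernelSpec = KernelSpec(),
             config: FitConfig = FitConfig(), ell_S: float | None = None,
             sigma_eps_bounds: tuple[float, float] | None = None,
             sigma_bounds: tuple[float, float] | None = None) -> GPDriftResults:
    """Fit the drift GP to QC intensities, optionally with ell_QC >= ell_S.

    The smoothness constraint is only applied when ell_S is resolvable
    within the run (ell_S no larger than the span of the QC orders): a scale
    beyond the run length means the experimental series showed no within-run
    correlation structure, and flooring at it would degenerate the QC fit to
    its linear mean.
    """
    t_arr = np.asarray(t_qc, dtype=float)
    if ell_S is not None and t_arr.size and ell_S > float(t_arr.max() - t_arr.min()):
        ell_S = None
    model = GPDriftModel(x_qc, t_qc, nu=kernel.nu, ell_floor=ell_S, jitter=kernel.jitter,
                         sigma_eps_bounds=sigma_eps_bounds, sigma_bounds=sigma_bounds)
    return model.fit(restarts=config.restarts, seed=config.seed,
                     maxiter=config.maxiter, gtol=config.gtol)


def estimate_sample_scale_1d(x_s, t_s, kernel: KernelSpec = KernelSpec(),
                             config: FitConfig = FitConfig()) -> float | None:
    """Unconstrained scale estimate from experimental-sample intensities.

    Returns None (fit unregularized) with a warning when fewer than 5
    experimental samples are available or the data are degenerate.
    """
    x_s = np.asarray(x_s, float)
    if len(x_s) < 5:
        warnings.warn("fewer than 5 experimental samples: ell_S omitted", stacklevel=2)
        return None
    if np.allclose(x_s, x_s[0]):
        warnings.warn("constant experimental intensities: ell_S omitted", stacklevel=2)
        return None
    try:
        res = fit_gprm(x_s, t_s, kernel, replace(config, restarts=min(config.restarts, 3)))
    except (ConvergenceError, ValidationError):
        return None
    return res.ell


@dataclass
class _FeatureCurve:
    feature_id: str
    batch: str
    experiment: str
    fit: GPFit | None
    correction: np.ndarray | None  # per-column additive correction (working space)


def estimate_sample_scale(fm: FeatureMatrix, st: SampleTable,
                          kernel: KernelSpec = KernelSpec(),
                          config: FitConfig = FitConfig()) -> dict[str, float | None]:
    """Per-feature ell_S from experimental (non-QC) samples, pooled blocks."""
    work = _to_working(fm.values, config.working_space)
    meta = st.loc(fm.sample_ids)
    out: dict[str, float | None] = {}
    mask = (meta["group"] != "QC").to_numpy()
    t = meta["analysis_order"].to_numpy(float)
    for i, fid in enumerate(fm.feature_ids):
        x = work[i, mask]
        ok = np.isfinite(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[fid] = estimate_sample_scale_1d(x[ok], t[mask][ok], kernel, config)
    return out


def _to_working(values: np.ndarray, space: str) -> np.ndarray:
    return np.log1p(values) if space == "log" else values.copy()


def _from_working(values: np.ndarray, space: str) -> np.ndarray:
    if space == "log":
        return np.maximum(np.expm1(values), 0.0)
    return np.maximum(values, 0.0)


def gprm_normalize(fm: FeatureMatrix, st: SampleTable,
                   kernel: KernelSpec = KernelSpec(),
                   config: FitConfig = FitConfig()) -> NormalizationResult:
    """Correct analysis-order drift of every feature using QC-fitted GPs.

    Per (batch, experiment) block and per feature: fit the GP to that block's
    QC runs (with the ell_QC >= ell_S constraint when ``config.regularize``),
    predict the posterior drift at every sample's order, and subtract the
    drift's deviation from its block mean, in the working space. Features
    whose fit fails (or with fewer than 3 finite QC values) pass through
    unchanged and are listed in ``result.failed_features``.
    """
    work = _to_working(fm.values, config.working_space)
    out = work.copy()
    meta = st.loc(fm.sample_ids)
    failed: list[str] = []
    theta_rows = []
    for batch, exp, cols in st.blocks(fm.sample_ids):
        sub = meta.iloc[cols]
        t_all = sub["analysis_order"].to_numpy(float)
        qc = (sub["group"] == "QC").to_numpy()
        texp = t_all[~qc]
        fits: list[tuple] = []  # (row, fid, x_qc, t_qc, ell_S, result)
        for i, fid in enumerate(fm.feature_ids):
            x_qc = work[i, cols][qc]
            t_qc = t_all[qc]
            ok = np.isfinite(x_qc)
            if ok.sum() < MIN_QC_FIT:
                failed.append(fid)
                logger.warning("feature %s block (%s,%s): <%d QC values, passed through",
                               fid, batch, exp, MIN_QC_FIT)
                continue
            ell_S = None
            if config.regularize:
                x_exp = work[i, cols][~qc]
                okx = np.isfinite(x_exp)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ell_S = estimate_sample_scale_1d(x_exp[okx], texp[okx], kernel, config)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = fit_gprm(x_qc[ok], t_qc[ok], kernel, config, ell_S=ell_S)
            except (ConvergenceError, ValidationError, DegenerateDataError):
                failed.append(fid)
                continue
            fits.append((i, fid, x_qc[ok], t_qc[ok], ell_S, res))
        # cross-feature moderation: instrument noise is shared across
        # features and the dominant drift mode is common-mode, so per-feature
        # (sigma, sigma_eps) estimates straying far from the ensemble medians
        # are refitted within bands around them (empirical-Bayes shrinkage of
        # the variance components, in the spirit of limma)
        if config.moderate_noise and len(fits) >= 10:
            pool_se = float(np.median([f[5].sigma_eps for f in fits]))
            pool_sg = float(np.median([f[5].sigma for f in fits]))
            band_se = (config.moderation_band[0] * pool_se,
                       config.moderation_band[1] * pool_se) if pool_se > 0 else None
            # sigma band is one-sided: collapsed fits are pulled up toward
            # the ensemble, but detected amplitudes are never dragged down
            band_sg = (0.3 * pool_sg, np.inf) if pool_sg > 0 else None
            for k, (i, fid, xq, tq, ell_S, res) in enumerate(fits):
                off_se = band_se is not None and not (band_se[0] <= res.sigma_eps <= band_se[1])
                off_sg = band_sg is not None and not (band_sg[0] <= res.sigma <= band_sg[1])
                if off_se or off_sg:
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res2 = fit_gprm(xq, tq, kernel, config, ell_S=ell_S,
                                            sigma_eps_bounds=band_se if off_se else None,
                                            sigma_bounds=band_sg if off_sg else None)
                        fits[k] = (i, fid, xq, tq, ell_S, res2)
                    except (ConvergenceError, ValidationError, DegenerateDataError):
                        pass
        for i, fid, _xq, _tq, _eS, res in fits:
            corr = res.correction(t_all)
            finite = np.isfinite(out[i, cols])
            vals = out[i, cols]
            vals[finite] = vals[finite] - corr[finite]
            out[i, cols] = vals
            theta_rows.append({
                "feature_id": fid, "batch": batch, "experiment": exp,
                "ell": res.ell, "sigma": res.sigma, "sigma_eps": res.sigma_eps,
                "mu0": res.mu0, "mu1": res.mu1, "nll": res.nll,
                "constrained": res.gpfit.constrained,
            })
    import pandas as pd

    matrix = fm.copy_with(_from_working(out, config.working_space))
    return NormalizationResult(
        matrix=matrix,
        factors=pd.DataFrame(theta_rows),
        method_tag="gprm",
        parameters={"nu": kernel.nu, "working_space": config.working_space,
                    "restarts": config.restarts, "seed": config.seed,
                    "regularize": config.regularize},
        failed_features=sorted(set(failed)),
    )


# ---------------------------------------------------------------------------
# 2-D (order x scan) GP
# ---------------------------------------------------------------------------


def product_covariance(t, s, theta, nu: float = 1.5, jitter: float = 1e-8) -> np.ndarray:
    """Separable covariance sigma^2 R(|dt|; ell_t) R(|ds|; ell_s) + noise.

    theta = [ell_t, ell_s, sigma, sigma_eps, mu0, mu1]; duplicate (t, s)
    pairs are rejected.
    """
    t = np.asarray(t, float)
    s = np.asarray(s, float)
    pairs = np.column_stack([t, s])
    if len(np.unique(pairs, axis=0)) != len(pairs):
        raise ValidationError("duplicate (order, scan) pairs")
    ell_t, ell_s, sigma, sigma_eps = theta[0], theta[1], theta[2], theta[3]
    Rt = matern_correlation(np.abs(t[:, None] - t[None, :]), ell_t, nu)
    Rs = matern_correlation(np.abs(s[:, None] - s[None, :]), ell_s, nu)
    K = sigma**2 * Rt * Rs
    K[np.diag_indices_from(K)] += sigma_eps**2 + jitter * max(sigma**2 + sigma_eps**2, 1e-12)
    return K


def _nll_grad_2d(x, t, s, theta, nu, jitter):
    n = len(x)
    ell_t, ell_s, sigma, sigma_eps = theta[0], theta[1], theta[2], theta[3]
    dt = np.abs(t[:, None] - t[None, :])
    ds = np.abs(s[:, None] - s[None, :])
    Rt = matern_correlation(dt, ell_t, nu)
    Rs = matern_correlation(ds, ell_s, nu)
    K = sigma**2 * Rt * Rs
    K[np.diag_indices_from(K)] += sigma_eps**2 + jitter * max(sigma**2 + sigma_eps**2, 1e-12)
    c, low = cho_factor(K, lower=True)
    r = x - (theta[4] + theta[5] * t)
    alpha = cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    nll = 0.5 * float(r @ alpha) + 0.5 * logdet + 0.5 * n * np.log(2.0 * np.pi)
    Kinv = cho_solve((c, low), np.eye(n))
    A = Kinv - np.outer(alpha, alpha)
    g = np.empty(6)
    g[0] = 0.5 * np.sum(A * (sigma**2 * _matern_dR_dell(dt, ell_t, nu) * Rs))
    g[1] = 0.5 * np.sum(A * (sigma**2 * Rt * _matern_dR_dell(ds, ell_s, nu)))
    g[2] = 0.5 * np.sum(A * (2.0 * sigma * Rt * Rs))
    g[3] = 0.5 * np.trace(A) * 2.0 * sigma_eps
    g[4] = -float(np.sum(alpha))
    g[5] = -float(t @ alpha)
    return nll, g


class GPDriftModel2D:
    """Joint order x scan drift GP with a separable Matern product kernel.

    One smooth drift surface m(t, s) per feature is fitted to all QC
    (order, scan) intensity points jointly, pooling information across scans;
    scales ell_t (analysis order) and ell_s (scan) are independent. The mean
    is linear in analysis order and shared across scans.
    """

    PARAM_NAMES = ("ell_t", "ell_s", "sigma", "sigma_eps", "mu0", "mu1")

    def __init__(self, endog, order, scan, nu: float = 1.5, jitter: float = 1e-8,
                 ell_min: float | str = "spacing"):
        self.endog = np.asarray(endog, float)
        self.order = np.asarray(order, float)
        self.scan = np.asarray(scan, float)
        if not (self.endog.shape == self.order.shape == self.scan.shape):
            raise ValidationError("endog, order, scan must have equal length")
        if len(self.endog) < 4:
            raise ValidationError("need at least 4 points for a 2-D fit")
        self.nu = nu
        self.jitter = jitter
        if ell_min == "spacing":
            uniq = np.unique(self.order)
            self.ell_min = float(np.mean(np.diff(uniq))) if len(uniq) > 1 else 1e-2
        else:
            self.ell_min = float(ell_min)

    def start_params(self) -> np.ndarray:
        t, s, x = self.order, self.scan, self.endog
        X = np.column_stack([np.ones_like(t), t])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        v = max(float(np.var(x - X @ beta)), 1e-12 * max(1.0, float(np.mean(x**2))))
        span_t = max(float(t.max() - t.min()), 1e-2)
        span_s = max(float(s.max() - s.min()), 1e-2)
        return np.array([span_t / 4.0, span_s / 2.0, np.sqrt(v / 2.0), np.sqrt(v / 2.0),
                         beta[0], beta[1]])

    def fit(self, restarts: int = 3, seed: int = 0, maxiter: int = 200,
            gtol: float = 1e-8) -> "GPDrift2DResults":
        x, t, s = self.endog, self.order, self.scan
        if np.allclose(x, x[0]):
            theta = np.array([1.0, 1.0, 0.0, 1e-8, float(x[0]), 0.0])
            nll, _ = _nll_grad_2d(x, t, s, np.maximum(theta, [1, 1, 1e-9, 1e-9, -np.inf, -np.inf]),
                                  self.nu, self.jitter)
            return GPDrift2DResults(self, theta, nll)
        theta0 = self.start_params()
        scale = max(float(np.std(x)), 1e-8)
        span_t = max(float(t.max() - t.min()), 1e-2)
        span_s = max(float(s.max() - s.min()), 1e-2)
        bounds = [
            (np.log(max(self.ell_min, span_t * 1e-3)), np.log(span_t * 100.0)),
            (np.log(span_s * 1e-2), np.log(span_s * 100.0)),
            (np.log(scale * 1e-6), np.log(scale * 1e3)),
            (np.log(scale * 1e-6), np.log(scale * 1e3)),
            (None, None), (None, None),
        ]

        def pack(th):
            z = th.copy()
            z[:4] = np.log(np.clip(th[:4], [np.exp(b[0]) for b in bounds[:4]],
                                   [np.exp(b[1]) for b in bounds[:4]]))
            return z

        def objective(z):
            theta = z.copy()
            theta[:4] = np.exp(z[:4])
            nll, g = _nll_grad_2d(x, t, s, theta, self.nu, self.jitter)
            g = g.copy()
            g[:4] *= theta[:4]
            return nll, g

        rng = np.random.default_rng(seed)
        starts = [pack(theta0)]
        for _ in range(max(restarts - 1, 0)):
            jit = theta0.copy()
            jit[:4] *= np.exp(rng.normal(0.0, 0.7, size=4))
            starts.append(pack(jit))
        best = None
        for z0 in starts:
            try:
                res = optimize.minimize(objective, z0, jac=True, method="L-BFGS-B",
                                        bounds=bounds, options={"maxiter": maxiter, "gtol": gtol})
            except (np.linalg.LinAlgError, DegenerateDataError):
                continue
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError("all 2-D GP restarts failed")
        theta = best.x.copy()
        theta[:4] = np.exp(best.x[:4])
        return GPDrift2DResults(self, theta, float(best.fun))


class GPDrift2DResults:
    """Fitted 2-D drift surface; predicts m(t, s) on arbitrary grids."""

    def __init__(self, model: GPDriftModel2D, params: np.ndarray, nll: float):
        self.model = model
        self.params = np.asarray(params, float)
        self.nll = nll

    def predict(self, t_query, s_query) -> np.ndarray:
        """Posterior mean at paired (t, s) query points."""
        th = self.params
        m = self.model
        tq = np.asarray(t_query, float)
        sq = np.asarray(s_query, float)
        K = product_covariance(m.order, m.scan, th, m.nu, m.jitter)
        c, low = cho_factor(K, lower=True)
        r = m.endog - (th[4] + th[5] * m.order)
        alpha = cho_solve((c, low), r)
        Rt = matern_correlation(np.abs(tq[:, None] - m.order[None, :]), th[0], m.nu)
        Rs = matern_correlation(np.abs(sq[:, None] - m.scan[None, :]), th[1], m.nu)
        k_star = th[2] ** 2 * Rt * Rs
        return th[4] + th[5] * tq + k_star @ alpha

    def summary(self) -> str:
        lines = ["2-D GP drift surface (Matern nu=%g), n=%d points"
                 % (self.model.nu, len(self.model.endog)), "-" * 46]
        for name, val in zip(GPDriftModel2D.PARAM_NAMES, self.params):
            lines.append("%-10s %14.5g" % (name, val))
        lines.append("NLL at optimum: %.6g" % self.nll)
        return "\n".join(lines)
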