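"""Interval-censored Gaussian maximum likelihood for WTP fractions.

Latent model: WTP_i = x_i'beta + eps_i with eps_i ~ iid N(0, sigma^2),
observed only through a censored interval [l_i, u_i).  Each observation
contributes

    ln[ Phi((u_i - x_i'beta)/sigma) - Phi((l_i - x_i'beta)/sigma) ]

with the obvious one-sided forms for left-/right-censored rows.  The
model is maximized over (beta, ln sigma) — the log parameterization
keeps sigma positive on every iterate — by BFGS with the analytic score
followed by Newton polishing to a tight gradient tolerance.  Inference
uses the heteroskedasticity-robust sandwich H^{-1} (sum s_i s_i') H^{-1}
built from per-observation scores, and a Wald chi-square test that all
slope coefficients are zero.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .bids import BidSchedule, WTPInterval, map_to_interval
from .errors import DataError, EstimationError
from .survey import MODEL_COLUMNS, build_model_frame, listwise_filter

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# numerically stable censored-normal pieces

def _log_norm_interval(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)) elementwise, stable in both tails.

    ``zl`` may be -inf (left censoring) and ``zu`` may be +inf (right
    censoring); a doubly infinite row returns exactly 0 = ln 1.
    """
    zl = np.asarray(zl, dtype=float)
    zu = np.asarray(zu, dtype=float)
    out = np.zeros(np.broadcast(zl, zu).shape)

    fin_l = np.isfinite(zl)
    fin_u = np.isfinite(zu)

    left = ~fin_l & fin_u
    out[left] = special.log_ndtr(zu[left])
    right = fin_l & ~fin_u
    out[right] = special.log_ndtr(-zl[right])

    both = fin_l & fin_u
    if np.any(both):
        a = zl[both]
        b = zu[both]
        # reflect so the pair sits in the lower tail, where log_ndtr is sharp
        flip = a + b > 0
        a2 = np.where(flip, -b, a)
        b2 = np.where(flip, -a, b)
        log_b = special.log_ndtr(b2)
        log_a = special.log_ndtr(a2)
        out[both] = log_b + np.log1p(-np.exp(log_a - log_b))
    return out


def _phi_ratio(z: np.ndarray, log_p: np.ndarray) -> np.ndarray:
    """phi(z)/P elementwise with phi(+-inf) = 0; P given as log_p."""
    out = np.zeros_like(log_p)
    fin = np.isfinite(z)
    out[fin] = np.exp(-0.5 * z[fin] ** 2 - _LOG_SQRT_2PI - log_p[fin])
    return out


# ---------------------------------------------------------------------------
# data containers

@dataclass
class EstimationDataset:
    """Aligned censored intervals and design matrix (intercept included)."""

    lower: np.ndarray
    upper: np.ndarray
    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n = self.lower.shape[0]
        if self.upper.shape[0] != n or self.X.shape[0] != n:
            raise DataError("intervals and design matrix are not aligned")
        if self.X.shape[1] != len(self.names):
            raise DataError("design width does not match the name list")
        if np.any(~(self.lower < self.upper)):
            raise DataError("every interval must satisfy lower < upper")
        if not np.any(np.isfinite(self.lower) | np.isfinite(self.upper)):
            raise EstimationError(
                "all intervals are unbounded on both sides; the likelihood is flat")

    @property
    def n(self) -> int:
        return int(self.lower.shape[0])

    @classmethod
    def from_intervals(cls, intervals: Sequence[WTPInterval], X, names) -> "EstimationDataset":
        lower = np.array([iv.lower for iv in intervals], dtype=float)
        upper = np.array([iv.upper for iv in intervals], dtype=float)
        return cls(lower=lower, upper=upper, X=np.asarray(X, dtype=float), names=list(names))

    def covariate_means(self) -> np.ndarray:
        return self.X.mean(axis=0)


def dataset_from_frame(frame, model_columns: Sequence[str],
                       floor_zero: bool = False) -> EstimationDataset:
    """Build an estimation dataset from an encoded, listwise-complete frame.

    ``floor_zero`` truncates the unrestrained lower bound of double-no
    responses at 0 (sensitivity option); the default keeps -inf.
    """
    intervals = [
        map_to_interval(r1, r2, f)
        for r1, r2, f in zip(frame["response1"], frame["response2"], frame["followup_frac"])
    ]
    lower = np.array([iv.lower for iv in intervals])
    upper = np.array([iv.upper for iv in intervals])
    if floor_zero:
        lower = np.maximum(lower, 0.0)
    names = ["const"] + list(model_columns)
    X = frame[names].to_numpy(dtype=float)
    return EstimationDataset(lower=lower, upper=upper, X=X, names=names)


def drop_degenerate_columns(data: EstimationDataset) -> tuple[EstimationDataset, list[str]]:
    """Omit covariates with no variation in the estimation sample.

    Small samples can leave an indicator all-0 or all-1, which is
    collinear with the intercept; the standard practice is to omit it
    from that model and say so.  Returns the reduced dataset and the
    omitted column names.
    """
    keep, dropped = [], []
    for j, nm in enumerate(data.names):
        if nm != "const" and np.ptp(data.X[:, j]) == 0:
            dropped.append(nm)
        else:
            keep.append(j)
    if not dropped:
        return data, []
    logger.info("omitting no-variation covariates: %s", dropped)
    reduced = EstimationDataset(lower=data.lower, upper=data.upper,
                                X=data.X[:, keep],
                                names=[data.names[j] for j in keep])
    return reduced, dropped


def prepare_estimation(records, group: str, floor_zero: bool = False):
    """records -> (EstimationDataset, drop_log) for one group's model."""
    frame = build_model_frame(records, group)
    if frame.empty:
        raise DataError(f"no classifiable {group} records")
    kept, drop_log = listwise_filter(frame, MODEL_COLUMNS[group])
    data = dataset_from_frame(kept, MODEL_COLUMNS[group], floor_zero=floor_zero)
    return data, drop_log


# ---------------------------------------------------------------------------
# likelihood, score, fitting

@dataclass
class FitOptions:
    gtol: float = 1e-8          # inf-norm of the total gradient (scaled space)
    maxiter: int = 200
    polish_iter: int = 50
    dof_scale: bool = False     # n/(n-p) small-sample scaling of the sandwich


@dataclass
class FitResult:
    names: list[str]
    beta: np.ndarray
    ln_sigma: float
    robust_cov: np.ndarray      # (k+1) x (k+1), last index = ln sigma
    model_cov: np.ndarray       # inverse observed information, same layout
    loglik: float
    wald_chi2: float
    wald_df: int
    wald_p: float
    n: int
    converged: bool
    n_iter: int = 0

    @property
    def sigma(self) -> float:
        return float(np.exp(self.ln_sigma))

    @property
    def params(self) -> np.ndarray:
        return np.append(self.beta, self.ln_sigma)

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def z_values(self) -> np.ndarray:
        return self.params / self.robust_se()

    def p_values(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.z_values()))

    def beta_cov(self) -> np.ndarray:
        k = len(self.names)
        return self.robust_cov[:k, :k]

    def to_dict(self) -> dict:
        se = self.robust_se()
        z = self.z_values()
        p = self.p_values()
        return {
            "n": self.n,
            "converged": self.converged,
            "loglik": self.loglik,
            "wald_chi2": self.wald_chi2,
            "wald_df": self.wald_df,
            "wald_p": self.wald_p,
            "ln_sigma": {"estimate": self.ln_sigma, "robust_se": float(se[-1]),
                         "z": float(z[-1]), "p": float(p[-1])},
            "sigma": self.sigma,
            "coefficients": {
                name: {"estimate": float(self.beta[j]), "robust_se": float(se[j]),
                       "z": float(z[j]), "p": float(p[j])}
                for j, name in enumerate(self.names)
            },
        }


def obs_loglik(interval: WTPInterval, x: np.ndarray, beta: np.ndarray,
               ln_sigma: float) -> float:
    """Log-likelihood contribution of a single censored observation."""
    sigma = np.exp(ln_sigma)
    mu = float(np.dot(np.asarray(x, dtype=float), np.asarray(beta, dtype=float)))
    zl = (interval.lower - mu) / sigma
    zu = (interval.upper - mu) / sigma
    return float(_log_norm_interval(np.array([zl]), np.array([zu]))[0])


def _loglik_terms(theta: np.ndarray, lower, upper, X) -> np.ndarray:
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    mu = X @ beta
    with np.errstate(invalid="ignore"):
        zl = (lower - mu) / sigma
        zu = (upper - mu) / sigma
    zl = np.where(np.isinf(lower), -np.inf, zl)
    zu = np.where(np.isinf(upper), np.inf, zu)
    return _log_norm_interval(zl, zu), zl, zu


def _score_matrix(theta: np.ndarray, lower, upper, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation scores (n x p) and per-observation logliks."""
    sigma = np.exp(theta[-1])
    ll, zl, zu = _loglik_terms(theta, lower, upper, X)
    rl = _phi_ratio(zl, ll)
    ru = _phi_ratio(zu, ll)
    g_mu = (rl - ru) / sigma
    zrl = np.where(np.isfinite(zl), zl, 0.0) * rl
    zru = np.where(np.isfinite(zu), zu, 0.0) * ru
    g_lns = zrl - zru
    S = np.column_stack([X * g_mu[:, None], g_lns])
    return S, ll


def _total_grad(theta, lower, upper, X) -> np.ndarray:
    S, _ = _score_matrix(theta, lower, upper, X)
    return S.sum(axis=0)


def _fd_hessian(theta, lower, upper, X, h: float = 6e-6) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = h * max(1.0, abs(theta[j]))
        gp = _total_grad(theta + step, lower, upper, X)
        gm = _total_grad(theta - step, lower, upper, X)
        H[:, j] = (gp - gm) / (2 * step[j])
    return 0.5 * (H + H.T)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the pivoted QR diagonal
        _, R, piv = _qr_pivot(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[j]] for j in range(len(diag)) if diag[j] <= tol]
        bad += [names[piv[j]] for j in range(len(diag), X.shape[1])]
        raise EstimationError(f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _midpoint_init(lower, upper, Xs) -> np.ndarray:
    """OLS of pseudo-midpoints on X: cheap scale-aware starting values."""
    mid = np.where(
        np.isfinite(lower) & np.isfinite(upper), (lower + upper) / 2,
        np.where(np.isfinite(lower), lower + 0.05,
                 np.where(np.isfinite(upper), upper - 0.05, 0.0)))
    beta0, *_ = np.linalg.lstsq(Xs, mid, rcond=None)
    resid = mid - Xs @ beta0
    sd = float(np.std(resid))
    ln_sigma0 = np.log(max(sd, 0.01))
    return np.append(beta0, ln_sigma0)


def fit(data: EstimationDataset, options: Optional[FitOptions] = None) -> FitResult:
    """Maximize the interval-censored Gaussian likelihood over (beta, ln sigma).

    Non-convergence returns a result with ``converged=False`` and a
    warning rather than raising; structural failures (rank deficiency,
    fully unbounded data, too few rows) raise :class:`EstimationError`.
    """
    options = options or FitOptions()
    k = len(data.names)
    p = k + 1
    if data.n <= p:
        raise EstimationError(f"n={data.n} does not exceed the {p} parameters")
    _check_rank(data.X, data.names)

    # standardize columns (root-mean-square scale) for optimizer conditioning
    scale = np.sqrt(np.mean(data.X ** 2, axis=0))
    scale[scale == 0] = 1.0
    Xs = data.X / scale
    lower, upper = data.lower, data.upper

    def negll(theta):
        ll, _, _ = _loglik_terms(theta, lower, upper, Xs)
        return -float(ll.sum())

    def neggrad(theta):
        return -_total_grad(theta, lower, upper, Xs)

    theta0 = _midpoint_init(lower, upper, Xs)
    res = optimize.minimize(negll, theta0, jac=neggrad, method="BFGS",
                            options={"gtol": options.gtol, "maxiter": options.maxiter})
    theta = res.x
    n_iter = int(res.nit)

    # Newton polish with the finite-difference Hessian of the analytic score
    for _ in range(options.polish_iter):
        g = _total_grad(theta, lower, upper, Xs)
        if np.max(np.abs(g)) <= options.gtol:
            break
        H = _fd_hessian(theta, lower, upper, Xs)
        try:
            step = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        f0 = negll(theta)
        t = 1.0
        improved = False
        for _ in range(30):
            cand = theta + t * step
            f1 = negll(cand)
            g1 = _total_grad(cand, lower, upper, Xs)
            if f1 < f0 or np.max(np.abs(g1)) < np.max(np.abs(g)):
                theta = cand
                improved = True
                break
            t /= 2
        n_iter += 1
        if not improved:
            break

    g = _total_grad(theta, lower, upper, Xs)
    converged = bool(np.max(np.abs(g)) <= options.gtol)
    if not converged:
        warnings.warn(
            f"interval MLE did not reach gradient tolerance "
            f"(|g|_inf={np.max(np.abs(g)):.2e})", stacklevel=2)

    ll_terms, _, _ = _loglik_terms(theta, lower, upper, Xs)
    loglik = float(ll_terms.sum())

    H = _fd_hessian(theta, lower, upper, Xs)
    A = -H  # observed information
    S, _ = _score_matrix(theta, lower, upper, Xs)
    B = S.T @ S
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular Hessian at the optimum") from exc
    V_s = Ainv @ B @ Ainv
    if options.dof_scale:
        V_s = V_s * data.n / (data.n - p)

    # transform out of the standardized space: beta_j = beta_s_j / scale_j
    D = np.append(1.0 / scale, 1.0)
    V = (V_s * D).T * D
    V = 0.5 * (V + V.T)
    Vm = (Ainv * D).T * D
    Vm = 0.5 * (Vm + Vm.T)
    beta = theta[:-1] / scale

    wald_chi2, wald_df, wald_p = _wald_slopes(beta, V, data.names)

    return FitResult(
        names=list(data.names), beta=beta, ln_sigma=float(theta[-1]),
        robust_cov=V, model_cov=Vm, loglik=loglik,
        wald_chi2=wald_chi2, wald_df=wald_df, wald_p=wald_p,
        n=data.n, converged=converged, n_iter=n_iter,
    )


def _wald_slopes(beta, V, names) -> tuple[float, int, float]:
    slope_idx = [j for j, nm in enumerate(names) if nm != "const"]
    if not slope_idx:
        return 0.0, 0, 1.0
    b = beta[slope_idx]
    Vb = V[np.ix_(slope_idx, slope_idx)]
    try:
        W = float(b @ np.linalg.solve(Vb, b))
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular slope covariance block in Wald test") from exc
    df = len(slope_idx)
    return W, df, float(stats.chi2.sf(W, df))


def robust_covariance(fit_result: FitResult, data: EstimationDataset,
                      dof_scale: bool = False) -> np.ndarray:
    """Recompute the sandwich H^{-1} (sum s s') H^{-1} at a fitted optimum."""
    theta = fit_result.params
    H = _fd_hessian(theta, data.lower, data.upper, data.X)
    A = -H
    S, _ = _score_matrix(theta, data.lower, data.upper, data.X)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular Hessian at the optimum") from exc
    V = Ainv @ (S.T @ S) @ Ainv
    if dof_scale:
        p = theta.size
        V = V * data.n / (data.n - p)
    return 0.5 * (V + V.T)


def wald_test(fit_result: FitResult) -> tuple[float, int, float]:
    """Wald chi-square that all slope coefficients are jointly zero."""
    return _wald_slopes(fit_result.beta, fit_result.beta_cov(), fit_result.names)


def sequence_probabilities(x, beta, sigma: float, schedule: BidSchedule) -> dict[str, float]:
    """Closed-form response-sequence distribution at one covariate vector.

    With mu = x'beta, the four (response1, response2) probabilities are
    telescoping normal-CDF differences at the schedule's three bid
    fractions; they always sum to 1.
    """
    if sigma <= 0:
        raise DataError(f"sigma must be > 0, got {sigma}")
    mu = float(np.dot(np.asarray(x, dtype=float), np.asarray(beta, dtype=float)))
    z = lambda c: (c - mu) / sigma
    p_nn = stats.norm.cdf(z(schedule.c2n_frac))
    p_ny = stats.norm.cdf(z(schedule.c1_frac)) - p_nn
    p_yy = stats.norm.sf(z(schedule.c2y_frac))
    p_yn = 1.0 - p_nn - p_ny - p_yy
    return {"yes_yes": float(p_yy), "yes_no": float(max(p_yn, 0.0)),
            "no_yes": float(max(p_ny, 0.0)), "no_no": float(p_nn)}
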