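"""Elastic-net penalized logistic regression with an unpenalized covariate block.

The association model regresses a binary K-locus indicator on the binary
protein-cluster presence matrix while adjusting for population structure
through lineage (SC) indicator covariates.  The covariates and intercept
are *unpenalized* — structure adjustment must not compete with predictors
for penalty budget — while the cluster columns carry the elastic-net
penalty

    (1/n) * binomial NLL  +  lambda * ( alpha * ||beta||_1
                                        + (1 - alpha)/2 * ||beta||_2^2 ).

The solver is proximal Newton (IRLS) with coordinate descent on the
penalized block, an exact weighted least-squares update of the
unpenalized block, active-set iteration with vectorized KKT checks, warm
starts along a descending lambda grid, and step halving so the penalized
objective never increases.  Penalized columns are standardized internally
(population SD) and coefficients reported back on the original 0/1 scale.

lambda_max is computed from the null model (intercept + covariates only)
as max_j |x_j' (y - p0)| / (n * max(alpha, 0.01)); the clamp keeps the
grid finite in the ridge-dominated mode.  At lambda >= lambda_max every
penalized coefficient is exactly zero (KKT boundary).

The grid's lambda is selected by stratified K-fold cross-validation
minimizing mean out-of-fold binomial deviance; ties prefer the stronger
penalty.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["EnetConfig", "EnetFit", "fit_enet", "lambda_max", "fit_null_logistic"]

_P_CLIP = 1e-5
_ALPHA_CLAMP = 0.01


@dataclass(frozen=True)
class EnetConfig:
    """Solver and cross-validation settings."""

    alphas: tuple[float, ...] = (0.8, 0.069)
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 10
    tol: float = 1e-7
    max_iter: int = 100
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not all(0.0 < a <= 1.0 for a in self.alphas):
            raise ValueError(f"alphas must lie in (0, 1], got {self.alphas}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.n_lambda < 2:
            raise ValueError(f"n_lambda must be >= 2, got {self.n_lambda}")


@dataclass
class EnetFit:
    """One fitted elastic-net path with its CV-selected solution."""

    alpha: float
    lambdas: np.ndarray
    lambda_best: float
    intercept: float
    covariate_coefs: np.ndarray
    beta: np.ndarray  # per penalized column, original 0/1 scale
    cv_deviance: np.ndarray  # mean out-of-fold deviance per lambda
    beta_path: np.ndarray  # (n_lambda, p) original scale
    converged: np.ndarray  # per lambda
    n_iter: np.ndarray
    objective_trace: list[float] = field(default_factory=list)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def fit_null_logistic(U: np.ndarray, y: np.ndarray,
                      ridge: float = 1e-8, max_iter: int = 100,
                      tol: float = 1e-10) -> np.ndarray:
    """Newton fit of the logistic null model on design ``U`` (with intercept column).

    A tiny ridge keeps coefficients finite under separation (e.g. an SC
    whose members all share the response class); the fit is deterministic.
    """
    n, q = U.shape
    coef = np.zeros(q)
    prev_nll = np.inf
    for _ in range(max_iter):
        eta = U @ coef
        p = np.clip(_sigmoid(eta), _P_CLIP, 1.0 - _P_CLIP)
        nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) + 0.5 * ridge * coef @ coef
        grad = U.T @ (p - y) + ridge * coef
        w = p * (1.0 - p)
        H = (U * w[:, None]).T @ U + ridge * np.eye(q)
        step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            new = coef - t * step
            eta_n = U @ new
            nll_n = float(np.sum(np.logaddexp(0.0, eta_n) - y * eta_n)) + 0.5 * ridge * new @ new
            if nll_n <= nll + 1e-12:
                break
            t *= 0.5
        coef = coef - t * step
        if abs(prev_nll - nll_n) <= tol * (abs(nll_n) + 1.0):
            break
        prev_nll = nll_n
    return coef


def lambda_max(Xs: np.ndarray, U: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all penalized coefficients are zero."""
    n = len(y)
    coef0 = fit_null_logistic(U, y)
    p0 = _sigmoid(U @ coef0)
    score = Xs.T @ (y - p0)
    denom = n * max(alpha, _ALPHA_CLAMP)
    lm = float(np.max(np.abs(score)) / denom) if Xs.shape[1] else 1.0
    return max(lm, 1e-10)


def _objective(eta, y, beta, lam, alpha, n):
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta)) / n
    pen = lam * (alpha * float(np.abs(beta).sum()) + 0.5 * (1 - alpha) * float(beta @ beta))
    return nll + pen


@numba.njit(cache=True, fastmath=True)
def _nb_objective(eta, y, beta, lam, alpha, n):
    nll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i]
        # stable log(1 + exp(e)) - y*e
        if e > 0:
            nll += e + np.log1p(np.exp(-e)) - y[i] * e
        else:
            nll += np.log1p(np.exp(e)) - y[i] * e
    l1 = 0.0
    l2 = 0.0
    for j in range(beta.shape[0]):
        l1 += abs(beta[j])
        l2 += beta[j] * beta[j]
    return nll / n + lam * (alpha * l1 + 0.5 * (1.0 - alpha) * l2)


@numba.njit(cache=True, fastmath=True)
def _nb_fit_at_lambda(Xs, Xs2, U, y, lam, alpha, coef_u_in, beta_in, tol,
                      max_iter, record_trace):
    """Proximal-Newton / coordinate-descent solve at one lambda (warm started).

    Returns (coef_u, beta, converged, n_iter, objective trace, trace length).
    """
    n, p = Xs.shape
    q = U.shape[1]
    coef_u = coef_u_in.copy()
    beta = beta_in.copy()
    eta = U @ coef_u + Xs @ beta
    obj = _nb_objective(eta, y, beta, lam, alpha, n)
    trace = np.zeros(max_iter + 1)
    tlen = 0
    if record_trace:
        trace[tlen] = obj
        tlen += 1
    converged = False
    it = 0
    eye = np.eye(q) * 1e-12
    for it in range(1, max_iter + 1):
        w = np.empty(n)
        wr = np.empty(n)  # w_i * (working residual r_i)
        for i in range(n):
            pr = 0.5 * (1.0 + np.tanh(0.5 * eta[i]))
            if pr < _P_CLIP:
                pr = _P_CLIP
            elif pr > 1.0 - _P_CLIP:
                pr = 1.0 - _P_CLIP
            w[i] = pr * (1.0 - pr)
            wr[i] = y[i] - pr  # = w * ((y - p)/w)
        coef_u0 = coef_u.copy()
        beta0 = beta.copy()

        wx2 = (Xs2.T @ w) / n
        denom = wx2 + lam * (1.0 - alpha)
        thresh = lam * alpha

        active = beta0 != 0.0
        H = (U * w.reshape(-1, 1)).T @ U + eye
        for _inner in range(200):
            # exact unpenalized-block update (w fixed within the quadratic)
            delta_u = np.linalg.solve(H, U.T @ wr)
            coef_u += delta_u
            Ud = U @ delta_u
            for i in range(n):
                wr[i] -= w[i] * Ud[i]
            # coordinate descent on the active set
            for _sweep in range(1000):
                max_delta = 0.0
                for j in range(p):
                    if not active[j]:
                        continue
                    bj = beta[j]
                    gj = 0.0
                    for i in range(n):
                        gj += Xs[i, j] * wr[i]
                    gj = gj / n + wx2[j] * bj
                    if gj > thresh:
                        bnew = (gj - thresh) / denom[j] if denom[j] > 0 else 0.0
                    elif gj < -thresh:
                        bnew = (gj + thresh) / denom[j] if denom[j] > 0 else 0.0
                    else:
                        bnew = 0.0
                    if bnew != bj:
                        d = bnew - bj
                        for i in range(n):
                            wr[i] -= w[i] * Xs[i, j] * d
                        beta[j] = bnew
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                if max_delta < 1e-9:
                    break
            # KKT check over all coordinates
            g = Xs.T @ wr / n
            nviol = 0
            for j in range(p):
                if (not active[j]) and beta[j] == 0.0 and abs(g[j]) > thresh * (1.0 + 1e-9):
                    active[j] = True
                    nviol += 1
            if nviol == 0:
                break

        # step halving guards the true (non-quadratic) objective
        du = coef_u - coef_u0
        db = beta - beta0
        t = 1.0
        cu_t = coef_u
        b_t = beta
        eta_t = U @ cu_t + Xs @ b_t
        obj_t = _nb_objective(eta_t, y, b_t, lam, alpha, n)
        for _h in range(25):
            if obj_t <= obj + 1e-12:
                break
            t *= 0.5
            cu_t = coef_u0 + t * du
            b_t = beta0 + t * db
            eta_t = U @ cu_t + Xs @ b_t
            obj_t = _nb_objective(eta_t, y, b_t, lam, alpha, n)
        coef_u, beta, eta = cu_t, b_t, eta_t
        if record_trace:
            trace[tlen] = min(obj_t, obj)
            tlen += 1
        if abs(obj - obj_t) <= tol * (abs(obj) + 1e-12):
            converged = True
            obj = obj_t
            break
        if obj_t < obj:
            obj = obj_t
    return coef_u, beta, converged, it, trace, tlen


def _fit_at_lambda(Xs, Xs2, U, y, lam, alpha, coef_u, beta, tol, max_iter,
                   trace=None):
    """Python wrapper around the jit kernel; appends objective values to trace."""
    # column-major: the kernel's hot loops walk single columns
    coef_u, beta, converged, it, tr, tlen = _nb_fit_at_lambda(
        np.asfortranarray(Xs), np.asfortranarray(Xs2),
        np.ascontiguousarray(U), np.ascontiguousarray(y, dtype=np.float64),
        float(lam), float(alpha), np.ascontiguousarray(coef_u, dtype=np.float64),
        np.ascontiguousarray(beta, dtype=np.float64), float(tol), int(max_iter),
        trace is not None,
    )
    if trace is not None:
        trace.extend(tr[:tlen].tolist())
    return coef_u, beta, bool(converged), int(it)


def _standardize(X: np.ndarray, enabled: bool):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if not enabled:
        mean = np.zeros_like(mean)
        sd = np.ones_like(sd)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd_safe
    Xs[:, sd == 0] = 0.0  # constant columns carry no signal
    return Xs, mean, sd_safe


def _path(X, C, y, alpha, lambdas, config, trace_last=None):
    """Fit the full descending-lambda path; returns coefficients per lambda."""
    n, p = X.shape
    U = np.hstack([np.ones((n, 1)), C]) if C is not None and C.shape[1] else np.ones((n, 1))
    U = np.ascontiguousarray(U)
    Xs, mean, sd = _standardize(X, config.standardize)
    Xs = np.asfortranarray(Xs)
    Xs2 = np.asfortranarray(Xs * Xs)
    y = np.ascontiguousarray(y, dtype=np.float64)
    coef_u = fit_null_logistic(U, y)
    const_cols = X.std(axis=0) == 0
    beta = np.zeros(p)
    betas = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    covs = np.zeros((len(lambdas), U.shape[1] - 1))
    conv = np.zeros(len(lambdas), dtype=bool)
    iters = np.zeros(len(lambdas), dtype=int)
    for k, lam in enumerate(lambdas):
        trace = trace_last if (trace_last is not None and k == len(lambdas) - 1) else None
        coef_u, beta, ok, it = _fit_at_lambda(
            Xs, Xs2, U, y, lam, alpha, coef_u, beta, config.tol, config.max_iter,
            trace=trace,
        )
        conv[k], iters[k] = ok, it
        # back-transform to the original 0/1 predictor scale
        b_orig = beta / sd
        b_orig[const_cols] = 0.0
        betas[k] = b_orig
        intercepts[k] = coef_u[0] - float(b_orig @ mean)
        covs[k] = coef_u[1:]
    return betas, intercepts, covs, conv, iters


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(_sigmoid(eta), _P_CLIP, 1.0 - _P_CLIP)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_enet(
    X: np.ndarray,
    C: np.ndarray | None,
    y: np.ndarray,
    alpha: float,
    config: EnetConfig | None = None,
) -> EnetFit:
    """Fit the elastic-net logistic path and select lambda by stratified CV.

    Parameters
    ----------
    X : (n, p) array
        Penalized binary predictor block (protein-cluster presence).
    C : (n, q) array or None
        Unpenalized covariate block (SC indicators), may be empty.
    y : (n,) binary array
        Response (K-locus indicator); must contain both classes.
    alpha : float
        Elastic-net mixing parameter in (0, 1]; 1 = lasso.
    """
    config = config or EnetConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.shape[1] == 0:
            C = None
    n, p = X.shape
    if y.min() == y.max():
        raise ValueError("degenerate response: y must contain both classes")

    U_full = np.hstack([np.ones((n, 1)), C]) if C is not None else np.ones((n, 1))
    Xs_full, _, _ = _standardize(X, config.standardize)
    lam_max = lambda_max(Xs_full, U_full, y, alpha)
    lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)

    # folds never exceed the minority-class count (keeps every fold two-class)
    n_splits = max(2, min(config.cv_folds, int(y.sum()), int((1 - y).sum())))
    folds = StratifiedKFold(n_splits=n_splits, shuffle=True,
                            random_state=config.seed)
    dev = np.zeros((n_splits, len(lambdas)))
    for f, (tr, te) in enumerate(folds.split(X, y)):
        Ctr = C[tr] if C is not None else None
        betas, icpt, covs, _, _ = _path(X[tr], Ctr, y[tr], alpha, lambdas, config)
        Ute = np.hstack([np.ones((len(te), 1)), C[te]]) if C is not None else np.ones((len(te), 1))
        for k in range(len(lambdas)):
            eta = Ute @ np.concatenate([[icpt[k]], covs[k]]) + X[te] @ betas[k]
            dev[f, k] = _deviance(eta, y[te])
    mean_dev = dev.mean(axis=0)
    best_k = int(np.argmin(mean_dev))  # ties -> first index = strongest penalty

    trace: list[float] = []
    betas, icpt, covs, conv, iters = _path(X, C, y, alpha, lambdas, config,
                                           trace_last=trace)
    return EnetFit(
        alpha=alpha,
        lambdas=lambdas,
        lambda_best=float(lambdas[best_k]),
        intercept=float(icpt[best_k]),
        covariate_coefs=covs[best_k],
        beta=betas[best_k],
        cv_deviance=mean_dev,
        beta_path=betas,
        converged=conv,
        n_iter=iters,
        objective_trace=trace,
    )
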