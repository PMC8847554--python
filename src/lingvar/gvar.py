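"""Sparse lag-1 graphical VAR estimation for one person's daily series.

Model: y_t = B y_{t-1} + eps_t with eps_t ~ N(0, K^{-1}). The temporal
matrix B is estimated by row-wise L1-penalised regression, the innovation
precision K by graphical lasso on the residual covariance, alternating to
convergence. The contemporaneous network is the partial-correlation matrix
Omega with omega_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj).

Model selection minimises EBIC over a (lambda_B x lambda_K) grid; at
gamma = 0 this is plain BIC, which deliberately prefers denser networks.
Everything here is deterministic: identical inputs give identical fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Estimator settings.

    ``lambda_beta_values`` / ``lambda_kappa_values`` override the automatic
    log-spaced grids; useful for large simulation studies where a fixed
    small penalty (or 0 for the unpenalised fit) is sufficient.
    """

    n_lambda: int = 10
    gamma: float = 0.0
    lambda_min_ratio: float = 0.01
    pairing_policy: str = "concatenate"  # or "calendar"
    max_iterations: int = 100
    tolerance: float = 1e-4
    standardise: bool = True
    lambda_beta_values: tuple[float, ...] | None = None
    lambda_kappa_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.pairing_policy not in ("concatenate", "calendar"):
            raise ValueError(f"unknown pairing policy {self.pairing_policy!r}")


@dataclass
class GvarFit:
    """One fitted personalised network.

    ``temporal[i, j]`` is the effect of node j at t-1 on node i at t;
    ``pcc`` is the contemporaneous partial-correlation matrix (symmetric,
    zero diagonal, entries in [-1, 1]).
    """

    node_names: list[str]
    temporal: np.ndarray
    precision: np.ndarray
    pcc: np.ndarray
    lambda_beta: float
    lambda_kappa: float
    ebic: float
    n_days: int
    n_pairs: int
    converged: bool = True
    loglik: float = float("nan")


def make_lag_pairs(matrix, policy: str = "concatenate") -> tuple[np.ndarray, np.ndarray]:
    """Build (current, lagged) row pairs from a daily feature matrix.

    ``concatenate`` pairs consecutive *observed* rows regardless of calendar
    gaps (missing days are simply absent); ``calendar`` keeps only pairs of
    truly adjacent calendar days.
    """
    values = matrix.values
    if len(values) < 2:
        raise ValueError("insufficient data: need at least 2 rows")
    if policy == "concatenate":
        current, lagged = values[1:], values[:-1]
    elif policy == "calendar":
        keep = [i for i in range(1, len(values))
                if (matrix.dates[i] - matrix.dates[i - 1]).days == 1]
        current = values[keep]
        lagged = values[[i - 1 for i in keep]]
    else:
        raise ValueError(f"unknown pairing policy {policy!r}")
    if len(current) < 2:
        raise ValueError("insufficient data: fewer than 2 usable pairs")
    return current, lagged


def standardise_series(current: np.ndarray, lagged: np.ndarray,
                       stats: tuple[np.ndarray, np.ndarray] | None = None,
                       node_names: list[str] | None = None):
    """Z-score both blocks with one mean/SD per node.

    By default the statistics come from the person's full series (the
    stacked unique rows); pass ``stats=(mean, sd)`` to reuse precomputed
    ones. A zero-variance node is an error, not a silent drop.
    """
    if stats is None:
        full = np.vstack([lagged[:1], current]) if len(current) == len(lagged) else np.vstack([lagged, current])
        mean = full.mean(axis=0)
        sd = full.std(axis=0, ddof=1)
    else:
        mean, sd = stats
    bad = np.flatnonzero(sd <= 1e-10 * np.maximum(np.abs(mean), 1.0))
    if bad.size:
        names = [node_names[i] if node_names else str(i) for i in bad]
        raise ValueError(f"zero-variance node(s): {names}")
    return (current - mean) / sd, (lagged - mean) / sd, mean, sd


def _safe_inverse(S: np.ndarray) -> np.ndarray:
    """Invert a covariance, ridge-jittering if it is not PD."""
    p = S.shape[0]
    scale = max(float(np.mean(np.diag(S))), 1e-12)
    jitter = 0.0
    for _ in range(12):
        Sj = S + jitter * np.eye(p) if jitter else S
        try:
            L = np.linalg.cholesky(Sj)
            d = np.diag(L)
            # (max/min diag of L)^2 approximates the condition number;
            # refuse wildly ill-conditioned inverses (rank-deficient residuals)
            if (d.max() / d.min()) ** 2 < 1e10:
                Linv = np.linalg.solve(L, np.eye(p))
                K = Linv.T @ Linv
                return (K + K.T) / 2
        except np.linalg.LinAlgError:
            pass
        jitter = 1e-6 * scale if jitter == 0 else jitter * 10
        log.debug("ill-conditioned residual covariance; ridge jitter %.1e applied", jitter)
    raise np.linalg.LinAlgError("residual covariance could not be inverted")


def _update_temporal(current: np.ndarray, lagged: np.ndarray, lam: float) -> np.ndarray:
    n, p = current.shape
    if lam <= 0:
        coef, *_ = np.linalg.lstsq(lagged, current, rcond=None)
        return coef.T
    B = np.empty((p, p))
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=2000, tol=1e-6)
    for i in range(p):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(lagged, current[:, i])
        B[i] = model.coef_
    return B


def _update_precision(S: np.ndarray, lam: float) -> np.ndarray:
    if lam <= 0:
        return _safe_inverse(S)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, K = graphical_lasso(S, alpha=lam, max_iter=200)
        return K
    except FloatingPointError:
        log.debug("graphical lasso failed; retrying with jittered covariance")
        S = S + 1e-6 * np.eye(S.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, K = graphical_lasso(S, alpha=lam, max_iter=200)
        return K


def fit_at(current: np.ndarray, lagged: np.ndarray, lambda_beta: float,
           lambda_kappa: float, config: FitConfig = FitConfig()):
    """Fit (B, K) at fixed penalties by alternating optimisation.

    Returns (B, K, loglik, converged) where loglik is the Gaussian profile
    log-likelihood (n/2)(log det K - trace(S K)) up to its constant.
    """
    n, p = current.shape
    if lambda_beta <= 0 and lambda_kappa <= 0:
        # both updates are closed-form and B does not depend on K: one pass
        B = _update_temporal(current, lagged, 0.0)
        resid = current - lagged @ B.T
        S = resid.T @ resid / n
        K = _update_precision(S, 0.0)
        sign, logdet = np.linalg.slogdet(K)
        loglik = 0.5 * n * (logdet - float(np.sum(S * K))) if sign > 0 else -np.inf
        return B, K, loglik, True
    B = np.zeros((p, p))
    K = np.eye(p)
    converged = False
    for _ in range(config.max_iterations):
        B_new = _update_temporal(current, lagged, lambda_beta)
        resid = current - lagged @ B_new.T
        S = resid.T @ resid / n
        K_new = _update_precision(S, lambda_kappa)
        delta = max(np.max(np.abs(B_new - B)), np.max(np.abs(K_new - K)))
        B, K = B_new, K_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        log.warning("fit did not converge within %d iterations", config.max_iterations)
    resid = current - lagged @ B.T
    S = resid.T @ resid / n
    sign, logdet = np.linalg.slogdet(K)
    loglik = 0.5 * n * (logdet - float(np.sum(S * K))) if sign > 0 else -np.inf
    return B, K, loglik, converged


def lambda_grid(current: np.ndarray, lagged: np.ndarray,
                config: FitConfig = FitConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced penalty grids, from full-shrinkage maxima downwards.

    The kappa maximum is the largest absolute off-diagonal of the covariance
    of ``current`` (the residual covariance when B = 0); the beta maximum is
    max |lagged' current| / n, the smallest penalty at which every lasso
    coefficient is zero.
    """
    n = current.shape[0]
    S0 = current.T @ current / n
    off = S0 - np.diag(np.diag(S0))
    kappa_max = float(np.max(np.abs(off)))
    beta_max = float(np.max(np.abs(lagged.T @ current)) / n)

    def grid(top: float) -> np.ndarray:
        if top <= 0:
            log.warning("degenerate cross-products; single-point grid {0}")
            return np.array([0.0])
        if config.n_lambda == 1:
            return np.array([top])
        return np.geomspace(top, top * config.lambda_min_ratio, config.n_lambda)

    return grid(beta_max), grid(kappa_max)


def pcc_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix.

    omega_ij = -kappa_ij / sqrt(kappa_ii * kappa_jj), zero diagonal.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision matrix must be positive definite")
    try:
        # tiny relative jitter: badly conditioned but PD matrices may fail
        # an exact Cholesky numerically
        np.linalg.cholesky((K + K.T) / 2 + (1e-12 * d.max()) * np.eye(K.shape[0]))
    except np.linalg.LinAlgError:
        raise ValueError("precision matrix must be positive definite") from None
    omega = -K / np.sqrt(np.outer(d, d))
    omega = (omega + omega.T) / 2
    np.fill_diagonal(omega, 0.0)
    return np.clip(omega, -1.0, 1.0)


def ebic_of(B: np.ndarray, K: np.ndarray, loglik: float, n: int, gamma: float,
            zero_tol: float = 1e-8) -> float:
    """EBIC = -2 loglik + E log n + 4 gamma E log(#candidate parameters).

    E counts the nonzero entries of B plus nonzero upper-triangle
    off-diagonals of K; at gamma = 0 this is plain BIC.
    """
    p = B.shape[0]
    e_temporal = int(np.sum(np.abs(B) > zero_tol))
    e_contemp = int(np.sum(np.abs(K[np.triu_indices(p, k=1)]) > zero_tol))
    E = e_temporal + e_contemp
    n_candidate = p * p + p * (p - 1) // 2
    return -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(n_candidate)


@dataclass(frozen=True)
class _Candidate:
    lambda_beta: float
    lambda_kappa: float
    B: np.ndarray = field(repr=False, compare=False, default=None)
    K: np.ndarray = field(repr=False, compare=False, default=None)
    loglik: float = float("nan")
    ebic: float = float("nan")
    converged: bool = True


def select_ebic(candidates: list[_Candidate], gamma: float, node_names: list[str],
                n_days: int, n_pairs: int) -> GvarFit:
    """Pick the EBIC-minimising fit; ties go to the smaller penalties."""
    if not candidates:
        raise ValueError("no candidate fits")
    best = min(candidates, key=lambda c: (round(c.ebic, 10), c.lambda_beta, c.lambda_kappa))
    return GvarFit(
        node_names=list(node_names),
        temporal=best.B,
        precision=best.K,
        pcc=pcc_from_precision(best.K),
        lambda_beta=best.lambda_beta,
        lambda_kappa=best.lambda_kappa,
        ebic=best.ebic,
        n_days=n_days,
        n_pairs=n_pairs,
        converged=best.converged,
        loglik=best.loglik,
    )


def estimate_network(matrix, nodes: list[str] | None = None,
                     config: FitConfig = FitConfig()) -> GvarFit:
    """End-to-end: subset nodes, pair, standardise, fit the grid, select."""
    if nodes is not None:
        if not nodes:
            raise ValueError("node subset is empty")
        matrix = matrix.select_features(nodes)
    current, lagged = make_lag_pairs(matrix, config.pairing_policy)
    if config.standardise:
        mean = matrix.values.mean(axis=0)
        sd = matrix.values.std(axis=0, ddof=1)
        current, lagged, _, _ = standardise_series(
            current, lagged, stats=(mean, sd), node_names=matrix.feature_names)
    n = current.shape[0]

    if config.lambda_beta_values is not None:
        beta_grid = np.asarray(config.lambda_beta_values, dtype=float)
    else:
        beta_grid, _ = lambda_grid(current, lagged, config)
    if config.lambda_kappa_values is not None:
        kappa_grid = np.asarray(config.lambda_kappa_values, dtype=float)
    else:
        _, kappa_grid = lambda_grid(current, lagged, config)

    candidates = []
    for lb in beta_grid:
        for lk in kappa_grid:
            B, K, ll, conv = fit_at(current, lagged, float(lb), float(lk), config)
            candidates.append(_Candidate(
                lambda_beta=float(lb), lambda_kappa=float(lk), B=B, K=K,
                loglik=ll, ebic=ebic_of(B, K, ll, n, config.gamma), converged=conv))
    fit = select_ebic(candidates, config.gamma, matrix.feature_names,
                      n_days=matrix.n_days, n_pairs=n)
    log.debug("user %s: selected lambda_beta=%.4g lambda_kappa=%.4g ebic=%.2f n=%d",
              matrix.user_id, fit.lambda_beta, fit.lambda_kappa, fit.ebic, n)
    return fit
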