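"""Weighted-LASSO solver: scaled-dual ADMM with Armijo-tuned learning rate.

Solves, for a fixed penalty level ``lam`` and per-coordinate weights ``w``,

    minimize  f(beta) + lam * ||w * beta||_1,
    f(beta) = (1/2) ||X beta - y||_2^2        (no 1/n factor),

by alternating

    beta <- argmin f(beta) + (1/(2 rho)) ||beta - (theta - u)||^2
         =  (X'X + (1/rho) I)^{-1} (X'y + (1/rho)(theta - u))
    theta <- S_{lam * rho * w}(beta + u)
    u <- u + beta - theta

where ``rho`` is re-tuned every iteration by a backtracking Armijo line
search (start rho0, halve until sufficient decrease) and convergence is
declared when ``||beta - theta||_inf <= eps_admm * (1 + ||u||_inf)``.

The beta-update never forms the q x q Gram matrix: a one-time
eigendecomposition of the n x n matrix X X' (p >> n) lets any learning
rate be handled at O(n^2 + n q) per solve via the matrix-inversion lemma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "ADMMState",
    "FitDiagnostics",
    "QuadraticCache",
    "soft_threshold",
    "prox_quadratic",
    "armijo_line_search",
    "admm_fit",
    "check_convergence",
    "penalized_objective",
    "kkt_residual",
]


@dataclass
class FitConfig:
    """Solver settings.

    eps_admm between 1e-4 and 1e-3 is the recommended range; smaller
    values buy accuracy at the cost of iterations.
    """

    eps_admm: float = 1e-4
    max_iter: int = 10000
    rho0: float = 1.0
    backtrack_factor: float = 0.5
    weight_cap: float = 1e12
    gamma: float = 1.0
    rho_floor: float = 1e-12
    linesearch_per_iteration: bool = True  # re-tune rho at every ADMM update
    reset_rho: bool = True  # restart each search from rho0 (vs 2x previous)
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.eps_admm <= 0:
            raise ValueError("eps_admm must be positive")
        if not 0.0 < self.backtrack_factor < 1.0:
            raise ValueError("backtrack_factor must be in (0, 1)")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass
class ADMMState:
    """Solver triple (beta, theta, u) plus learning rate and counter."""

    beta: np.ndarray
    theta: np.ndarray
    u: np.ndarray
    rho: float
    t: int = 0

    def __post_init__(self) -> None:
        if not (len(self.beta) == len(self.theta) == len(self.u)):
            raise ValueError("beta, theta, u must have equal length")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class FitDiagnostics:
    converged: bool
    n_iter: int
    objective: float
    primal_residual_inf: float
    rho_final: float
    primal_residual_trace: list = field(default_factory=list)
    rho_trace: list = field(default_factory=list)
    objective_trace: list = field(default_factory=list)


class QuadraticCache:
    """Spectral factorization of X X' enabling the beta-update at any rho.

    Stores ``X``, ``X'y``, ``X X'y`` and the eigendecomposition
    ``X X' = Q diag(evals) Q'``; ``prox_quadratic`` then costs two
    matrix-vector products with X and two with Q.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, check: bool = True):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        self.X = X
        self.Xty = X.T @ y
        gram = X @ X.T
        evals, Q = np.linalg.eigh(gram)
        self.evals = np.maximum(evals, 0.0)  # clip tiny negative round-off
        self.Q = Q
        self.XXty = X @ self.Xty
        if check:
            recon = (Q * evals) @ Q.T
            denom = np.linalg.norm(gram)
            err = np.linalg.norm(recon - gram) / denom if denom > 0 else 0.0
            if err > 1e-8:
                raise np.linalg.LinAlgError(
                    f"Gram eigendecomposition reconstruction error {err:.2e}"
                )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]


def soft_threshold(v: np.ndarray, kappa) -> np.ndarray:
    """Elementwise shrinkage S_kappa(v) = (v - kappa)_+ - (-v - kappa)_+."""
    v = np.asarray(v, dtype=np.float64)
    kappa = np.asarray(kappa, dtype=np.float64)
    if np.any(kappa < 0):
        raise ValueError("soft-threshold kappa must be nonnegative")
    return np.sign(v) * np.maximum(np.abs(v) - kappa, 0.0)


def prox_quadratic(v: np.ndarray, rho: float, cache: QuadraticCache) -> np.ndarray:
    """argmin_b (1/2)||Xb - y||^2 + (1/(2 rho))||b - v||^2 via Woodbury.

    Equals (X'X + (1/rho) I)^{-1} (X'y + (1/rho) v), computed through the
    n x n factorization — the q x q system is never formed.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    c = 1.0 / rho
    v = np.asarray(v, dtype=np.float64).ravel()
    b = cache.Xty + c * v
    Xb = cache.XXty + c * (cache.X @ v)
    t = cache.Q @ ((cache.Q.T @ Xb) / (cache.evals + c))
    return (b - cache.X.T @ t) / c


def armijo_line_search(
    beta: np.ndarray,
    candidate_fn: Callable[[float], np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    config: FitConfig,
    rho_start: Optional[float] = None,
    grad: Optional[np.ndarray] = None,
    f_beta: Optional[float] = None,
) -> float:
    """Backtrack rho until the sufficient-decrease condition holds.

    Starting from ``rho_start`` (default ``config.rho0``) and halving by
    ``config.backtrack_factor``, accepts the first rho whose candidate
    point z = candidate_fn(rho) satisfies

        f(z) <= f(beta) + grad(beta)'(z - beta) + (1/(2 rho))||z - beta||^2.

    Raises ``FloatingPointError`` if no rho above ``config.rho_floor``
    qualifies.
    """
    beta = np.asarray(beta, dtype=np.float64).ravel()
    if grad is None:
        r = X @ beta - y
        grad = X.T @ r
        f_beta = 0.5 * float(r @ r)
    elif f_beta is None:
        r = X @ beta - y
        f_beta = 0.5 * float(r @ r)
    rho = config.rho0 if rho_start is None else rho_start
    slack = 1e-12 * (1.0 + abs(f_beta))
    while rho > config.rho_floor:
        z = candidate_fn(rho)
        dz = z - beta
        rz = X @ z - y
        f_z = 0.5 * float(rz @ rz)
        bound = f_beta + float(grad @ dz) + float(dz @ dz) / (2.0 * rho)
        if f_z <= bound + slack:
            # invariant: accepted rho satisfies the inequality it was tested on
            assert f_z <= bound + slack
            return rho
        rho *= config.backtrack_factor
    raise FloatingPointError(
        f"Armijo line search found no acceptable rho above {config.rho_floor:g}; "
        "the iteration appears to diverge"
    )


def check_convergence(state: ADMMState, eps_admm: float) -> bool:
    """Scaled infinity-norm criterion on the primal residual beta - theta."""
    resid = np.max(np.abs(state.beta - state.theta)) if len(state.beta) else 0.0
    return bool(resid <= eps_admm * (1.0 + np.max(np.abs(state.u), initial=0.0)))


def penalized_objective(
    X: np.ndarray, y: np.ndarray, theta: np.ndarray, lam: float, w=1.0
) -> float:
    """(1/2)||X theta - y||^2 + lam * ||w * theta||_1."""
    r = X @ theta - y
    return 0.5 * float(r @ r) + lam * float(np.sum(np.abs(np.asarray(w) * theta)))


def kkt_residual(
    X: np.ndarray, y: np.ndarray, theta: np.ndarray, lam: float, w=1.0
) -> float:
    """Max KKT violation of the weighted LASSO, on the lambda scale.

    For zero coordinates, (|x_j' r| - lam w_j)_+ ; for active ones,
    |x_j' r + lam w_j sign(theta_j)|.  Returns max over j divided by lam.
    """
    g = X.T @ (X @ theta - y)
    w = np.broadcast_to(np.asarray(w, dtype=np.float64), g.shape)
    active = theta != 0
    viol = np.where(
        active,
        np.abs(g + lam * w * np.sign(theta)),
        np.maximum(np.abs(g) - lam * w, 0.0),
    )
    return float(np.max(viol) / lam)


def admm_fit(
    X,
    y,
    lam: float,
    weights=None,
    config: Optional[FitConfig] = None,
    warm: Optional[tuple[np.ndarray, np.ndarray]] = None,
    cache: Optional[QuadraticCache] = None,
) -> tuple[ADMMState, FitDiagnostics]:
    """Run ADMM to convergence at a fixed penalty level.

    Parameters
    ----------
    X, y : arrays or objects with a ``values`` attribute
        Training design and (centered) phenotype.
    lam : float
        Penalty level (> 0); on the ``||X'y||_inf`` scale (no 1/n loss factor).
    weights : array or AdaptiveWeights, optional
        Per-coordinate penalty weights w (default all ones).
    warm : (beta, theta), optional
        Warm start; u always initializes to 0.
    cache : QuadraticCache, optional
        Reusable factorization of the training data (built if absent).

    Returns
    -------
    (ADMMState, FitDiagnostics)
        Hitting ``max_iter`` is reported via ``diagnostics.converged``,
        not raised, so a surrounding search can proceed with a warning.
    """
    X = getattr(X, "values", X)
    y = getattr(y, "values", y)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if lam <= 0:
        raise ValueError("lam must be positive")
    config = config or FitConfig()
    q = X.shape[1]
    w = np.ones(q) if weights is None else np.asarray(getattr(weights, "w", weights), dtype=np.float64)
    if w.shape != (q,):
        raise ValueError("weights length must match design width")
    if cache is None:
        cache = QuadraticCache(X, y)

    if warm is not None:
        beta = np.array(warm[0], dtype=np.float64).ravel().copy()
        theta = np.array(warm[1], dtype=np.float64).ravel().copy()
    else:
        beta = np.zeros(q)
        theta = np.zeros(q)
    u = np.zeros(q)
    rho = config.rho0
    state = ADMMState(beta=beta, theta=theta, u=u, rho=rho)
    diag = FitDiagnostics(False, 0, np.nan, np.inf, rho)

    lamw = lam * w
    theta_prev = theta.copy()
    for t in range(config.max_iter):
        if config.linesearch_per_iteration or t == 0:
            r = X @ beta - y
            grad = X.T @ r
            f_beta = 0.5 * float(r @ r)
            start = config.rho0 if (config.reset_rho or t == 0) else min(
                config.rho0, 2.0 * rho
            )
            new_rho = armijo_line_search(
                beta,
                lambda rr: soft_threshold(beta - rr * grad, lamw * rr),
                X,
                y,
                config,
                rho_start=start,
                grad=grad,
                f_beta=f_beta,
            )
            if new_rho != rho and t > 0:
                u *= new_rho / rho  # keep the unscaled dual fixed across rho changes
            rho = new_rho

        beta = prox_quadratic(theta - u, rho, cache)
        theta = soft_threshold(beta + u, lamw * rho)
        u = u + beta - theta

        if not np.all(np.isfinite(beta)):
            raise FloatingPointError(f"non-finite ADMM iterate at t={t}")

        state = ADMMState(beta=beta, theta=theta, u=u, rho=rho, t=t + 1)
        resid = float(np.max(np.abs(beta - theta), initial=0.0))
        if config.verbose:
            diag.primal_residual_trace.append(resid)
            diag.rho_trace.append(rho)
            diag.objective_trace.append(penalized_objective(X, y, theta, lam, w))
        # Primal criterion alone can fire while iterates still move (the
        # near-unpenalized regime, where u ~ lam*rho and beta - theta
        # vanishes long before beta is stationary); require theta
        # stationarity on the same scale as well.
        theta_moved = float(np.max(np.abs(theta - theta_prev), initial=0.0))
        theta_prev = theta
        if check_convergence(state, config.eps_admm) and theta_moved <= config.eps_admm * (
            1.0 + float(np.max(np.abs(theta), initial=0.0))
        ):
            diag.converged = True
            break

    diag.n_iter = state.t
    diag.primal_residual_inf = float(np.max(np.abs(state.beta - state.theta), initial=0.0))
    diag.rho_final = rho
    diag.objective = penalized_objective(X, y, state.theta, lam, w)
    if not diag.converged:
        logger.warning(
            "ADMM did not converge in %d iterations (primal residual %.3g)",
            config.max_iter,
            diag.primal_residual_inf,
        )
    return state, diag
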