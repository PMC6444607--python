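"""Penalty-level tuning: lambda_max and golden-section search on test error.

The search brackets the optimum of the (assumed unimodal) squared test
error SE(lambda) between ``lam_a`` and ``lam_b``, evaluates both interior
golden points once, and thereafter re-evaluates exactly one point per
iteration (the ``flag`` bookkeeping), shrinking the bracket by 1/phi per
step until the relative width |lam_d - lam_c| / ((lam_c + lam_d)/2)
drops below ``eps_gss``.  Solver fits are warm-started from the previous
evaluation's (beta, theta) with the dual reset to zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .admm import FitConfig, QuadraticCache, admm_fit
from .weights import AdaptiveWeights, marginal_weights

logger = logging.getLogger(__name__)

PHI = (1.0 + math.sqrt(5.0)) / 2.0

__all__ = [
    "PHI",
    "GSSBracket",
    "SearchResult",
    "lambda_max",
    "se_test",
    "golden_section_search",
    "auto_fit",
]


@dataclass
class GSSBracket:
    """Bracketing state lam_a < lam_c < lam_d < lam_b with cached interior fits."""

    lam_a: float
    lam_b: float
    eps_gss: float
    lam_c: float = field(init=False)
    lam_d: float = field(init=False)
    se_c: float = math.nan
    se_d: float = math.nan
    theta_c: Optional[np.ndarray] = None
    theta_d: Optional[np.ndarray] = None
    flag: int = 1  # 1 -> lam_c needs (re)evaluation, 0 -> lam_d does

    def __post_init__(self) -> None:
        if not 0 < self.lam_a < self.lam_b:
            raise ValueError("require 0 < lam_a < lam_b")
        if not 0 < self.eps_gss < 1:
            raise ValueError("eps_gss must be in (0, 1)")
        # track the width explicitly: dividing by phi each shrink is exact to
        # one ulp, whereas lam_b - lam_a cancels catastrophically once the
        # bracket is narrow
        self._width = self.lam_b - self.lam_a
        self._set_interior()

    def _set_interior(self) -> None:
        self.lam_c = self.lam_b - self._width / PHI
        self.lam_d = self.lam_a + self._width / PHI

    @property
    def width(self) -> float:
        return self._width

    def converged(self) -> bool:
        mid = 0.5 * (self.lam_c + self.lam_d)
        return abs(self.lam_d - self.lam_c) / mid < self.eps_gss

    def shrink(self) -> None:
        """Move one endpoint toward the smaller cached SE; tie moves lam_a."""
        if self.se_c < self.se_d:
            self.lam_b = self.lam_d
            self.se_d, self.theta_d = self.se_c, self.theta_c
            self.se_c, self.theta_c = math.nan, None
            self.flag = 1
        else:
            self.lam_a = self.lam_c
            self.se_c, self.theta_c = self.se_d, self.theta_d
            self.se_d, self.theta_d = math.nan, None
            self.flag = 0
        self._width /= PHI
        self._set_interior()


@dataclass
class SearchResult:
    lam_opt: float
    theta_opt: np.ndarray
    se_test_opt: float
    n_lambda_evaluated: int
    trace: list[tuple[float, float]]
    lam_max: float = math.nan
    weights: Optional[AdaptiveWeights] = None
    converged: bool = True


def lambda_max(X, y) -> float:
    """Smallest penalty zeroing the unweighted LASSO: ||X'y||_inf."""
    X = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(getattr(y, "values", y), dtype=np.float64).ravel()
    val = float(np.max(np.abs(X.T @ y), initial=0.0))
    if val == 0.0:
        warnings.warn("lambda_max is 0 (y orthogonal to every column)", stacklevel=2)
    return val


def se_test(theta, X_test, y_test) -> float:
    """Halved squared prediction error (1/2)||X theta - y||^2 on the test set."""
    X_test = np.asarray(getattr(X_test, "values", X_test), dtype=np.float64)
    y_test = np.asarray(getattr(y_test, "values", y_test), dtype=np.float64).ravel()
    r = X_test @ np.asarray(theta, dtype=np.float64).ravel() - y_test
    return 0.5 * float(r @ r)


def golden_section_search(
    fit: Callable[..., tuple[Optional[np.ndarray], float]],
    lam_a: float,
    lam_b: float,
    eps_gss: float = 1e-2,
    evaluate_endpoints: bool = True,
) -> SearchResult:
    """Minimize SE(lambda) over [lam_a, lam_b] by golden-section bracketing.

    ``fit(lam, warm=...)`` must return ``(theta, se)``; ``theta`` may be
    None for analytic test functions, and is otherwise passed back as the
    warm start of the next evaluation.  After the two initial interior
    evaluations exactly one fit runs per bracket iteration; the final
    answer is a fresh fit at lam_opt = (lam_c + lam_d)/2.
    """
    trace: list[tuple[float, float]] = []
    last_warm: dict = {"theta": None}
    n_evals = 0

    def evaluate(lam: float) -> tuple[Optional[np.ndarray], float]:
        nonlocal n_evals
        theta, se = fit(lam, warm=last_warm["theta"])
        if theta is not None:
            last_warm["theta"] = theta
        n_evals += 1
        trace.append((lam, se))
        return theta, se

    if evaluate_endpoints:
        evaluate(lam_a)
        evaluate(lam_b)

    br = GSSBracket(lam_a=lam_a, lam_b=lam_b, eps_gss=eps_gss)
    br.theta_c, br.se_c = evaluate(br.lam_c)
    br.theta_d, br.se_d = evaluate(br.lam_d)
    while True:
        br.shrink()
        if br.converged():
            break
        if br.flag == 1:
            br.theta_c, br.se_c = evaluate(br.lam_c)
        else:
            br.theta_d, br.se_d = evaluate(br.lam_d)
        logger.info(
            "GSS bracket [%.6g, %.6g] interior (%.6g, %.6g) SE (%.6g, %.6g)",
            br.lam_a, br.lam_b, br.lam_c, br.lam_d, br.se_c, br.se_d,
        )

    lam_opt = 0.5 * (br.lam_c + br.lam_d)
    theta_opt, se_opt = evaluate(lam_opt)
    distinct = len({lam for lam, _ in trace})
    return SearchResult(
        lam_opt=lam_opt,
        theta_opt=theta_opt if theta_opt is not None else np.empty(0),
        se_test_opt=se_opt,
        n_lambda_evaluated=distinct,
        trace=trace,
    )


def auto_fit(
    train: tuple,
    test: tuple,
    config: Optional[FitConfig] = None,
    lam_a_frac: float = 0.001,
    lam_b_frac: float = 1.0,
    eps_gss: float = 1e-2,
) -> SearchResult:
    """Full pipeline for encoded, centered data: weights -> lambda_max -> GSS.

    ``train`` and ``test`` are (X, y) pairs; ``y_test`` must be centered
    with the training mean.  Adaptive weights come from the marginal pilot
    with ``config.gamma`` (gamma = 0 yields the plain LASSO).  Returns a
    SearchResult carrying the trace, the weights and lambda_max.
    """
    if not 0 < lam_a_frac < lam_b_frac <= 1:
        raise ValueError("require 0 < lam_a_frac < lam_b_frac <= 1")
    config = config or FitConfig()
    X_tr = np.asarray(getattr(train[0], "values", train[0]), dtype=np.float64)
    y_tr = np.asarray(getattr(train[1], "values", train[1]), dtype=np.float64).ravel()
    X_te = np.asarray(getattr(test[0], "values", test[0]), dtype=np.float64)
    y_te = np.asarray(getattr(test[1], "values", test[1]), dtype=np.float64).ravel()

    wts = marginal_weights(X_tr, y_tr, gamma=config.gamma, weight_cap=config.weight_cap)
    lmax = lambda_max(X_tr, y_tr)
    if lmax == 0.0:
        raise ValueError("degenerate problem: lambda_max is 0")
    cache = QuadraticCache(X_tr, y_tr)
    all_converged = True

    # GSS treats the (beta, theta) pair as an opaque warm-start payload
    def fit_at(lam: float, warm=None):
        nonlocal all_converged
        state, diag = admm_fit(
            X_tr, y_tr, lam, weights=wts, config=config, warm=warm, cache=cache
        )
        if not diag.converged:
            all_converged = False
        return (state.beta, state.theta), se_test(state.theta, X_te, y_te)

    res = golden_section_search(
        fit_at, lam_a_frac * lmax, lam_b_frac * lmax, eps_gss=eps_gss
    )
    res.lam_max = lmax
    res.weights = wts
    res.converged = all_converged
    res.theta_opt = np.asarray(res.theta_opt[1])
    return res
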