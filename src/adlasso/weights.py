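"""Adaptive-LASSO weights from univariate marginal regression coefficients.

The pilot estimate is beta_hat_j = x_j' y / n per design column; the
penalty weight is w_j = 1 / |beta_hat_j|^gamma, capped at ``weight_cap``
so that columns uncorrelated with the phenotype get a finite (but
effectively excluding) penalty instead of an infinite one.  gamma = 0
recovers the ordinary unweighted LASSO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdaptiveWeights", "marginal_weights"]


@dataclass
class AdaptiveWeights:
    w: np.ndarray
    gamma: float
    capped_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64).ravel()
        if np.any(self.w <= 0):
            raise ValueError("adaptive weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.w)

    def to_tsv(self, path) -> None:
        """Write weights (with a capped flag) for audit."""
        capped = set(self.capped_indices)
        with open(path, "w") as fh:
            fh.write("index\tweight\tcapped\n")
            for j, wj in enumerate(self.w):
                fh.write(f"{j}\t{float(wj)!r}\t{int(j in capped)}\n")


def marginal_weights(
    X, y, gamma: float = 1.0, weight_cap: float = 1e12
) -> AdaptiveWeights:
    """Build w_j = 1/|x_j' y / n|^gamma with a cap absorbing degeneracies."""
    X = np.asarray(getattr(X, "values", X), dtype=np.float64)
    y = np.asarray(getattr(y, "values", y), dtype=np.float64).ravel()
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if weight_cap <= 0:
        raise ValueError("weight_cap must be positive")
    n = X.shape[0]
    if gamma == 0.0:
        return AdaptiveWeights(w=np.ones(X.shape[1]), gamma=0.0)
    beta_hat = (X.T @ y) / n
    mag = np.abs(beta_hat) ** gamma
    capped = mag < 1.0 / weight_cap
    w = np.empty_like(mag)
    w[capped] = weight_cap
    w[~capped] = np.minimum(1.0 / mag[~capped], weight_cap)
    return AdaptiveWeights(
        w=w, gamma=gamma, capped_indices=list(np.flatnonzero(capped | (w >= weight_cap)))
    )
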