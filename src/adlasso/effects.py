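"""Additive/dominance effect extraction, prediction and test metrics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import CovariateColumn, DesignMatrix, SnpColumn

__all__ = ["EffectsTable", "EvaluationResult", "extract_effects", "predict", "evaluate"]


@dataclass
class EffectsTable:
    """Per-SNP additive effect a = -theta(gen 0) + theta(gen 2) and
    dominance effect d = theta(gen 1)."""

    table: pd.DataFrame  # columns: snp_id, a, d, nonzero_a, nonzero_d

    @property
    def n_selected_additive(self) -> int:
        return int(self.table["nonzero_a"].sum())

    @property
    def n_selected_dominance(self) -> int:
        return int(self.table["nonzero_d"].sum())

    def top_by(self, which: str, k: int) -> pd.DataFrame:
        """Rows with the k largest |a| or |d|."""
        return self.table.reindex(
            self.table[which].abs().sort_values(ascending=False).index
        ).head(k)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class EvaluationResult:
    mse_test: float
    r_test: float
    sd_yhat: float
    sd_y: float
    cov_yhat_y: float

    def to_dict(self) -> dict:
        return {
            "mse_test": self.mse_test,
            "r_test": self.r_test,
            "sd_yhat": self.sd_yhat,
            "sd_y": self.sd_y,
            "cov_yhat_y": self.cov_yhat_y,
        }


def extract_effects(
    theta: np.ndarray, columns, zero_epsilon: float = 0.0
) -> EffectsTable:
    """Translate one-hot coefficients into per-SNP (a, d) effects.

    Covariate columns are excluded.  ``zero_epsilon`` optionally widens
    the definition of "zero" for the nonzero flags; by default exact
    sparsity from the soft-threshold is trusted.
    """
    theta = np.asarray(theta, dtype=np.float64).ravel()
    if len(theta) != len(columns):
        raise ValueError("theta length does not match column provenance")
    per_snp: dict[str, dict[int, float]] = {}
    order: list[str] = []
    for coef, col in zip(theta, columns):
        if isinstance(col, CovariateColumn):
            continue
        if not isinstance(col, SnpColumn):
            raise TypeError(f"unknown column provenance {col!r}")
        if col.snp_id not in per_snp:
            per_snp[col.snp_id] = {}
            order.append(col.snp_id)
        per_snp[col.snp_id][col.genotype_class] = float(coef)
    rows = []
    for sid in order:
        classes = per_snp[sid]
        if set(classes) != {0, 1, 2}:
            raise ValueError(f"SNP {sid!r} is missing genotype-class columns")
        a = -classes[0] + classes[2]
        d = classes[1]
        rows.append(
            {
                "snp_id": sid,
                "a": a,
                "d": d,
                "nonzero_a": abs(a) > zero_epsilon,
                "nonzero_d": abs(d) > zero_epsilon,
            }
        )
    return EffectsTable(table=pd.DataFrame(rows, columns=["snp_id", "a", "d", "nonzero_a", "nonzero_d"]))


def predict(X_new, theta: np.ndarray, training_mean: float = 0.0) -> np.ndarray:
    """yhat = X_new @ theta + training_mean (adds back the centering mean)."""
    theta = np.asarray(theta, dtype=np.float64).ravel()
    if isinstance(X_new, DesignMatrix) and len(X_new.columns) != len(theta):
        raise ValueError("design width does not match fitted coefficients")
    X = np.asarray(getattr(X_new, "values", X_new), dtype=np.float64)
    if X.shape[1] != len(theta):
        raise ValueError("design width does not match fitted coefficients")
    return X @ theta + training_mean


def evaluate(y_hat: np.ndarray, y: np.ndarray) -> EvaluationResult:
    """MSE (plain mean of squared residuals) and Pearson r with its parts.

    Variance and covariance use the population (1/n) convention; the
    convention cancels inside r.  A zero-variance prediction makes r
    undefined: reported as NaN with a warning, never silently 0.
    """
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if y_hat.shape != y.shape or len(y) < 2:
        raise ValueError("y_hat and y must have equal length >= 2")
    resid = y_hat - y
    mse = float(np.mean(resid**2))
    sd_yhat = float(y_hat.std(ddof=0))
    sd_y = float(y.std(ddof=0))
    cov = float(np.mean((y_hat - y_hat.mean()) * (y - y.mean())))
    if sd_yhat == 0.0 or sd_y == 0.0:
        warnings.warn("zero variance in predictions or targets; r_test undefined", stacklevel=2)
        r = float("nan")
    else:
        r = cov / (sd_yhat * sd_y)
    return EvaluationResult(mse_test=mse, r_test=r, sd_yhat=sd_yhat, sd_y=sd_y, cov_yhat_y=cov)
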