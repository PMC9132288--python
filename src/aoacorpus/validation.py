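"""Validation battery: correlations, standardized regressions, VIF, repeated CV.

The analyses that evaluate the corpus AoA estimate against the other
measures: complete-case correlation matrices within each k-child word set;
standardized (z-scored) multiple regressions of an outcome (parent-report
AoA50, or adult lexical decision RT) on the AoA measures plus log-frequency,
with variance inflation factors as the multicollinearity diagnostic; and
repeated k-fold cross-validation reporting out-of-fold RMSE on the
standardized outcome scale (so a null model has RMSE 1 by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "CorrelationMatrix",
    "RegressionResult",
    "correlation_matrix",
    "standardized_regression",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    n: int
    method: str

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "r": self.r.round(6).values.tolist(),
            "n": self.n,
            "method": self.method,
        }


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    predictors: tuple[str, ...]
    beta_std: dict[str, float]
    p_value: dict[str, float]
    r2: float
    r2_adj: float
    vif: dict[str, float]
    n: int
    cv_rmse: float = float("nan")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["predictors"] = list(self.predictors)
        return d

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta_std": pd.Series(self.beta_std),
                "p_value": pd.Series(self.p_value),
                "vif": pd.Series(self.vif),
            }
        )


def correlation_matrix(
    table: pd.DataFrame,
    variables: list[str],
    method: str = "pearson",
) -> CorrelationMatrix:
    """Listwise complete-case correlations among the requested variables."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    data = table[variables].dropna()
    if len(data) < 3:
        raise ValueError("need >= 3 complete-case rows")
    constant = [v for v in variables if np.isclose(data[v].var(ddof=0), 0.0)]
    if constant:
        logger.warning("constant variables give undefined correlations: %s", constant)
    r = data.corr(method=method)
    return CorrelationMatrix(tuple(variables), r, len(data), method)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)


def standardized_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
) -> RegressionResult:
    """OLS on z-scored variables: standardized betas, p-values, R², VIF.

    All variables are standardized on the complete-case analysis rows, so the
    coefficients are comparable across predictors regardless of their native
    units.  VIF_j = 1/(1 - R²_j) from regressing predictor j on the others;
    an R²_j of 1 (perfect collinearity) is an error naming the predictor.
    """
    cols = [outcome] + list(predictors)
    data = table[cols].dropna()
    n = len(data)
    if n < len(predictors) + 3:
        raise ValueError(f"need >= {len(predictors) + 3} complete cases, got {n}")

    Z = pd.DataFrame(_zscore(data.to_numpy(dtype=float)), columns=cols)
    y = Z[outcome].to_numpy()
    X = sm.add_constant(Z[list(predictors)].to_numpy())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("perfect collinearity among predictors")
    fit = sm.OLS(y, X).fit()

    vif: dict[str, float] = {}
    for j, pred in enumerate(predictors):
        if len(predictors) == 1:
            vif[pred] = 1.0
            continue
        others = [p for p in predictors if p != pred]
        Xo = sm.add_constant(Z[others].to_numpy())
        r2_j = sm.OLS(Z[pred].to_numpy(), Xo).fit().rsquared
        if r2_j >= 1 - 1e-12:
            raise ValueError(f"predictor {pred!r} is perfectly collinear with the others")
        vif[pred] = 1.0 / (1.0 - r2_j)

    betas = dict(zip(predictors, (float(b) for b in fit.params[1:])))
    pvals = dict(zip(predictors, (float(p) for p in fit.pvalues[1:])))
    return RegressionResult(
        outcome=outcome,
        predictors=tuple(predictors),
        beta_std=betas,
        p_value=pvals,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        vif=vif,
        n=n,
    )


def cross_validate(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    folds: int = 5,
    repeats: int = 4,
    seed: int | None = None,
) -> float:
    """Mean out-of-fold RMSE of the linear model under repeated k-fold CV.

    Variables are z-scored with statistics computed *inside each training
    fold* (no leakage into the held-out fold), and the outcome is on the
    standardized scale, so an uninformative model scores RMSE ≈ 1.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible folds")
    cols = [outcome] + list(predictors)
    data = table[cols].dropna().to_numpy(dtype=float)
    n = len(data)
    if n < folds:
        raise ValueError(f"need >= {folds} complete cases, got {n}")

    splitter = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    rmses = []
    for train_idx, test_idx in splitter.split(data):
        if len(train_idx) < 2 or len(test_idx) < 1:
            raise ValueError("fold with fewer than 2 training rows")
        train, test = data[train_idx], data[test_idx]
        mu = train.mean(axis=0)
        sd = train.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column within a training fold")
        train_z = (train - mu) / sd
        test_z = (test - mu) / sd
        Xtr = sm.add_constant(train_z[:, 1:], has_constant="add")
        Xte = sm.add_constant(test_z[:, 1:], has_constant="add")
        beta = np.linalg.lstsq(Xtr, train_z[:, 0], rcond=None)[0]
        pred = Xte @ beta
        rmses.append(float(np.sqrt(np.mean((test_z[:, 0] - pred) ** 2))))
    return float(np.mean(rmses))
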