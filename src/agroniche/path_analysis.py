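"""Ridge-regression path analysis.

Decomposes each predictor trait's correlation with yield into a direct
effect (its standardized ridge coefficient) and indirect effects routed
through the other, correlated predictors (r_ij * beta_j).  At k = 0 with
full-rank predictors the direct plus indirect effects reproduce the simple
correlations r_iy exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PathResult", "ridge_path"]

DEFAULT_K_GRID = np.logspace(-4, 0, 25)


@dataclass
class PathResult:
    k: float
    direct: pd.Series             # standardized ridge coefficients
    indirect: pd.DataFrame        # [i, j] = r_ij * beta_j, diagonal 0
    total: pd.Series              # direct + sum of indirect
    r_with_y: pd.Series           # simple correlations with the response
    r_squared: float
    residual: float               # sqrt(1 - R^2)


def _standardize(A: np.ndarray) -> np.ndarray:
    # population (ddof=0) standardization
    return (A - A.mean(axis=0)) / A.std(axis=0)


def _loo_mse(Z: np.ndarray, y: np.ndarray, k: float) -> float:
    """Leave-one-out MSE of ridge on standardized data."""
    n = Z.shape[0]
    G = Z.T @ Z / n + k * np.eye(Z.shape[1])
    beta = np.linalg.solve(G, Z.T @ y / n)
    H = Z @ np.linalg.solve(G, Z.T) / n
    resid = y - Z @ beta
    h = np.clip(np.diag(H), None, 1 - 1e-10)
    return float(np.mean((resid / (1 - h)) ** 2))


def ridge_path(
    X: pd.DataFrame,
    y: pd.Series,
    k: float | str = "auto",
) -> PathResult:
    """Ridge path analysis of standardized predictors against yield.

    beta(k) = (X'X/n + kI)^{-1} X'y/n on internally standardized data.
    k="auto" picks the grid point in [1e-4, 1] minimizing leave-one-out
    cross-validated squared error.  Constant predictors are dropped with a
    warning.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 germplasms")
    if not X.index.equals(y.index):
        X = X.loc[y.index]
    sd = X.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"constant traits dropped from path analysis: {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant predictors remain")
    cols = list(X.columns)
    Z = _standardize(X.to_numpy(dtype=float))
    yv = y.to_numpy(dtype=float)
    if yv.std() == 0:
        raise ValueError("response is constant")
    yz = _standardize(yv.reshape(-1, 1)).ravel()
    n, m = Z.shape

    if k == "auto":
        scores = [_loo_mse(Z, yz, kk) for kk in DEFAULT_K_GRID]
        k_val = float(DEFAULT_K_GRID[int(np.argmin(scores))])
    else:
        k_val = float(k)
        if k_val < 0:
            raise ValueError("ridge parameter must be non-negative")

    R = Z.T @ Z / n                      # predictor correlation matrix
    r_xy = Z.T @ yz / n                  # correlations with the response
    beta = np.linalg.solve(R + k_val * np.eye(m), r_xy)

    indirect = R * beta[None, :]         # [i, j] = r_ij * beta_j
    np.fill_diagonal(indirect, 0.0)
    total = beta + indirect.sum(axis=1)

    resid = yz - Z @ beta
    r2 = float(1.0 - np.mean(resid**2))  # yz has unit population variance
    r2 = min(max(r2, 0.0), 1.0)

    idx = pd.Index(cols, name="trait")
    return PathResult(
        k=k_val,
        direct=pd.Series(beta, index=idx, name="direct"),
        indirect=pd.DataFrame(indirect, index=idx, columns=idx),
        total=pd.Series(total, index=idx, name="total"),
        r_with_y=pd.Series(r_xy, index=idx, name="r_with_y"),
        r_squared=r2,
        residual=float(np.sqrt(1.0 - r2)),
    )
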