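"""Regression models for DBH, stem volume and carbon stock from canopy
metrics: VIF-based multicollinearity pruning, bidirectional stepwise AIC
selection over ordinary least squares, and leave-one-out cross-validation.

The AIC used for selection is the Gaussian profile-likelihood form
``n·ln(RSS/n) + 2(p+1)`` with p the number of predictors (intercept always
included).  Stepwise search starts from the full post-VIF model and at each
step takes the single add-or-drop move that lowers AIC most, until no move
improves it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class ModelFit:
    """A selected OLS model with in-sample and cross-validated accuracy."""

    response: str
    selected_predictors: list[str]
    coefficients: pd.Series
    pvalues: pd.Series
    std_errors: pd.Series
    aic: float
    vif_table: pd.Series
    r_squared: float
    rmse: float
    loocv_rmse: float = math.nan
    loocv_r_squared: float = math.nan

    def report(self) -> dict:
        """Table-style report: coefficients at 5 dp, R²/RMSE at 2 dp."""

        def stars(p: float) -> str:
            return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

        return {
            "response": self.response,
            "selected_predictors": self.selected_predictors,
            "coefficients": {
                name: f"{coef:.5f} {stars(self.pvalues[name])}".strip()
                for name, coef in self.coefficients.items()
            },
            "r_squared": round(self.r_squared, 2),
            "rmse": round(self.rmse, 2),
            "loocv_rmse": round(self.loocv_rmse, 2),
            "loocv_r_squared": round(self.loocv_r_squared, 2),
            "aic": round(self.aic, 2),
            "vif": {k: round(float(v), 2) for k, v in self.vif_table.items()},
        }


def near_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distance for each tree: min over j≠i of d(i, j)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2:
        raise ValueError("near distance needs at least two trees")
    from scipy.spatial.distance import cdist

    pts = np.column_stack([x, y])
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _vif(x: pd.DataFrame) -> pd.Series:
    """VIF_k = 1/(1−R²_k) of predictor k regressed on the other predictors."""
    out = {}
    for k in x.columns:
        others = x.drop(columns=k)
        X = sm.add_constant(others, has_constant="add")
        r2 = sm.OLS(x[k], X).fit().rsquared
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(
    predictors: pd.DataFrame, threshold: float = 5.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Iteratively drop the predictor with the largest VIF until all ≤ threshold.

    Perfectly collinear (infinite-VIF) predictors are dropped first.  Returns
    the reduced table and the final VIF values of the retained predictors.
    """
    x = predictors.copy()
    while x.shape[1] >= 2:
        vifs = _vif(x)
        worst = vifs.idxmax()
        if vifs[worst] <= threshold:
            break
        x = x.drop(columns=worst)
    final = _vif(x) if x.shape[1] >= 2 else pd.Series(1.0, index=x.columns)
    return x, final


def aic_ols(y: np.ndarray, X: pd.DataFrame | None) -> float:
    """n·ln(RSS/n) + 2(p+1) for an OLS fit with intercept."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or X.shape[1] == 0:
        rss = float(np.sum((y - y.mean()) ** 2))
        p = 0
    else:
        Xc = sm.add_constant(X, has_constant="add")
        fit = sm.OLS(y, Xc).fit()
        rss = float(fit.ssr)
        p = X.shape[1]
    # floor RSS at the machine-noise scale of the response so numerically
    # exact fits compare by the penalty term alone
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    noise_floor = n * (1e-12 * (float(np.abs(y).mean()) + 1.0)) ** 2
    rss = max(rss, 1e-12 * ss_tot, noise_floor, 1e-300)
    return n * math.log(rss / n) + 2 * (p + 1)


def stepwise_aic(
    predictors: pd.DataFrame,
    response: pd.Series,
    response_name: str = "y",
    vif_threshold: float = 5.0,
    loocv: bool = True,
) -> ModelFit:
    """VIF-prune then bidirectional stepwise AIC selection; returns the OLS fit.

    Candidate models with n ≤ p+1 are skipped.  The empty (intercept-only)
    model is always a candidate, so the selected AIC never exceeds either the
    full or the empty model's.
    """
    y = response.to_numpy(dtype=float)
    n = len(y)
    if predictors.shape[0] != n:
        raise ValueError("predictor and response lengths differ")
    if predictors.isna().any().any() or response.isna().any():
        raise ValueError("missing values in the predictor table")

    if predictors.shape[1] >= 2:
        x, vifs = vif_filter(predictors, vif_threshold)
    else:
        x, vifs = predictors, pd.Series(1.0, index=predictors.columns)

    pool = list(x.columns)
    # start from the full post-VIF model; grow from empty if unidentifiable
    current = list(pool) if n > len(pool) + 1 else []
    best_aic = aic_ols(y, x[current] if current else None)

    improved = True
    while improved:
        improved = False
        moves: list[tuple[float, list[str]]] = []
        for c in pool:
            if c in current:
                cand = [p for p in current if p != c]
            else:
                cand = current + [c]
            if n <= len(cand) + 1:
                continue
            moves.append((aic_ols(y, x[cand] if cand else None), cand))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], len(t[1])))
        if moves[0][0] < best_aic - 1e-10:
            best_aic, current = moves[0][0], moves[0][1]
            improved = True

    current = sorted(current, key=list(x.columns).index)
    Xc = sm.add_constant(x[current], has_constant="add")
    fit = sm.OLS(y, Xc).fit()
    yhat = fit.fittedvalues
    r2, rmse = goodness_of_fit(y, np.asarray(yhat))

    result = ModelFit(
        response=response_name,
        selected_predictors=current,
        coefficients=fit.params,
        pvalues=fit.pvalues,
        std_errors=fit.bse,
        aic=best_aic,
        vif_table=vifs,
        r_squared=r2,
        rmse=rmse,
    )
    if loocv:
        result.loocv_rmse, result.loocv_r_squared = loocv_scores(x[current], y)
    return result


def goodness_of_fit(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """(R², RMSE): R² = 1 − SS_res/SS_tot, RMSE = sqrt(mean squared residual).

    R² is NaN when the response has zero variance.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = math.sqrt(ss_res / len(y))
    r2 = math.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return r2, rmse


def loocv_scores(X: pd.DataFrame, y: np.ndarray) -> tuple[float, float]:
    """Leave-one-out RMSE and R² for an OLS fit of y on X (with intercept).

    Each observation is predicted by the model fitted to the other n−1; the
    held-out predictions are scored with the same RMSE/R² formulas, R² against
    the full-sample response mean.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi = sm.add_constant(X.iloc[keep], has_constant="add")
        fit = sm.OLS(y[keep], Xi).fit()
        row = sm.add_constant(X, has_constant="add").iloc[[i]]
        preds[i] = float(fit.predict(row).iloc[0])
    r2, rmse = goodness_of_fit(y, preds)
    return rmse, r2


def fit_stand_models(
    table: pd.DataFrame,
    responses: list[str],
    predictor_cols: list[str],
    vif_threshold: float = 5.0,
) -> dict[str, ModelFit]:
    """Fit one stepwise model per response column over a shared predictor pool."""
    out = {}
    for resp in responses:
        if resp not in table.columns:
            raise ValueError(f"response column {resp!r} missing from table")
        out[resp] = stepwise_aic(
            table[predictor_cols], table[resp], response_name=resp,
            vif_threshold=vif_threshold,
        )
    return out
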