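"""Statistical modelling of strains and kinematics from clinical predictors.

The layer mirrors how the biomechanical outcomes are related to clinical
spine measures in practice:

* collinearity screen — predictors with a variance inflation factor
  VIF = 1/(1 − R²) of 10 or more are removed iteratively, worst first;
* backward elimination — ordinary least squares on all remaining
  predictors, repeatedly dropping the predictor with the largest partial
  p ≥ ``p_out`` (default 0.10) until all retained p are below it;
* diagnostics — residual normality (Shapiro–Wilk) and homoscedasticity
  (Breusch–Pagan) at α = 0.05; violating models are flagged "excluded";
* familywise correction — Hommel step-up adjustment over each per-level
  family of model p-values;
* reliability — inter-rater ICC(2,1): two-way random effects, absolute
  agreement, single measurement, with 95 % confidence interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import variance_inflation_factor
from scipy import stats as sps

__all__ = [
    "RegressionModel",
    "ICCResult",
    "vif_screen",
    "backward_fit",
    "model_diagnostics",
    "hommel_adjust",
    "icc_absolute",
]


# --------------------------------------------------------------------------
# collinearity
# --------------------------------------------------------------------------

def vif_screen(table: pd.DataFrame, predictors: list[str],
               threshold: float = 10.0) -> tuple[list[str], list[dict]]:
    """Iteratively drop the worst-VIF predictor while any VIF ≥ threshold.

    Returns the retained predictor list and a ledger of removals (predictor,
    VIF, reason).  Perfectly collinear predictors are removed with an
    "infinite VIF" entry.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors to screen")
    if len(table) <= len(predictors):
        raise ValueError("need more rows than predictors")
    retained = list(predictors)
    ledger: list[dict] = []
    while len(retained) >= 2:
        X = sm.add_constant(table[retained].to_numpy(float), has_constant="add")
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(X, j + 1)
                             for j in range(len(retained))])
        vifs = np.where(np.isfinite(vifs), vifs, np.inf)
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        name = retained.pop(worst)
        ledger.append({
            "predictor": name,
            "vif": float(vifs[worst]) if np.isfinite(vifs[worst]) else None,
            "reason": "infinite VIF (perfect collinearity)"
            if not np.isfinite(vifs[worst]) else f"VIF {vifs[worst]:.2f} >= {threshold}",
        })
    return retained, ledger


# --------------------------------------------------------------------------
# backward elimination
# --------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """Backward-eliminated OLS model report."""

    outcome: str
    retained: list[str]
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    f_value: float
    adj_r2: float
    model_p: float
    model_p_corrected: float | None = None
    vif_ledger: list[dict] = field(default_factory=list)
    elimination_ledger: list[dict] = field(default_factory=list)
    diagnostics: dict[str, object] = field(default_factory=dict)
    intercept_only: bool = False
    residuals: np.ndarray | None = None
    fitted: np.ndarray | None = None

    @property
    def excluded(self) -> bool:
        d = self.diagnostics
        return bool(d) and not (d.get("normality_ok", True)
                                and d.get("homoscedasticity_ok", True))


def backward_fit(table: pd.DataFrame, outcome: str, predictors: list[str],
                 p_out: float = 0.10) -> RegressionModel:
    """OLS with backward elimination on partial p-values.

    Fits all predictors (plus intercept), repeatedly removes the predictor
    with the largest p ≥ ``p_out`` and refits, stopping when every retained
    predictor has p < ``p_out``.  If nothing survives, an intercept-only
    model is reported and flagged.
    """
    if len(table) <= len(predictors) + 1:
        raise ValueError("need more rows than predictors + 1")
    if not 0 < p_out <= 1:
        raise ValueError("p_out must be in (0, 1]")
    y = table[outcome].to_numpy(float)
    retained = list(predictors)
    elim: list[dict] = []
    while True:
        X = sm.add_constant(table[retained].to_numpy(float), has_constant="add") \
            if retained else np.ones((len(y), 1))
        res = sm.OLS(y, X).fit()
        if not retained:
            break
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] < p_out:
            break
        elim.append({"predictor": retained[worst], "p": float(pvals[worst])})
        retained.pop(worst)
    coef = {"intercept": float(res.params[0])}
    se = {"intercept": float(res.bse[0])}
    p = {"intercept": float(res.pvalues[0])}
    for i, name in enumerate(retained):
        coef[name] = float(res.params[i + 1])
        se[name] = float(res.bse[i + 1])
        p[name] = float(res.pvalues[i + 1])
    return RegressionModel(
        outcome=outcome,
        retained=retained,
        coef=coef, se=se, p=p,
        f_value=float(res.fvalue) if retained else float("nan"),
        adj_r2=float(res.rsquared_adj) if retained else 0.0,
        model_p=float(res.f_pvalue) if retained else 1.0,
        elimination_ledger=elim,
        intercept_only=not retained,
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
    )


def model_diagnostics(model: RegressionModel, alpha: float = 0.05,
                      table: pd.DataFrame | None = None) -> dict[str, object]:
    """Residual-normality and homoscedasticity flags at the given α.

    Shapiro–Wilk on the residuals and Breusch–Pagan of squared residuals on
    the fitted values; the flags are stored on the model and a violating
    model is marked "excluded".  Degenerate (constant) residuals pass both.
    """
    resid = model.residuals
    fitted = model.fitted
    if resid is None or fitted is None:
        raise ValueError("model carries no residuals")
    resid = np.asarray(resid, float)
    if np.allclose(resid, resid[0]):
        diags = {"normality_ok": True, "homoscedasticity_ok": True,
                 "normality_p": 1.0, "homoscedasticity_p": 1.0}
    else:
        _, p_norm = sps.shapiro(resid)
        exog = sm.add_constant(np.asarray(fitted, float))
        _, p_het, _, _ = het_breuschpagan(resid, exog)
        diags = {
            "normality_ok": bool(p_norm >= alpha),
            "homoscedasticity_ok": bool(p_het >= alpha),
            "normality_p": float(p_norm),
            "homoscedasticity_p": float(p_het),
        }
    diags["excluded"] = not (diags["normality_ok"] and diags["homoscedasticity_ok"])
    model.diagnostics = diags
    return diags


# --------------------------------------------------------------------------
# familywise correction
# --------------------------------------------------------------------------

def hommel_adjust(p_values) -> np.ndarray:
    """Hommel step-up adjusted p-values (closed-testing based).

    Adjusted values are never below the raw ones and preserve the raw
    ordering; the family is typically the set of model p-values at one
    vertebral level.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    _, adj, _, _ = multipletests(p, method="hommel")
    return np.maximum(adj, p)


# --------------------------------------------------------------------------
# reliability
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    model: str = "two-way random, absolute agreement, single measurement"
    degenerate: bool = False


def icc_absolute(ratings: np.ndarray) -> ICCResult:
    """ICC(2,1) of a rater × subject matrix with a 95 % confidence interval.

    Requires at least two raters and three subjects with no missing cells.
    A matrix with zero between-subject variance is flagged degenerate (the
    coefficient is undefined when subjects do not differ).
    """
    import pingouin as pg

    mat = np.asarray(ratings, float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 3:
        raise ValueError("need a complete rater x subject matrix, >=2 raters, >=3 subjects")
    if np.any(~np.isfinite(mat)):
        raise ValueError("ratings matrix must be complete")
    k, n = mat.shape
    between_var = mat.mean(axis=0).var()
    if between_var == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    if np.allclose(mat, mat[0]):       # identical raters: perfect agreement
        return ICCResult(1.0, 1.0, 1.0)
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), k),
        "rater": np.repeat(np.arange(k), n),
        "score": mat.reshape(-1),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
    # the absolute-agreement single-measurement row is labelled ICC2 or
    # ICC(A,1) depending on the pingouin release
    sel = icc["Type"].isin(["ICC2", "ICC(A,1)"])
    row = icc[sel].iloc[0]
    ci_col = "CI95%" if "CI95%" in icc.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(float(row["ICC"]), float(lo), float(hi))
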