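"""Multivariate quadratic fatigue models.

Overall fatigue Y is regressed on a condition-level iEMG summary (X1) and
baseline-relative change rates of the saccade metrics, in percent
(X2: saccade count ST, X3: saccade speed SS, X4: saccade amplitude SA).
The candidate pool is the full quadratic surface in X1..X4 — intercept,
4 linear terms, 4 squares, 6 pairwise interactions (15 terms) — pruned by
backward elimination until every retained predictor has p < alpha
(intercept always kept).  Generalisability is assessed with leave-one-out
cross-validation, re-running the selection inside each fold.

The seven published per-condition equations (loading types A-D and the
three road slopes) are available verbatim through
:func:`evaluate_fixed` / :data:`FIXED_EQUATIONS`.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

FEATURE_NAMES = ("X1", "X2", "X3", "X4")

#: Candidate term names in fixed design-matrix order (intercept first).
TERM_POOL = (
    ("const",)
    + FEATURE_NAMES
    + tuple(f"{n}^2" for n in FEATURE_NAMES)
    + tuple(f"{a}{b}" for a, b in combinations(FEATURE_NAMES, 2))
)

#: Published per-condition quadratic equations (term -> coefficient).
FIXED_EQUATIONS: dict[str, dict[str, float]] = {
    "A": {"X1": 7.27, "X2": 0.34, "X3": -0.94, "X4": -0.91,
          "X3^2": -0.04, "X4^2": -0.03, "const": 9.47},
    "B": {"X1": 11.03, "X2": -0.35, "X3": -1.15, "X4": 2.21,
          "X3^2": -0.18, "X3X4": 0.26, "const": 4.42},
    "C": {"X1": 27.56, "X2": -0.87, "X4": 1.28, "X4^2": -0.17,
          "X2X4": -0.04, "X3X4": 0.09, "const": -13.42},
    "D": {"X1": 30.51, "X3": -0.34, "X4": 0.38, "X3^2": -0.10,
          "X3X4": 0.13, "const": -21.66},
    "Flat": {"X1": 0.02, "X3": -0.08, "X4": -1.44, "X3^2": -0.64,
             "X4^2": -0.70, "X3X4": 1.29, "const": 18.01},
    "Down": {"X1": 4.30, "X2": 0.41, "X3": -0.70, "X4": -0.57,
             "X2X4": 0.02, "X3X4": -0.04, "const": 10.77},
    "Up": {"X1": 7.20, "X2": 0.33, "X3": -0.76, "X4": -1.01,
           "X3^2": 0.11, "X4^2": 0.13, "X3X4": -0.30, "const": 9.09},
}

#: Published goodness-of-fit per condition: (R2, LOOCV RMSE).
FIXED_EQUATION_FIT: dict[str, tuple[float, float]] = {
    "A": (0.90, 0.54), "B": (0.91, 0.94), "C": (0.96, 0.94),
    "D": (0.96, 0.30), "Flat": (0.91, 0.57), "Down": (0.92, 0.78),
    "Up": (0.91, 0.19),
}

# residual variance below this (relative to var(Y)) is treated as a perfect
# fit, where t-based p-values are numerically meaningless
_PERFECT_FIT_TOL = 1e-12


def build_design(X: np.ndarray) -> pd.DataFrame:
    """Quadratic design matrix over the 15-term pool, raw (uncentered) terms."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("X must be (n_samples, 4): X1..X4")
    cols: dict[str, np.ndarray] = {"const": np.ones(X.shape[0])}
    for i, name in enumerate(FEATURE_NAMES):
        cols[name] = X[:, i]
    for i, name in enumerate(FEATURE_NAMES):
        cols[f"{name}^2"] = X[:, i] ** 2
    for (i, a), (j, b) in combinations(enumerate(FEATURE_NAMES), 2):
        cols[f"{a}{b}"] = X[:, i] * X[:, j]
    return pd.DataFrame(cols, columns=list(TERM_POOL))


class QuadraticFatigueModel(BaseEstimator, RegressorMixin):
    """Quadratic fatigue regression with significance-based term selection.

    Parameters
    ----------
    alpha : float, default 0.05
        Retention threshold: backward elimination drops the least-significant
        term until all retained predictors have p < alpha.
    scope : str or None
        Optional label for the condition the model covers (a loading type or
        a road slope); purely descriptive.

    Attributes
    ----------
    terms_ : list of str
        Retained term names (always includes "const").
    coef_ : dict
        Coefficient per retained term.
    pvalues_ : dict
        Final-fit p-value per retained term.
    r2_ : float
        Coefficient of determination on the fitting data.
    loocv_rmse_ : float or None
        Filled by :meth:`score_loocv` (not during ``fit``).
    """

    def __init__(self, alpha: float = 0.05, scope: str | None = None):
        self.alpha = alpha
        self.scope = scope

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        design = build_design(X)
        terms = self._eliminate(design, y)
        res = sm.OLS(y, design[terms]).fit()
        self.terms_ = list(terms)
        self.coef_ = dict(zip(terms, map(float, res.params)))
        self.pvalues_ = dict(zip(terms, map(float, res.pvalues)))
        self.r2_ = self._r2(y, res.fittedvalues)
        self.n_features_in_ = 4
        self.loocv_rmse_ = None
        self._result = res
        return self

    def _eliminate(self, design: pd.DataFrame, y: np.ndarray) -> list[str]:
        n = len(design)
        terms = list(TERM_POOL)
        # restrict the pool when a full fit would be rank-deficient
        if n <= len(terms):
            warnings.warn("insufficient observations for the full quadratic "
                          "pool; starting from linear terms", stacklevel=2)
            terms = ["const", *FEATURE_NAMES]
        var_y = float(np.var(y)) or 1.0
        # omnibus gate: without a significant overall regression the
        # term-wise retention criterion has nothing to interpret, and pure
        # noise would otherwise keep chance survivors
        full = sm.OLS(y, design[terms]).fit()
        if full.mse_resid / var_y >= _PERFECT_FIT_TOL and not (
            np.isfinite(full.f_pvalue) and full.f_pvalue < self.alpha
        ):
            warnings.warn("overall regression not significant; returning an "
                          "intercept-only model", stacklevel=3)
            return ["const"]
        while len(terms) > 1:
            res = sm.OLS(y, design[terms]).fit()
            if res.mse_resid / var_y < _PERFECT_FIT_TOL:
                # numerically perfect fit: prune exact-zero terms instead of
                # relying on 0/0 t statistics
                scale = np.abs(design[terms]).mean().replace(0, 1.0)
                contrib = np.abs(res.params) * scale.to_numpy()
                droppable = [
                    t for t, c in zip(terms, contrib)
                    if t != "const" and c < 1e-7 * max(contrib.max(), 1.0)
                ]
                if not droppable:
                    return terms
                terms = [t for t in terms if t not in droppable]
                continue
            pvals = pd.Series(res.pvalues, index=terms).drop("const")
            pvals = pvals.fillna(1.0)
            worst = pvals.idxmax()
            if pvals[worst] < self.alpha:
                return terms
            terms.remove(worst)
        return terms

    @staticmethod
    def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        if ss_tot == 0:
            return 1.0 if ss_res == 0 else 0.0
        return max(0.0, 1.0 - ss_res / ss_tot)

    # -- prediction ------------------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "terms_")
        X = check_array(X)
        design = build_design(X)
        return design[self.terms_].to_numpy() @ np.array(
            [self.coef_[t] for t in self.terms_]
        )

    # -- cross-validation ------------------------------------------------
    def score_loocv(self, X, y) -> float:
        """Leave-one-out RMSE, re-running term selection within each fold."""
        rmse = loocv_rmse(X, y, alpha=self.alpha)
        self.loocv_rmse_ = rmse
        return rmse


def fit_with_selection(
    X, y, alpha: float = 0.05, scope: str | None = None
) -> QuadraticFatigueModel:
    """Convenience wrapper: fit a :class:`QuadraticFatigueModel`."""
    return QuadraticFatigueModel(alpha=alpha, scope=scope).fit(X, y)


def loocv_rmse(X, y, alpha: float = 0.05) -> float:
    """Leave-one-out RMSE of the selection-plus-fit procedure.

    Each observation is predicted from a model fitted (selection included)
    on the remaining n-1; failed folds are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    residuals = []
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = QuadraticFatigueModel(alpha=alpha).fit(X[mask], y[mask])
            residuals.append(y[i] - m.predict(X[i : i + 1])[0])
        except Exception:  # noqa: BLE001 - fold failure is reported, not fatal
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} LOOCV fold(s) failed and were skipped",
                      stacklevel=2)
    if not residuals:
        raise ValueError("all LOOCV folds failed")
    return float(np.sqrt(np.mean(np.square(residuals))))


def evaluate_fixed(scope: str, features) -> float:
    """Evaluate one of the published per-condition equations verbatim.

    ``features`` is (X1, X2, X3, X4) with change rates in percent.
    """
    if scope not in FIXED_EQUATIONS:
        raise KeyError(f"no such equation: {scope!r}")
    x = np.asarray(features, dtype=float)
    if x.shape != (4,):
        raise ValueError("features must be (X1, X2, X3, X4)")
    design = build_design(x[None, :]).iloc[0]
    eq = FIXED_EQUATIONS[scope]
    return float(sum(coef * design[term] for term, coef in eq.items()))
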