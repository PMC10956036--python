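"""Standardized regression families, correlations, t-tests and collinearity.

Three model families link individual differences to task measures, always
controlling for age and gender, with every variable z-scored so coefficients
are in standard-deviation units:

* ``measure ~ log(questionnaire total) + age + gender`` (one model per
  instrument);
* ``measure ~ AD + CIT + SW + age + gender`` (the three symptom dimensions
  jointly);
* ``measure ~ big5 + AD + CIT + SW + age + gender`` (personality controlling
  for symptoms).

Bonferroni correction is applied over the number of dependent variables in
each family.  Variance inflation factors flag collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "standardized_ols",
    "bonferroni_alpha",
    "vif",
    "compare_measures",
]


@dataclass
class RegressionResult:
    model_id: str
    outcome: str
    terms: pd.DataFrame  # term, beta, ci_low, ci_high, p, vif
    n: int
    alpha_corrected: float

    def significant(self, term: str) -> bool:
        p = float(self.terms.set_index("term").loc[term, "p"])
        return p < self.alpha_corrected

    def to_tidy(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "outcome", self.outcome)
        out.insert(0, "model_id", self.model_id)
        out["alpha_corrected"] = self.alpha_corrected
        out["significant"] = out["p"] < self.alpha_corrected
        return out


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError(f"zero-variance variable: {name}")
    return (x - x.mean()) / sd


def standardized_ols(outcome: pd.Series | np.ndarray, predictors: pd.DataFrame,
                     model_id: str = "model", outcome_name: str | None = None,
                     n_dependent_tests: int = 1, alpha: float = 0.05) -> RegressionResult:
    """Ordinary least squares on z-scored variables.

    Gender (or any two-level categorical column) is first encoded as a 0/1
    contrast, then z-scored like every other predictor so coefficients stay
    comparable.  p-values are two-sided from the t distribution with
    n − p − 1 degrees of freedom; 95% CIs likewise.
    """
    y = np.asarray(outcome, dtype=float) if not isinstance(outcome, pd.Series) \
        else outcome.to_numpy(dtype=float)
    if outcome_name is None:
        outcome_name = getattr(outcome, "name", None) or "outcome"
    X = pd.DataFrame(index=predictors.index if isinstance(predictors, pd.DataFrame)
                     else None)
    for colname in predictors.columns:
        col = predictors[colname]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            if len(levels) != 2:
                raise ValueError(f"categorical predictor {colname!r} must have "
                                 f"exactly 2 levels, got {levels}")
            X[colname] = (col == levels[1]).astype(float)
        else:
            X[colname] = col.to_numpy(dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in regression variables")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    yz = _zscore(y, outcome_name)
    Xz = np.column_stack([_zscore(X[c].to_numpy(), c) for c in X.columns])
    design = sm.add_constant(Xz)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix")
    res = sm.OLS(yz, design).fit()
    ci = res.conf_int(alpha=0.05)
    vifs = vif(Xz) if p >= 2 else np.array([1.0])
    terms = pd.DataFrame({
        "term": list(X.columns),
        "beta": res.params[1:],
        "ci_low": ci[1:, 0],
        "ci_high": ci[1:, 1],
        "p": res.pvalues[1:],
        "vif": vifs,
    })
    return RegressionResult(model_id=model_id, outcome=outcome_name, terms=terms,
                            n=n, alpha_corrected=bonferroni_alpha(alpha, n_dependent_tests))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Corrected alpha over ``m`` dependent-variable tests (exact; display at 4 dp)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def vif(predictors: np.ndarray) -> np.ndarray:
    """Variance inflation factor 1/(1−R²_k) for each predictor column."""
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 predictor columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient predictor matrix")
    out = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        others = sm.add_constant(np.delete(X, k, axis=1))
        r2 = sm.OLS(X[:, k], others).fit().rsquared
        out[k] = 1.0 / max(1.0 - r2, 1e-12)
    return out


def compare_measures(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired comparison of one measure across two tasks.

    Returns the paired t-test (df = n − 1) and the Pearson correlation
    (p-value on df = n − 2), aligned by participant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired measures must align by participant")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        t_stat, t_p, t_defined = float("nan"), float("nan"), False
    else:
        t_stat = diff.mean() / (sd / np.sqrt(n))
        t_p = 2 * stats.t.sf(abs(t_stat), n - 1)
        t_defined = True
    r, r_p = stats.pearsonr(a, b)
    return {"t": t_stat, "t_p": t_p, "t_df": n - 1, "t_defined": t_defined,
            "r": float(r), "r_p": float(r_p), "r_df": n - 2, "n": n}
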