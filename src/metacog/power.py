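"""Noncentral-F power analysis for a tested coefficient in multiple regression.

For Cohen's effect size f² = R²_change / (1 − R²_full), the F test of
``p_tested`` coefficients among ``p_total`` predictors at sample size n has
power

    P( F'(df1, df2, λ) > F_crit(alpha, df1, df2) ),
    df1 = p_tested,  df2 = n − p_total − 1,  λ = f² · n,

the convention used by the G*Power "linear multiple regression, R² increase"
module.  Defaults (five predictors, one tested) correspond to testing a
single symptom-dimension coefficient while controlling for the other two
dimensions, age and gender.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "power_for_n", "required_n"]


@dataclass
class PowerSpec:
    f2: float
    n: int
    alpha: float = 0.05
    p_total: int = 5
    p_tested: int = 1

    def __post_init__(self) -> None:
        if self.f2 < 0:
            raise ValueError("f2 must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def power_for_n(spec: PowerSpec) -> float:
    """Achieved power of the noncentral-F test at the spec's sample size."""
    df1 = spec.p_tested
    df2 = spec.n - spec.p_total - 1
    if df2 <= 0:
        raise ValueError(f"n = {spec.n} leaves no residual degrees of freedom")
    lam = spec.f2 * spec.n
    fcrit = stats.f.ppf(1 - spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_n(f2: float, target_power: float, alpha: float = 0.05,
               p_total: int = 5, p_tested: int = 1, n_max: int = 10 ** 6) -> int:
    """Smallest n whose power reaches ``target_power`` (monotone bisection)."""
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")

    def power(n: int) -> float:
        return power_for_n(PowerSpec(f2, n, alpha, p_total, p_tested))

    lo = p_total + 2
    hi = lo
    while power(hi) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power unreachable below n = {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
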