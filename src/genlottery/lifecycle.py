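"""Age-specific returns profiles, lifetime returns and the internal rate of
return (IRR).

For each age the chosen estimator (OLS, family FE or MR) is re-run with the
absolute earnings observed at that age as the outcome — individuals with
zero earnings (still in school) are retained, which is what produces the
negative early-career returns: an extra year of schooling delays entry and
forgoes earnings. The IRR is the discount rate r at which the discounted sum
of age-specific returns is zero; schooling "pays off" if the IRR exceeds the
market interest rate (2.3% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import AnalysisSample
from .estimators import EstimateResult, ModelSpec, fit_family_fe, fit_ols, fit_tsls
from .regress import EstimationError

COMPARISON_RATE = 0.023  # real market interest rate

_ESTIMATORS = {"ols": fit_ols, "fe": fit_family_fe, "mr": fit_tsls}


@dataclass
class IRRResult:
    irr: float
    bracket: tuple
    comparison_rate: float = COMPARISON_RATE
    profitable: bool = False
    multiple_roots: bool = False


def age_specific_returns(sample: AnalysisSample, estimator: str = "ols",
                         spec: ModelSpec | None = None, ages=None) -> pd.DataFrame:
    """Profile of absolute-scale returns per year of schooling by age.

    Returns a frame with columns age, estimator, beta, se, ci_low, ci_high, n.
    """
    if sample.earnings is None:
        raise EstimationError("sample carries no earnings panel")
    if estimator not in _ESTIMATORS:
        raise EstimationError(f"estimator must be one of {sorted(_ESTIMATORS)}")
    spec = spec or ModelSpec(outcome="abs")
    fit = _ESTIMATORS[estimator]
    panel_ages = list(sample.ages)
    ages = panel_ages if ages is None else list(ages)
    rows = []
    base_df = sample.df
    for a in ages:
        if a not in panel_ages:
            warnings.warn(f"age {a} outside the earnings panel; skipped")
            continue
        col = panel_ages.index(a)
        df = base_df.copy()
        df["earnings_prime"] = sample.earnings[:, col]
        sub = AnalysisSample(label=f"{sample.label}@age{a}", df=df,
                             covariate_names=list(sample.covariate_names))
        res: EstimateResult = fit(sub, spec)
        rows.append({"age": a, "estimator": estimator, "beta": res.beta,
                     "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "n": res.n})
    return pd.DataFrame(rows)


def lifetime_return(profile: pd.DataFrame) -> float:
    """Undiscounted average of the age-specific returns."""
    if len(profile) == 0:
        raise EstimationError("empty life-cycle profile")
    return float(profile["beta"].mean())


def internal_rate_of_return(profile: pd.DataFrame,
                            comparison_rate: float = COMPARISON_RATE,
                            tol: float = 1e-6) -> IRRResult:
    """Discount rate equating life-cycle costs and benefits.

    Solves ``sum_a beta_a (1+r)^-(a - a_min) = 0`` by bracketed root-finding.
    Requires at least one sign change in the profile (negative early returns,
    positive later); with several roots the one nearest zero is returned with
    a multiplicity warning.
    """
    beta = profile.sort_values("age")["beta"].to_numpy(dtype=float)
    ages = profile.sort_values("age")["age"].to_numpy(dtype=float)
    if (beta >= 0).all() or (beta <= 0).all():
        raise EstimationError("no sign change in returns profile; IRR undefined")
    t = ages - ages.min()

    def npv(r):
        return float(np.sum(beta * (1.0 + r) ** (-t)))

    grid = np.linspace(-0.75, 1.5, 451)
    vals = np.array([npv(r) for r in grid])
    roots, brackets = [], []
    for i in np.flatnonzero(vals == 0.0):
        roots.append(float(grid[i]))
        brackets.append((float(grid[max(i - 1, 0)]), float(grid[min(i + 1, len(grid) - 1)])))
    for i in np.flatnonzero(vals[:-1] * vals[1:] < 0):
        roots.append(float(brentq(npv, grid[i], grid[i + 1], xtol=tol)))
        brackets.append((float(grid[i]), float(grid[i + 1])))
    if not roots:
        raise EstimationError("no IRR found in bracket (-0.75, 1.5)")
    multiple = len(roots) > 1
    if multiple:
        warnings.warn(f"multiple IRR roots found ({len(roots)}); reporting nearest zero")
    j = int(np.argmin(np.abs(roots)))
    return IRRResult(
        irr=roots[j], bracket=brackets[j],
        comparison_rate=comparison_rate,
        profitable=bool(roots[j] > comparison_rate), multiple_roots=multiple,
    )
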