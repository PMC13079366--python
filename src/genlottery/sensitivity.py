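"""Union-of-confidence-intervals (UCI) sensitivity analysis for exclusion
violations.

For a grid of hypothesized direct (pleiotropic) effects ``delta`` of the
standardized polygenic instrument on the outcome, the IV model is re-run on
the adjusted outcome ``Y - delta * Z``; the union interval collects every
per-delta CI. With a single instrument the adjusted point estimate obeys the
identity ``beta(delta) = beta_hat - delta / first_stage_beta``. The
"breakdown" direct effect is the smallest delta >= 0 at which the union CI
reaches zero — how big an exclusion violation would have to be to wipe out
statistical significance.

``delta`` is denominated in outcome units per 1 SD of the instrument, so
dividing the breakdown delta by the reduced-form association gives a
dimensionless share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cohort import AnalysisSample
from .estimators import ModelSpec, fit_tsls
from .regress import EstimationError


@dataclass
class SensitivityCurve:
    deltas: np.ndarray
    estimates: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    union: tuple
    breakdown_delta: float | None
    breakdown_reached: bool
    reduced_form_beta: float
    first_stage_beta: float
    flags: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "delta": self.deltas, "estimate": self.estimates,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def _fit_adjusted(sample: AnalysisSample, spec: ModelSpec, delta: float):
    inst = spec.instrument or "piv_std"
    z = sample.df[inst].to_numpy(dtype=float)
    col = "log_earnings" if spec.outcome == "log" else "earnings_prime"
    df = sample.df.copy()
    df[col] = df[col].to_numpy(dtype=float) - delta * z
    adj = AnalysisSample(label=sample.label, df=df,
                         covariate_names=list(sample.covariate_names))
    return fit_tsls(adj, spec)


def uci_sensitivity(sample: AnalysisSample, spec: ModelSpec | None = None,
                    delta_grid=None, n_grid: int = 201,
                    breakdown_tol: float = 1e-4) -> SensitivityCurve:
    """UCI curve over hypothesized direct effects of the instrument.

    Default grid: ``n_grid`` points from 0 to 1.5 x |reduced-form beta|. The
    breakdown delta solves ``ci_low(delta) = 0`` by bisection (the per-delta
    lower bound is monotone in delta when the first stage is positive); on a
    non-monotone grid the code falls back to a grid scan and flags it.
    """
    spec = spec or ModelSpec(instrument="piv_std", outcome="abs")
    base = fit_tsls(sample, spec)
    rf = base.reduced_form_beta
    fs = base.first_stage_beta
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 1.5 * abs(rf), n_grid)
    delta_grid = np.asarray(delta_grid, dtype=float)

    est = np.empty_like(delta_grid)
    lo = np.empty_like(delta_grid)
    hi = np.empty_like(delta_grid)
    for i, d in enumerate(delta_grid):
        r = _fit_adjusted(sample, spec, d) if d != 0 else base
        est[i], lo[i], hi[i] = r.beta, r.ci_low, r.ci_high
    union = (float(lo.min()), float(hi.max()))

    flags = {}
    monotone = fs > 0 and np.all(np.diff(lo) <= 1e-9 * max(1.0, abs(lo[0])))
    breakdown = None
    reached = False
    if lo[0] <= 0:
        breakdown, reached = 0.0, True
    elif monotone or len(delta_grid) < 3:
        if lo[-1] > 0:
            breakdown, reached = None, False
        else:
            a, b = 0.0, float(delta_grid[-1])
            f_lo = lambda d: _fit_adjusted(sample, spec, d).ci_low
            tol = breakdown_tol * max(abs(rf), 1.0)
            while b - a > tol:
                m = 0.5 * (a + b)
                if f_lo(m) > 0:
                    a = m
                else:
                    b = m
            breakdown, reached = 0.5 * (a + b), True
    else:
        warnings.warn("non-monotone lower bound on grid; using grid scan for breakdown")
        flags["grid_scan_fallback"] = True
        below = np.flatnonzero(lo <= 0)
        if len(below):
            breakdown, reached = float(delta_grid[below[0]]), True
    return SensitivityCurve(
        deltas=delta_grid, estimates=est, ci_low=lo, ci_high=hi,
        union=union, breakdown_delta=breakdown, breakdown_reached=reached,
        reduced_form_beta=rf, first_stage_beta=fs, flags=flags,
    )


def breakdown_share(breakdown_delta: float, reduced_form_beta: float) -> float:
    """Breakdown direct effect as a percent of the reduced-form association,
    rounded half-up to one decimal (e.g. 12650/14133 -> 89.5)."""
    if reduced_form_beta == 0:
        raise EstimationError("reduced-form association is zero; share undefined")
    share = 100.0 * breakdown_delta / reduced_form_beta
    return float(Decimal(repr(float(share))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
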