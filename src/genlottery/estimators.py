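"""Individual-level estimators of the return to a year of schooling.

OLS, family (sibling/twin) fixed effects, just-identified two-stage least
squares with a polygenic instrument, and sibling-MR (fixed-effects IV), all
with cluster-robust sandwich inference, Anderson-Rubin test inversion for
weak-instrument-robust confidence intervals, instrument-covariate balance
diagnostics, and subgroup stratification.

All IV fits use Frisch-Waugh-Lovell partialling: covariates are residualized
out of outcome, exposure and instrument, after which the coefficient is the
ratio of cross-moments; the first-stage partial F is the squared
cluster-robust t-statistic of the instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import AnalysisSample
from .regress import (
    EstimationError,
    check_rank,
    cluster_ols,
    demean_within,
    factorize_clusters,
    partial_out,
)


class DegenerateVariationError(EstimationError):
    pass


class WeakInstrumentError(EstimationError):
    pass


@dataclass
class ModelSpec:
    """What to estimate and how to do inference.

    ``cluster`` may be a column name, a tuple of column names (intersection
    clusters), or "auto": birth year for pooled models, family x birth year
    for fixed-effects models, following the convention of clustering at the
    level of the fixed effect interacted with cohort.
    """

    outcome: str = "log"  # "log" or "abs"
    covariates: list | None = None
    fixed_effects: str | None = None  # None or "family"
    instrument: str | None = None  # None or a column, e.g. "piv_std"
    cluster: object = "auto"
    ci_level: float = 0.95
    ci_method: str = "wald"  # "wald" or "anderson_rubin"
    #: adjust for the subpopulation label (genetic-PC analog), default off
    include_subpop: bool = False


@dataclass
class EstimateResult:
    model: str
    outcome_scale: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    ci_method: str
    n: int
    n_clusters: int
    F_first_stage: float | None = None
    first_stage_beta: float | None = None
    first_stage_se: float | None = None
    reduced_form_beta: float | None = None
    reduced_form_se: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "model": self.model, "outcome_scale": self.outcome_scale,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "ci_method": self.ci_method, "n": self.n, "n_clusters": self.n_clusters,
        }
        for k in ("F_first_stage", "first_stage_beta", "reduced_form_beta", "reduced_form_se"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


# ------------------------------------------------------------------ helpers

def _outcome(sample: AnalysisSample, spec: ModelSpec) -> np.ndarray:
    col = "log_earnings" if spec.outcome == "log" else "earnings_prime"
    return sample.df[col].to_numpy(dtype=float)


def _covariates(sample: AnalysisSample, spec: ModelSpec):
    names = list(spec.covariates) if spec.covariates is not None else list(sample.covariate_names)
    if spec.include_subpop and "subpop" not in names:
        names = names + ["subpop"]
    C = sample.df[names].to_numpy(dtype=float)
    keep = [j for j in range(C.shape[1]) if C[:, j].std() > 1e-12]
    if len(keep) < len(names):
        dropped = [names[j] for j in range(len(names)) if j not in keep]
        warnings.warn(f"dropping constant covariates: {dropped}")
        C, names = C[:, keep], [names[j] for j in keep]
    return C, names


def _clusters(sample: AnalysisSample, spec: ModelSpec) -> np.ndarray:
    cl = spec.cluster
    if cl == "auto":
        cl = ("family_id", "birth_year") if spec.fixed_effects else "birth_year"
    if cl is None:
        return np.arange(sample.n)
    if isinstance(cl, str):
        cl = (cl,)
    return factorize_clusters(*(sample.df[c].to_numpy() for c in cl))


def _drop_within_constant(C: np.ndarray, names: list, groups: np.ndarray):
    """Remove covariates with (numerically) no within-family variation."""
    W = demean_within(C, groups)
    keep = [j for j in range(C.shape[1]) if np.var(W[:, j]) > 1e-10 * max(np.var(C[:, j]), 1e-12)]
    dropped = [names[j] for j in range(C.shape[1]) if j not in keep]
    return W[:, keep], [names[j] for j in keep], dropped


def _wald_ci(beta, se, level):
    zc = stats.norm.ppf(0.5 + level / 2.0)
    return beta - zc * se, beta + zc * se


# ------------------------------------------------------------------ OLS / FE

def fit_ols(sample: AnalysisSample, spec: ModelSpec | None = None) -> EstimateResult:
    """Pooled OLS of the outcome on schooling plus covariates."""
    spec = spec or ModelSpec()
    y = _outcome(sample, spec)
    s = sample.df["schooling_years"].to_numpy(dtype=float)
    C, names = _covariates(sample, spec)
    X = np.column_stack([np.ones(sample.n), s, C])
    check_rank(X, ["const", "schooling_years"] + names)
    cl = _clusters(sample, spec)
    beta, cov, n, g = cluster_ols(y, X, cl)
    b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    lo, hi = _wald_ci(b, se, spec.ci_level)
    return EstimateResult("ols", spec.outcome, b, se, lo, hi, "wald", n, g)


def fit_family_fe(sample: AnalysisSample, spec: ModelSpec | None = None) -> EstimateResult:
    """Family fixed-effects (sibling/twin) regression via within-demeaning.

    Covariates constant within family are dropped; families without
    within-family schooling variation contribute nothing to identification
    (their demeaned rows are zero) but remain in the reported n.
    """
    spec = spec or ModelSpec(fixed_effects="family")
    spec = replace(spec, fixed_effects="family")
    fam = factorize_clusters(sample.df["family_index"].to_numpy())
    y = _outcome(sample, spec)
    s = sample.df["schooling_years"].to_numpy(dtype=float)
    sw = demean_within(s, fam)
    if float(sw @ sw) <= 1e-12:
        raise DegenerateVariationError("no within-family variation in schooling")
    C, names = _covariates(sample, spec)
    Cw, kept, dropped = _drop_within_constant(C, names, fam)
    yw = demean_within(y, fam)
    X = np.column_stack([sw, Cw]) if Cw.size else sw[:, None]
    n_groups = int(fam.max()) + 1
    cl = _clusters(sample, spec)
    beta, cov, n, g = cluster_ols(yw, X, cl, k_absorbed=n_groups)
    b, se = float(beta[0]), float(np.sqrt(cov[0, 0]))
    lo, hi = _wald_ci(b, se, spec.ci_level)
    disc = int(((np.bincount(fam, weights=sw ** 2)) <= 1e-12).sum())
    return EstimateResult(
        "family_fe", spec.outcome, b, se, lo, hi, "wald", n, g,
        extras={"dropped_covariates": dropped, "n_families": n_groups,
                "n_families_no_variation": disc},
    )


# ------------------------------------------------------------------ IV

def _iv_arrays(sample: AnalysisSample, spec: ModelSpec):
    """Partialled (and optionally within-family demeaned) y, s, z arrays."""
    inst = spec.instrument or "piv_std"
    y = _outcome(sample, spec)
    s = sample.df["schooling_years"].to_numpy(dtype=float)
    z = sample.df[inst].to_numpy(dtype=float)
    C, names = _covariates(sample, spec)
    k_absorbed = 0
    if spec.fixed_effects == "family":
        fam = factorize_clusters(sample.df["family_index"].to_numpy())
        y, s, z = (demean_within(v, fam) for v in (y, s, z))
        C, names, _ = _drop_within_constant(C, names, fam)
        k_absorbed = int(fam.max()) + 1
    yt = partial_out(y, C)
    st = partial_out(s, C)
    zt = partial_out(z, C)
    return yt, st, zt, C.shape[1] + k_absorbed


def fit_tsls(sample: AnalysisSample, spec: ModelSpec | None = None) -> EstimateResult:
    """Just-identified 2SLS of the outcome on schooling, instrumented by the
    polygenic index, with covariates partialled from all three variables."""
    spec = spec or ModelSpec(instrument="piv_std")
    yt, st, zt, k_abs = _iv_arrays(sample, spec)
    n = len(yt)
    zz = float(zt @ zt)
    zs = float(zt @ st)
    if zz <= 0 or abs(zs) < 1e-10 * np.sqrt(zz * max(float(st @ st), 1e-300)):
        raise WeakInstrumentError("first-stage covariance between instrument and schooling is ~0")
    beta = float(zt @ yt) / zs
    u = yt - beta * st
    cl = _clusters(sample, spec)
    # scalar sandwich for the IV coefficient
    codes = cl
    g = int(codes.max()) + 1
    score = np.zeros(g)
    np.add.at(score, codes, zt * u)
    k_eff = 2 + k_abs
    corr = (g / max(g - 1, 1)) * ((n - 1) / max(n - k_eff, 1))
    se = float(np.sqrt(corr * np.sum(score ** 2)) / abs(zs))

    fs_b, fs_cov, _, _ = cluster_ols(st, zt[:, None], codes, k_absorbed=k_abs)
    fs_beta, fs_se = float(fs_b[0]), float(np.sqrt(fs_cov[0, 0]))
    F = (fs_beta / fs_se) ** 2 if fs_se > 0 else np.inf
    rf_b, rf_cov, _, _ = cluster_ols(yt, zt[:, None], codes, k_absorbed=k_abs)
    rf_beta, rf_se = float(rf_b[0]), float(np.sqrt(rf_cov[0, 0]))

    model = "sibling_mr" if spec.fixed_effects == "family" else "mr"
    if spec.ci_method == "anderson_rubin":
        ar = ar_confidence_interval(sample, spec)
        lo, hi, ci_method = ar.ci_low, ar.ci_high, "anderson_rubin"
    else:
        lo, hi = _wald_ci(beta, se, spec.ci_level)
        ci_method = "wald"
    return EstimateResult(
        model, spec.outcome, beta, se, lo, hi, ci_method, n, g,
        F_first_stage=F, first_stage_beta=fs_beta, first_stage_se=fs_se,
        reduced_form_beta=rf_beta, reduced_form_se=rf_se,
    )


def fit_sibling_mr(sample: AnalysisSample, spec: ModelSpec | None = None) -> EstimateResult:
    """2SLS with sibling (family) fixed effects in the estimation stage."""
    spec = spec or ModelSpec(instrument="piv_std")
    return fit_tsls(sample, replace(spec, fixed_effects="family"))


# ------------------------------------------------------------------ AR

@dataclass
class ARResult:
    p_value: object  # callable b -> p
    ci_low: float
    ci_high: float
    unbounded_low: bool = False
    unbounded_high: bool = False


def ar_confidence_interval(sample: AnalysisSample, spec: ModelSpec | None = None,
                           grid=None, tol: float = 1e-6) -> ARResult:
    """Invert the Anderson-Rubin test for a weak-instrument-robust CI.

    For a candidate value b, the AR statistic is the cluster-robust Wald test
    that the instrument coefficient is zero in a regression of ``y - b*s`` on
    the instrument (covariates partialled). The CI is the set of b with
    p(b) >= 1 - level; endpoints are found by bisection from a bracket that
    starts at +-10 Wald SEs and doubles until the test rejects (or the
    interval is declared open-ended).
    """
    spec = spec or ModelSpec(instrument="piv_std")
    yt, st, zt, k_abs = _iv_arrays(sample, spec)
    cl = _clusters(sample, spec)

    n_cl = int(np.max(cl)) + 1

    def p_value(b: float) -> float:
        coef, cov, _, _ = cluster_ols(yt - b * st, zt[:, None], cl, k_absorbed=k_abs)
        t = coef[0] / max(np.sqrt(cov[0, 0]), 1e-300)
        # t reference with G-1 dof: the usual few-cluster correction
        return float(2.0 * stats.t.sf(abs(t), max(n_cl - 1, 1)))

    zs = float(zt @ st)
    if abs(zs) < 1e-300:
        raise WeakInstrumentError("zero first stage; AR interval undefined")
    beta = float(zt @ yt) / zs
    wald = fit_tsls(sample, replace(spec, ci_method="wald"))
    alpha = 1.0 - spec.ci_level
    step = 10.0 * max(wald.se, 1e-12)

    def solve(direction: int):
        b_in = beta
        b_out = beta + direction * step
        for _ in range(8):
            if p_value(b_out) < alpha:
                break
            b_out = beta + direction * (b_out - beta) * 2.0
        else:
            return direction * np.inf, True
        lo, hi = (b_out, b_in) if direction < 0 else (b_in, b_out)
        # bisect p(b) - alpha between the accepted point and the rejected one
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if hi - lo < tol:
                break
            if direction < 0:
                if p_value(mid) >= alpha:
                    hi = mid
                else:
                    lo = mid
            else:
                if p_value(mid) >= alpha:
                    lo = mid
                else:
                    hi = mid
        return 0.5 * (lo + hi), False

    if grid is not None:
        ps = np.array([p_value(b) for b in grid])
        inside = grid[ps >= alpha]
        if len(inside) == 0:
            warnings.warn("AR acceptance region not found on supplied grid")
    lo, unb_lo = solve(-1)
    hi, unb_hi = solve(+1)
    return ARResult(p_value, float(lo), float(hi), unb_lo, unb_hi)


# ------------------------------------------------------------------ diagnostics

def balance_test(sample: AnalysisSample, instrument: str = "piv_std",
                 covariates=None, within_family: bool = False):
    """Standardized instrument-covariate associations plus a joint test.

    Regresses the standardized polygenic index on each standardized covariate
    (optionally within-family demeaned); under a valid genetic lottery the
    within-family associations are ~0 even when between-family ones are not.
    Returns ``(per_covariate_frame, joint_test_dict)``.
    """
    import pandas as pd

    names = list(covariates) if covariates is not None else list(sample.covariate_names)
    z = sample.df[instrument].to_numpy(dtype=float)
    C = sample.df[names].to_numpy(dtype=float)
    fam = factorize_clusters(sample.df["family_index"].to_numpy())
    if within_family:
        z = demean_within(z, fam)
        C = demean_within(C, fam)
    rows = []
    kept = []
    for j, nm in enumerate(names):
        c = C[:, j]
        if c.std() <= 1e-12:
            rows.append({"covariate": nm, "coef": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "skipped": True})
            warnings.warn(f"balance test: covariate {nm!r} is constant; skipped")
            continue
        zs = (z - z.mean()) / max(z.std(), 1e-12)
        cs = (c - c.mean()) / c.std()
        coef, cov, _, _ = cluster_ols(zs, np.column_stack([np.ones_like(cs), cs]), fam)
        b, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
        lo, hi = _wald_ci(b, se, 0.95)
        rows.append({"covariate": nm, "coef": b, "se": se,
                     "ci_low": lo, "ci_high": hi, "skipped": False})
        kept.append(j)
    joint = {"F": np.nan, "df": 0, "p": np.nan}
    if kept:
        Ck = C[:, kept]
        zs = (z - z.mean()) / max(z.std(), 1e-12)
        X = np.column_stack([np.ones(len(zs)), Ck])
        coef, cov, _, _ = cluster_ols(zs, X, fam)
        b = coef[1:]
        V = cov[1:, 1:]
        chi2 = float(b @ np.linalg.pinv(V) @ b)
        k = len(kept)
        joint = {"F": chi2 / k, "df": k, "p": float(stats.chi2.sf(chi2, k))}
    return pd.DataFrame(rows), joint


def parental_earnings_quartiles(values: np.ndarray) -> np.ndarray:
    """Quartile codes 0-3 with ties assigned to the lower quartile."""
    v = np.asarray(values, dtype=float)
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    return np.searchsorted(cuts, v, side="left")


def stratified_estimates(sample: AnalysisSample, spec: ModelSpec, stratifier,
                         estimator=fit_ols, min_n: int = 200) -> dict:
    """Run an estimator separately within strata of a grouping variable.

    ``stratifier`` is a column name or the string "parental_earnings_quartile"
    (quartiles of the estimation sample's parental-earnings distribution,
    ties to the lower quartile). Strata below ``min_n`` are omitted with a
    warning.
    """
    if stratifier == "parental_earnings_quartile":
        codes = parental_earnings_quartiles(sample.df["parental_earnings"].to_numpy())
    else:
        codes = sample.df[stratifier].to_numpy()
    levels = np.unique(codes)
    if len(levels) < 2:
        raise EstimationError("stratifier must have at least 2 levels")
    out = {}
    for lev in levels:
        mask = codes == lev
        if mask.sum() < min_n:
            warnings.warn(f"stratum {stratifier}={lev} has n={int(mask.sum())} < {min_n}; omitted")
            continue
        sub = sample.subset(mask, label=f"{sample.label}|{stratifier}={lev}")
        names = list(spec.covariates) if spec.covariates is not None else list(sub.covariate_names)
        keep = [c for c in names if sub.df[c].to_numpy(dtype=float).std() > 1e-12]
        out[lev] = estimator(sub, replace(spec, covariates=keep))
    return out
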