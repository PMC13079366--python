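"""SNP-level summary statistics and pleiotropy-robust summary MR estimators.

Per-SNP covariate-adjusted exposure (schooling) and outcome (log earnings)
associations feed the standard two-sample-style toolkit: inverse-variance
weighted (IVW) pooling with Cochran's Q, MR-Egger regression with its
directional-pleiotropy intercept test, the weighted median, mode-based
estimation (kernel-smoothed density of the per-SNP Wald ratios), a
core-gene ("corge") analysis that pools cumulatively from the strongest
instruments outward, and leave-one-out outlier screening.

Summaries are harmonized so every exposure association is non-negative
(effect alleles flipped as needed), the orientation MR-Egger requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisSample
from .regress import EstimationError, partial_out

SUMMARY_COLUMNS = ["SNP", "EA", "NEA", "EAF", "BETA_EXP", "SE_EXP", "BETA_OUT", "SE_OUT"]


@dataclass
class MRResult:
    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    Q: float | None = None
    Q_df: int | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_ci: tuple | None = None
    trajectory: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def _ci(b, se, level=0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    return b - z * se, b + z * se


# ------------------------------------------------------------------ summaries

def per_snp_associations(sample: AnalysisSample, covariates=None,
                         exposure: str = "published") -> pd.DataFrame:
    """Per-SNP exposure (schooling) and outcome (log-earnings) associations.

    The outcome side is always the covariate-adjusted regression of log
    earnings on each SNP's allele count within the sample. The exposure side
    defaults to the published discovery-GWAS betas carried by the SNP panel
    (the two-sample layout used when the score weights come from a large
    external discovery study, whose per-SNP precision a same-sample
    regression cannot match); ``exposure="sample"`` re-estimates it from the
    sample's own schooling regressions instead. Monomorphic SNPs are dropped
    with a warning, and alleles are flipped so every exposure association
    is >= 0.
    """
    if sample.genotypes is None or sample.panel is None:
        raise EstimationError("sample has no genotypes; use a genotyped sample")
    if exposure not in ("published", "sample"):
        raise ValueError("exposure must be 'published' or 'sample'")
    names = list(covariates) if covariates is not None else list(sample.covariate_names)
    C = sample.df[names].to_numpy(dtype=float)
    s = sample.df["schooling_years"].to_numpy(dtype=float)
    y = sample.df["log_earnings"].to_numpy(dtype=float)
    G = sample.genotypes.astype(float)
    n, m = G.shape

    poly = G.std(axis=0) > 0
    if not poly.all():
        warnings.warn(f"dropping {int((~poly).sum())} monomorphic SNPs")
    keep = np.flatnonzero(poly)
    Gt = partial_out(G[:, keep], C)
    yt = partial_out(y, C)

    gg = np.einsum("ij,ij->j", Gt, Gt)
    Gamma = (Gt.T @ yt) / gg
    k = C.shape[1] + 2  # intercept + covariates + allele count
    rss_out = np.maximum(yt @ yt - Gamma ** 2 * gg, 0.0)
    se_out = np.sqrt(rss_out / (n - k) / gg)
    if exposure == "sample":
        st = partial_out(s, C)
        gamma = (Gt.T @ st) / gg
        rss_exp = np.maximum(st @ st - gamma ** 2 * gg, 0.0)
        se_exp = np.sqrt(rss_exp / (n - k) / gg)
    else:
        gamma = sample.panel.score_weight[keep].astype(float).copy()
        se_exp = sample.panel.pub_se_exp[keep].astype(float).copy()

    panel = sample.panel
    ea = panel.effect_allele[keep].copy()
    nea = panel.other_allele[keep].copy()
    eaf = G[:, keep].mean(axis=0) / 2.0
    flip = gamma < 0
    gamma[flip] *= -1.0
    Gamma[flip] *= -1.0
    ea[flip], nea[flip] = nea[flip], ea[flip].copy()
    eaf[flip] = 1.0 - eaf[flip]

    return pd.DataFrame({
        "SNP": panel.ids[keep], "EA": ea, "NEA": nea, "EAF": eaf,
        "BETA_EXP": gamma, "SE_EXP": se_exp, "BETA_OUT": Gamma, "SE_OUT": se_out,
    })


def harmonize(summary: pd.DataFrame) -> pd.DataFrame:
    """Flip allele coding so every exposure association is non-negative."""
    out = summary.copy()
    flip = out["BETA_EXP"].to_numpy() < 0
    for col, fn in (("BETA_EXP", lambda v: -v), ("BETA_OUT", lambda v: -v),
                    ("EAF", lambda v: 1.0 - v)):
        vals = out[col].to_numpy(dtype=float).copy()
        vals[flip] = fn(vals[flip])
        out[col] = vals
    ea, nea = out["EA"].to_numpy().copy(), out["NEA"].to_numpy().copy()
    ea[flip], nea[flip] = nea[flip], ea[flip].copy()
    out["EA"], out["NEA"] = ea, nea
    return out


def _ratios_weights(summary: pd.DataFrame):
    g = summary["BETA_EXP"].to_numpy(dtype=float)
    G = summary["BETA_OUT"].to_numpy(dtype=float)
    seG = summary["SE_OUT"].to_numpy(dtype=float)
    ok = g != 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} SNPs with zero exposure association")
    g, G, seG = g[ok], G[ok], seG[ok]
    b = G / g
    w = g ** 2 / seG ** 2
    return b, w, g, G, seG


# ------------------------------------------------------------------ estimators

def ivw(summary: pd.DataFrame) -> MRResult:
    """Inverse-variance-weighted MR with Cochran's Q heterogeneity.

    Equivalent to weighted through-origin regression of the outcome
    associations on the exposure associations with weights 1/se_out^2.
    """
    b, w, *_ = _ratios_weights(summary)
    if len(b) < 1:
        raise EstimationError("IVW needs at least 1 usable SNP")
    est = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    Q = float(np.sum(w * (b - est) ** 2))
    lo, hi = _ci(est, se)
    return MRResult("ivw", est, se, lo, hi, len(b), Q=Q, Q_df=len(b) - 1)


def egger(summary: pd.DataFrame) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure associations with
    a free intercept; the intercept estimates directional pleiotropy.

    Standard errors use a multiplicative overdispersion factor bounded below
    by 1 (random-effects convention).
    """
    s = harmonize(summary)
    _, w, g, G, seG = _ratios_weights(s)
    if len(g) < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    if np.ptp(g) < 1e-12:
        raise EstimationError("all exposure associations equal; Egger slope unidentified")
    wt = 1.0 / seG ** 2
    X = np.column_stack([np.ones_like(g), g])
    WX = X * wt[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ G)
    resid = G - X @ coef
    df = len(g) - 2
    disp = max(1.0, float(np.sum(wt * resid ** 2) / df))
    cov = disp * np.linalg.inv(xtwx)
    slope, slope_se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    icpt, icpt_se = float(coef[0]), float(np.sqrt(cov[0, 0]))
    lo, hi = _ci(slope, slope_se)
    return MRResult("egger", slope, slope_se, lo, hi, len(g),
                    egger_intercept=icpt, egger_intercept_se=icpt_se,
                    egger_intercept_ci=_ci(icpt, icpt_se))


def weighted_median(summary: pd.DataFrame, n_boot: int = 1000,
                    rng=None) -> MRResult:
    """Weighted median of per-SNP ratios (valid if <50% of weight is invalid).

    The estimate interpolates the order statistics where the cumulative
    standardized IVW weight crosses 0.5; the SE comes from a parametric
    bootstrap of the per-SNP associations.
    """
    rng = np.random.default_rng(rng if rng is not None else 0)
    s = harmonize(summary)
    b, w, g, G, seG = _ratios_weights(s)
    if len(b) < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    seg = s.loc[s["BETA_EXP"] != 0, "SE_EXP"].to_numpy(dtype=float)

    def wm(bv, wv):
        # aggregate exact ties so the estimate is order-invariant
        bs, inv = np.unique(bv, return_inverse=True)
        ws = np.bincount(inv, weights=wv)
        ws = ws / ws.sum()
        cum = np.cumsum(ws) - ws / 2.0
        return float(np.interp(0.5, cum, bs))

    est = wm(b, w)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        gb = rng.normal(g, seg)
        Gb = rng.normal(G, seG)
        ok = gb != 0
        boots[i] = wm(Gb[ok] / gb[ok], gb[ok] ** 2 / seG[ok] ** 2)
    se = float(boots.std(ddof=1))
    lo, hi = _ci(est, se)
    return MRResult("weighted_median", est, se, lo, hi, len(b))


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw - w[order] / 2.0, x[order]))


def _mode_point(b, w, bandwidth_factor):
    """Weighted kernel-density mode of the ratio estimates.

    The modified-Silverman scale uses weighted spread measures so that
    low-precision ratios (weak SNPs with exploding Wald ratios) cannot blow
    up the bandwidth.
    """
    sd = np.sqrt(np.average((b - np.average(b, weights=w)) ** 2, weights=w))
    med = _weighted_quantile(b, w, 0.5)
    mad = _weighted_quantile(np.abs(b - med), w, 0.5) / 0.6745
    scale = min(sd, mad) if mad > 0 else sd
    h = max(bandwidth_factor * 0.9 * scale * len(b) ** (-1 / 5), 1e-12)
    # search where the weighted mass lives, at a resolution finer than h
    # (extreme weak-SNP ratios must not coarsen the grid past the peak width)
    lo = _weighted_quantile(b, w, 0.005) - 3 * h
    hi = _weighted_quantile(b, w, 0.995) + 3 * h
    n_grid = int(min(max(1024, 4 * (hi - lo) / h), 200_000))
    grid = np.linspace(lo, hi, n_grid)
    dens = (w[None, :] * stats.norm.pdf((grid[:, None] - b[None, :]) / h)).sum(axis=1)
    peak = dens.max()
    top = np.flatnonzero(dens >= peak * (1 - 1e-9))
    tie = False
    if len(top) > 1 and (grid[top[-1]] - grid[top[0]]) > 2 * h:
        tie = True
        # keep the candidate with more total nearby weight
        best, best_w = grid[top[0]], -np.inf
        for t in top:
            near = np.abs(b - grid[t]) <= h
            if w[near].sum() > best_w:
                best, best_w = grid[t], w[near].sum()
        return float(best), tie, h
    return float(grid[dens.argmax()]), tie, h


def mode_estimator(summary: pd.DataFrame, bandwidth_factor: float = 1.0,
                   weighted: bool = True, n_boot: int = 1000, rng=None) -> MRResult:
    """Mode-based estimate: the most common per-SNP ratio is taken as causal.

    ``weighted=False`` gives the simple (unweighted) variant. SE by
    parametric bootstrap.
    """
    rng = np.random.default_rng(rng if rng is not None else 0)
    s = harmonize(summary)
    b, w, g, G, seG = _ratios_weights(s)
    if len(b) < 3:
        raise EstimationError("mode estimator needs at least 3 SNPs")
    seg = s.loc[s["BETA_EXP"] != 0, "SE_EXP"].to_numpy(dtype=float)
    wts = w if weighted else np.ones_like(b)
    est, tie, h = _mode_point(b, wts, bandwidth_factor)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        gb = rng.normal(g, seg)
        Gb = rng.normal(G, seG)
        ok = gb != 0
        bb = Gb[ok] / gb[ok]
        wb = (gb[ok] ** 2 / seG[ok] ** 2) if weighted else np.ones(ok.sum())
        boots[i], _, _ = _mode_point(bb, wb, bandwidth_factor)
    se = float(boots.std(ddof=1))
    lo, hi = _ci(est, se)
    label = "weighted_mode" if weighted else "simple_mode"
    return MRResult(label, est, se, lo, hi, len(b),
                    flags={"bandwidth": h, "multimodal_tie": tie})


def corge(summary: pd.DataFrame, n_groups: int = 10) -> MRResult:
    """Core-gene analysis: IVW within cumulative groups ranked by instrument
    strength (descending gamma^2/se_gamma^2); the core-group estimate is
    primary and the trajectory across cumulative groups is reported."""
    if n_groups < 2:
        raise EstimationError("corge needs n_groups >= 2")
    s = harmonize(summary).reset_index(drop=True)
    if len(s) < n_groups:
        raise EstimationError("corge needs at least n_groups SNPs")
    strength = (s["BETA_EXP"] / s["SE_EXP"]) ** 2
    order = np.argsort(-strength.to_numpy())
    groups = np.array_split(order, n_groups)
    trajectory = []
    cum_idx = np.array([], dtype=int)
    core = None
    for gi, idx in enumerate(groups, start=1):
        cum_idx = np.concatenate([cum_idx, idx])
        res = ivw(s.iloc[cum_idx])
        trajectory.append({"groups": gi, "n_snps": len(cum_idx),
                           "estimate": res.estimate, "se": res.se})
        if gi == 1:
            core = res
    return MRResult("corge", core.estimate, core.se, core.ci_low, core.ci_high,
                    core.n_snps, trajectory=trajectory)


def leave_one_out(summary: pd.DataFrame, estimator=ivw, flag_multiple: float = 3.0) -> pd.DataFrame:
    """Recompute an estimator leaving each SNP out once; flag influential SNPs
    whose omission moves the estimate by more than ``flag_multiple`` full-
    sample SEs."""
    s = summary.reset_index(drop=True)
    if len(s) < 4:
        raise EstimationError("leave-one-out needs at least 4 SNPs")
    full = estimator(s)
    rows = []
    for i in range(len(s)):
        res = estimator(s.drop(index=i))
        rows.append({
            "SNP": s.loc[i, "SNP"],
            "estimate": res.estimate,
            "shift": res.estimate - full.estimate,
            "flagged": abs(res.estimate - full.estimate) > flag_multiple * full.se,
        })
    return pd.DataFrame(rows)
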