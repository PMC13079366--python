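"""Analysis-variable derivation and sample construction.

Turns a simulated :class:`~genlottery.simulate.Population` into the analysis
samples the estimation suite runs on: the full population, the sibling sample
(families with at least two included offspring), complete DZ and MZ twin
pairs, and the genotyped cohort with its sibling (FGWAS discovery) and
unrelated (one-per-family estimation) subsamples. Cohort participation is
decided at the family level, optionally correlated with parental earnings to
emulate self-selected study enrolment.

The prime-age outcome is the mean of the top three earnings years during ages
34-40; schooling is the final integer years-of-schooling value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AGES, ENTRY_LAG, InputError, Population

#: covariates used by all covariate-adjusted models (demographics + family)
DEFAULT_COVARIATES = [
    "sex",
    "parental_education",
    "log_parental_earnings",
    "n_children",
    "birth_year",
    "birth_order",
    "mother_age_at_birth",
    "father_age_at_birth",
]

PRIME_AGE_WINDOW = (34, 40)
TOP_K = 3


def prime_age_earnings(earnings_by_age, window=PRIME_AGE_WINDOW, k=TOP_K) -> float:
    """Mean of the k largest earnings among observed ages in the window.

    ``earnings_by_age`` is a mapping age -> earnings. If fewer than ``k``
    years are observed in the window, the mean of what exists is returned.
    """
    lo, hi = window
    if hi < lo:
        raise InputError("empty prime-age window")
    vals = [v for a, v in earnings_by_age.items() if lo <= a <= hi]
    if not vals:
        raise InputError(f"no observed ages in window [{lo}, {hi}]")
    top = sorted(vals, reverse=True)[:k]
    return float(np.mean(top))


def prime_age_earnings_matrix(earnings: np.ndarray, ages: np.ndarray,
                              window=PRIME_AGE_WINDOW, k=TOP_K) -> np.ndarray:
    """Vectorized prime-age outcome over an (n, n_ages) earnings matrix."""
    lo, hi = window
    cols = np.flatnonzero((ages >= lo) & (ages <= hi))
    if len(cols) == 0:
        raise InputError(f"no panel ages in window [{lo}, {hi}]")
    sub = earnings[:, cols]
    kk = min(k, sub.shape[1])
    part = np.partition(sub, sub.shape[1] - kk, axis=1)[:, sub.shape[1] - kk:]
    return part.mean(axis=1)


def potential_experience(age, schooling_years):
    """Potential labor-market experience: age - schooling - 7, floored at 0."""
    return np.maximum(np.asarray(age) - np.asarray(schooling_years) - ENTRY_LAG, 0)


@dataclass
class AnalysisSample:
    """One analysis sample: outcome/schooling vectors plus aligned arrays.

    ``df`` rows align with ``genotypes`` and ``earnings`` rows. ``piv_std``
    in ``df`` is re-standardized within this sample (mean 0, SD 1) for
    genotyped samples.
    """

    label: str
    df: pd.DataFrame
    covariate_names: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    genotypes: np.ndarray | None = None
    panel: object | None = None
    earnings: np.ndarray | None = None
    ages: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    def covariate_matrix(self, names=None) -> np.ndarray:
        names = self.covariate_names if names is None else names
        return self.df[list(names)].to_numpy(dtype=float)

    def subset(self, mask, label: str | None = None,
               restandardize_piv: bool = True) -> "AnalysisSample":
        """Row-subset keeping genotype/earnings alignment."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        df = self.df.iloc[idx].reset_index(drop=True)
        if restandardize_piv and "piv_std" in df and len(df) > 1:
            piv = df["piv_raw"].to_numpy()
            sd = piv.std()
            if sd > 0:
                df = df.assign(piv_std=(piv - piv.mean()) / sd)
        return AnalysisSample(
            label=label or self.label,
            df=df,
            covariate_names=list(self.covariate_names),
            genotypes=None if self.genotypes is None else self.genotypes[idx],
            panel=self.panel,
            earnings=None if self.earnings is None else self.earnings[idx],
            ages=self.ages,
        )


def _family_sizes(df: pd.DataFrame) -> pd.Series:
    return df.groupby("family_index")["id"].transform("size")


def build_samples(population: Population, standardize_piv_within_sample: bool = True):
    """Construct the six sample types plus the genotyped base sample.

    Returns ``(samples, flow_log)`` where ``samples`` maps labels
    (full, sibling, twin_dz, twin_mz, genotyped, genotyped_sibling,
    genotyped_unrelated) to :class:`AnalysisSample`. Membership is a pure
    function of the population (participation draws are seeded from the
    population seed).
    """
    cfg = population.config
    off = population.offspring.copy()
    off["row"] = np.arange(len(off))
    flow = {"n_offspring": int(len(off))}

    y = prime_age_earnings_matrix(population.earnings, population.ages)
    off["earnings_prime"] = y
    valid_earn = y > 0
    flow["excluded_nonpositive_prime_earnings"] = int((~valid_earn).sum())
    off = off[valid_earn].copy()
    off["log_earnings"] = np.log(off["earnings_prime"])
    off["log_parental_earnings"] = np.log(off["parental_earnings"])
    flow["n_after_exclusions"] = int(len(off))

    # family-level cohort participation (parental decision), optionally
    # correlated with parental earnings
    rng = np.random.default_rng(population.seed + 77003)
    n_fam = population.n_families
    fam_logpe = np.zeros(n_fam)
    fam_pe = off.groupby("family_index")["log_parental_earnings"].first()
    fam_logpe[fam_pe.index.to_numpy()] = fam_pe.to_numpy()
    z = (fam_logpe - fam_logpe.mean()) / max(fam_logpe.std(), 1e-12)
    base = np.clip(cfg.genotyped_family_prob, 1e-9, 1 - 1e-9)
    logit = np.log(base / (1 - base)) + cfg.genotyped_selection_on_parental_earnings * z
    p_fam = 1.0 / (1.0 + np.exp(-logit))
    geno_fam = rng.random(n_fam) < p_fam
    flow["n_genotyped_families"] = int(geno_fam.sum())

    def make(label: str, sub: pd.DataFrame, genotyped: bool) -> AnalysisSample:
        sub = sub.copy()
        rows = sub["row"].to_numpy()
        geno = population.geno_offspring[rows] if genotyped else None
        if genotyped and len(sub) > 1 and standardize_piv_within_sample:
            piv = sub["piv_raw"].to_numpy()
            sub["piv_std"] = (piv - piv.mean()) / max(piv.std(), 1e-12)
        return AnalysisSample(
            label=label,
            df=sub.reset_index(drop=True),
            covariate_names=list(DEFAULT_COVARIATES),
            genotypes=geno,
            panel=population.panel if genotyped else None,
            earnings=population.earnings[rows],
            ages=population.ages,
        )

    samples = {"full": make("full", off, genotyped=False)}

    sib = off[_family_sizes(off) >= 2]
    samples["sibling"] = make("sibling", sib, genotyped=False)
    flow["n_sibling"] = int(len(sib))
    if len(sib) == 0:
        flow["warning_sibling_empty"] = True

    for zt, label in (("DZ", "twin_dz"), ("MZ", "twin_mz")):
        tw = off[off["zygosity"] == zt]
        complete = tw.groupby("family_index")["id"].transform("size") == 2
        tw = tw[complete]
        samples[label] = make(label, tw, genotyped=False)
        flow[f"n_{label}"] = int(len(tw))

    geno_off = off[geno_fam[off["family_index"].to_numpy()]]
    samples["genotyped"] = make("genotyped", geno_off, genotyped=True)
    flow["n_genotyped"] = int(len(geno_off))

    gsib = geno_off[_family_sizes(geno_off) >= 2]
    samples["genotyped_sibling"] = make("genotyped_sibling", gsib, genotyped=True)
    flow["n_genotyped_sibling"] = int(len(gsib))

    discovery_fams = set(gsib["family_index"].unique())
    unrel = geno_off[~geno_off["family_index"].isin(discovery_fams)]
    unrel = unrel.sort_values(["family_index", "birth_order"]).groupby("family_index").head(1)
    samples["genotyped_unrelated"] = make("genotyped_unrelated", unrel, genotyped=True)
    flow["n_genotyped_unrelated"] = int(len(unrel))

    return samples, flow
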