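"""Family-genetics and earnings-panel simulator.

Generates pedigree-linked populations (parent pairs plus 1-3 offspring,
including MZ/DZ twins) with Mendelian transmission at independent biallelic
SNPs, a weighted polygenic index for educational attainment, integer years of
schooling in [6, 23], and annual earnings panels over ages 17-62 with concave
experience profiles. Every confounding channel a genetic-lottery study must
worry about is a switchable parameter: individual ability, dynastic (genetic
nurture) effects, assortative mating, population stratification (optionally
absorbed into the published score weights), SNP-level pleiotropy, and
heterogeneous returns concentrated among instrument compliers.

The model for offspring ``i`` at age ``t`` (after labor-market entry at age
``S_i + 7``, with potential experience ``x_it = t - S_i - 7``):

    S*_i    = 13 + (1 + h * g_i) * T_i + a_S * A_i + d_S * M_i + strat + eps
    S_i     = round(S*_i) clipped to [6, 23]
    log y_it = mu + s * x_it - c * x_it^2 + beta_i * S_i
               + a_Y * A_i + d_Y * M_i + sum_j delta_j G_ij + strat + u_i + e_it

where ``T_i`` is the true per-allele genetic score (scaled so one SD moves
schooling by ``pi_first_stage`` years), ``A_i`` latent ability, ``M_i`` the
standardized mid-parental polygenic score, ``g_i`` the latent gain modifier,
and ``beta_i = beta_true + hetero_kappa * g_i (+ sex gap)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimConfig

AGES = np.arange(17, 63)  # observed panel ages, inclusive
SCHOOL_MIN, SCHOOL_MAX = 6, 23
ENTRY_LAG = 7  # labor-market entry at schooling + 7 (school entry at age 7)

_BASES = np.array(list("ACGT"))


class InputError(ValueError):
    """Raised on malformed inputs to simulation operations."""


# --------------------------------------------------------------------------
# SNP panel
# --------------------------------------------------------------------------

@dataclass
class SNPPanel:
    """Per-SNP truth: frequencies, published score weights and causal effects.

    ``freqs`` has shape (n_subpops, n_snps). ``true_schooling_effect`` is in
    years per effect allele; ``true_direct_effect`` in log-earnings per effect
    allele (zero for valid instruments). ``score_weight`` is the published
    ("discovery GWAS") weight actually used to build the polygenic index.
    """

    ids: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    freqs: np.ndarray
    score_weight: np.ndarray
    true_schooling_effect: np.ndarray
    true_direct_effect: np.ndarray
    #: published discovery-GWAS sampling SE per SNP (years/allele); the
    #: score weights ARE the published discovery betas
    pub_se_exp: np.ndarray = field(default=None)
    #: orientation of the stratification frequency contrast per SNP (+1/-1/0)
    strat_direction: np.ndarray = field(default=None)

    @property
    def n_snps(self) -> int:
        return len(self.ids)

    @property
    def mean_freq(self) -> np.ndarray:
        return self.freqs.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "snp": self.ids,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "score_weight": self.score_weight,
                "true_schooling_effect": self.true_schooling_effect,
                "true_direct_effect": self.true_direct_effect,
            }
        )
        for k in range(self.freqs.shape[0]):
            df[f"freq_subpop{k}"] = self.freqs[k]
        return df


def draw_snp_panel(config: SimConfig, rng: np.random.Generator) -> SNPPanel:
    """Draw an independent biallelic SNP panel with truth and score weights.

    Exactly ``round(pleio_fraction * n_snps)`` SNPs (chosen by a seeded
    shuffle, so the set is deterministic given the generator state) receive a
    nonzero direct effect on earnings. Per-allele schooling effects are scaled
    so that one SD of the true genetic score shifts schooling by
    ``pi_first_stage`` years under Hardy-Weinberg proportions.
    """
    m = config.n_snps
    lo, hi = config.allele_freq_range
    base_freq = rng.uniform(lo, hi, size=m)

    # raw effect directions/magnitudes; the published weight is truth plus
    # estimation noise (plus optional stratification contamination)
    u = rng.normal(0.0, config.snp_effect_sd, size=m)
    u[u == 0.0] = config.snp_effect_sd  # guard: keep signs well defined

    # stratification structure of allele frequencies across subpopulations
    if config.n_subpops > 1 and config.subpop_freq_offset > 0:
        if config.subpop_align_effects:
            direction = np.sign(u)
        else:
            direction = rng.choice([-1.0, 1.0], size=m)
        spread = np.linspace(-1.0, 1.0, config.n_subpops)[:, None]
        freqs = base_freq[None, :] + spread * config.subpop_freq_offset * direction[None, :]
        freqs = np.clip(freqs, 0.005, 0.995)
    else:
        direction = np.zeros(m)
        freqs = base_freq[None, :].repeat(config.n_subpops, axis=0)

    # scale per-allele effects so SD(true score) = pi_first_stage under HWE
    fbar = freqs.mean(axis=0)
    raw_var = float(np.sum(u ** 2 * 2.0 * fbar * (1.0 - fbar)))
    scale = config.pi_first_stage / np.sqrt(raw_var) if raw_var > 0 else 0.0
    true_effect = u * scale

    # published discovery-GWAS betas: truth plus estimation noise (plus the
    # stratification contamination a confounded discovery sample absorbs);
    # these serve both as score weights and as the summary-MR exposure side
    sd_e = float(np.std(true_effect)) or 1.0
    weight = true_effect + rng.normal(0.0, config.discovery_gwas_se, size=m)
    if config.weight_strat_contamination != 0.0:
        weight = weight + config.weight_strat_contamination * sd_e * direction
    pub_se = np.full(m, max(config.discovery_gwas_se, 1e-12))

    # pleiotropic direct effects, directional component aligned with the
    # schooling-increasing allele (survives gamma>=0 harmonization)
    n_pleio = int(round(config.pleio_fraction * m))
    direct = np.zeros(m)
    if n_pleio > 0:
        idx = rng.permutation(m)[:n_pleio]
        direct[idx] = (
            config.pleio_effect_mean * np.sign(u[idx])
            + rng.normal(0.0, config.pleio_effect_sd, size=n_pleio)
        )
        zero = direct[idx] == 0.0
        if np.any(zero):  # keep "nonzero direct effect" literally true
            direct[idx[zero]] = config.pleio_effect_mean if config.pleio_effect_mean else 1e-12

    alleles = rng.integers(0, 4, size=m)
    other = (alleles + 1 + rng.integers(0, 3, size=m)) % 4
    ids = np.array([f"rs{100000 + j}" for j in range(m)])
    return SNPPanel(
        ids=ids,
        effect_allele=_BASES[alleles],
        other_allele=_BASES[other],
        freqs=freqs,
        score_weight=weight,
        true_schooling_effect=true_effect,
        true_direct_effect=direct,
        pub_se_exp=pub_se,
        strat_direction=direction,
    )


# --------------------------------------------------------------------------
# polygenic index
# --------------------------------------------------------------------------

def compute_piv(genotypes: np.ndarray, weights: np.ndarray, standardize: bool = True):
    """Weighted allele score ``sum_j G_ij * w_j``; optionally standardized.

    Returns ``(raw, std)``; ``std`` is None when ``standardize`` is False.
    Standardization is within the supplied sample (mean 0, SD 1).
    """
    genotypes = np.asarray(genotypes)
    weights = np.asarray(weights, dtype=float)
    if genotypes.shape[-1] != weights.shape[0]:
        raise InputError(
            f"genotype columns ({genotypes.shape[-1]}) != weight length ({weights.shape[0]})"
        )
    raw = genotypes.astype(float) @ weights
    if not standardize:
        return raw, None
    sd = raw.std()
    if sd == 0:
        raise InputError("cannot standardize a constant polygenic score")
    return raw, (raw - raw.mean()) / sd


# --------------------------------------------------------------------------
# parents
# --------------------------------------------------------------------------

@dataclass
class ParentPairs:
    """Matched mother/father pairs with genotypes and phenotypes."""

    geno_mother: np.ndarray
    geno_father: np.ndarray
    subpop: np.ndarray
    mother_piv_raw: np.ndarray
    father_piv_raw: np.ndarray
    mother_edu: np.ndarray
    father_edu: np.ndarray
    mother_earn: np.ndarray
    father_earn: np.ndarray

    @property
    def n(self) -> int:
        return len(self.subpop)


def _draw_genotypes(freqs: np.ndarray, subpop: np.ndarray, rng) -> np.ndarray:
    """Binomial(2, f) genotypes for individuals with given subpop labels."""
    p = freqs[subpop]  # (n, m)
    return rng.binomial(2, p).astype(np.int8)


def simulate_parent_pairs(config: SimConfig, panel: SNPPanel, rng: np.random.Generator) -> ParentPairs:
    """Draw parent pairs; assortative mating by Gaussian-copula rank matching.

    Spousal polygenic-score correlation is induced by matching father score
    ranks to a latent variable correlated ``rho_assortative`` with the
    mother's standardized score, within subpopulation (so stratification and
    assortment do not conflate).
    """
    n = config.n_families
    subpop = rng.integers(0, config.n_subpops, size=n)
    gm = _draw_genotypes(panel.freqs, subpop, rng)
    gf = _draw_genotypes(panel.freqs, subpop, rng)
    piv_m, _ = compute_piv(gm, panel.score_weight, standardize=False)
    piv_f, _ = compute_piv(gf, panel.score_weight, standardize=False)

    rho = config.rho_assortative
    if rho > 0:
        order = np.arange(n)
        for k in range(config.n_subpops):
            mask = np.flatnonzero(subpop == k)
            if len(mask) < 2:
                continue
            a = piv_m[mask]
            a_std = (a - a.mean()) / max(a.std(), 1e-12)
            latent = rho * a_std + np.sqrt(1.0 - rho ** 2) * rng.normal(size=len(mask))
            # father with r-th smallest score goes to mother with r-th
            # smallest latent value
            perm = np.empty(len(mask), dtype=int)
            perm[np.argsort(latent)] = np.argsort(piv_f[mask])
            order[mask] = mask[perm]
        gf = gf[order]
        piv_f = piv_f[order]

    def _phenotypes(piv):
        z = (piv - piv.mean()) / max(piv.std(), 1e-12)
        edu = np.clip(
            np.round(13.0 + config.parent_edu_piv_loading * z
                     + rng.normal(0.0, config.parent_edu_noise_sd, size=n)),
            SCHOOL_MIN, SCHOOL_MAX,
        )
        earn = np.exp(
            12.9
            + config.parent_earn_edu_loading * (edu - 13.0)
            + rng.normal(0.0, config.parent_earn_noise_sd, size=n)
        )
        return edu, earn

    edu_m, earn_m = _phenotypes(piv_m)
    edu_f, earn_f = _phenotypes(piv_f)
    return ParentPairs(
        geno_mother=gm, geno_father=gf, subpop=subpop,
        mother_piv_raw=piv_m, father_piv_raw=piv_f,
        mother_edu=edu_m, father_edu=edu_f,
        mother_earn=earn_m, father_earn=earn_f,
    )


# --------------------------------------------------------------------------
# Mendelian transmission
# --------------------------------------------------------------------------

def _transmit_block(gm: np.ndarray, gf: np.ndarray, rng) -> np.ndarray:
    """One offspring genotype per row: one allele drawn per parent.

    For a parent with genotype g in {0,1,2} the transmitted allele is an
    effect allele with probability g/2 (uniform draw of one of two alleles).
    """
    pm = gm.astype(np.float32) * 0.5
    pf = gf.astype(np.float32) * 0.5
    child = (rng.random(pm.shape, dtype=np.float32) < pm).astype(np.int8)
    child += (rng.random(pf.shape, dtype=np.float32) < pf).astype(np.int8)
    return child


def mendelian_transmit(pair, panel: SNPPanel, rng, zygosity: str | None = None):
    """Offspring genotype vector(s) from a (mother, father) genotype pair.

    Returns a list of one vector, or two for ``zygosity`` in {"MZ", "DZ"}:
    MZ twins are one meiotic draw duplicated, DZ twins two independent draws.
    """
    gm, gf = (np.asarray(g, dtype=np.int8).reshape(1, -1) for g in pair)
    if gm.shape != gf.shape or gm.shape[1] != panel.n_snps:
        raise InputError("parental genotype vectors must both have one entry per panel SNP")
    first = _transmit_block(gm, gf, rng)[0]
    if zygosity is None or zygosity == "none":
        return [first]
    if zygosity == "MZ":
        return [first, first.copy()]
    if zygosity == "DZ":
        return [first, _transmit_block(gm, gf, rng)[0]]
    raise InputError(f"unknown zygosity {zygosity!r}")


# --------------------------------------------------------------------------
# population container
# --------------------------------------------------------------------------

@dataclass
class Population:
    """A simulated pedigree-linked population.

    ``offspring`` rows align with ``geno_offspring`` and ``earnings`` rows;
    ``parents`` rows (two per family) align with the family order of
    ``geno_mother`` / ``geno_father`` through ``family_index``.
    """

    config: SimConfig
    seed: int
    panel: SNPPanel
    offspring: pd.DataFrame
    parents: pd.DataFrame
    geno_offspring: np.ndarray
    geno_mother: np.ndarray
    geno_father: np.ndarray
    earnings: np.ndarray = None
    ages: np.ndarray = field(default_factory=lambda: AGES.copy())

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    @property
    def n_families(self) -> int:
        return self.geno_mother.shape[0]

    def validate(self) -> None:
        off = self.offspring
        assert off["family_index"].between(0, self.n_families - 1).all()
        assert off["schooling_years"].between(SCHOOL_MIN, SCHOOL_MAX).all()
        if self.earnings is not None:
            assert (self.earnings >= 0).all()


def _assemble_offspring(config, panel, pairs, rng) -> Population:
    n_fam = pairs.n
    sizes = rng.choice([1, 2, 3], size=n_fam, p=config.offspring_dist)
    twin_fam = rng.random(n_fam) < config.twin_prob
    sizes = np.where(twin_fam, np.maximum(sizes, 2), sizes)
    mz_fam = twin_fam & (rng.random(n_fam) < config.mz_share)

    fam_index = np.repeat(np.arange(n_fam), sizes)
    n_off = len(fam_index)
    within = np.concatenate([np.arange(k) for k in sizes])  # 0-based birth order

    zyg = np.full(n_off, "none", dtype=object)
    is_twin = twin_fam[fam_index] & (within < 2)
    zyg[is_twin & mz_fam[fam_index]] = "MZ"
    zyg[is_twin & ~mz_fam[fam_index]] = "DZ"

    # genotypes: independent meioses, then duplicate the MZ co-twin
    geno = np.empty((n_off, panel.n_snps), dtype=np.int8)
    block = 20000
    for start in range(0, n_off, block):
        sl = slice(start, min(start + block, n_off))
        geno[sl] = _transmit_block(
            pairs.geno_mother[fam_index[sl]], pairs.geno_father[fam_index[sl]], rng
        )
    mz_second = np.flatnonzero((zyg == "MZ") & (within == 1))
    geno[mz_second] = geno[mz_second - 1]

    piv_raw, piv_std = compute_piv(geno, panel.score_weight)

    # birth years: shared for twins, sorted within family for birth order
    byear = rng.integers(1959, 1983, size=n_off)
    fam_starts = np.concatenate([[0], np.cumsum(sizes)])
    for f in np.flatnonzero(twin_fam):
        s = fam_starts[f]
        byear[s + 1] = byear[s]
    # sort birth years within each family block so birth order is coherent
    # (twins already share a year, so adjacency is preserved)
    for f in range(n_fam):
        s, e = fam_starts[f], fam_starts[f + 1]
        if e - s > 1:
            byear[s:e] = np.sort(byear[s:e])

    sex = rng.integers(0, 2, size=n_off)  # 1 = female
    ability = rng.normal(0.0, config.ability_sd, size=n_off)
    gain = rng.normal(0.0, 1.0, size=n_off)
    mother_age = np.clip(rng.normal(28.0, 4.0, size=n_off), 18, 45)
    father_age = np.clip(rng.normal(31.0, 5.0, size=n_off), 18, 48)

    zm = (pairs.mother_piv_raw - pairs.mother_piv_raw.mean()) / max(pairs.mother_piv_raw.std(), 1e-12)
    zf = (pairs.father_piv_raw - pairs.father_piv_raw.mean()) / max(pairs.father_piv_raw.std(), 1e-12)
    mid = (zm + zf) / 2.0
    mid = (mid - mid.mean()) / max(mid.std(), 1e-12)

    fam_ids = np.array([f"fam{f}" for f in range(n_fam)])
    offspring = pd.DataFrame(
        {
            "id": [f"fam{f}_c{w + 1}" for f, w in zip(fam_index, within)],
            "family_id": fam_ids[fam_index],
            "family_index": fam_index,
            "mother_id": [f"fam{f}_m" for f in fam_index],
            "father_id": [f"fam{f}_f" for f in fam_index],
            "zygosity": zyg,
            "sex": sex,
            "birth_year": byear,
            "birth_order": within + 1,
            "n_children": sizes[fam_index],
            "subpop": pairs.subpop[fam_index],
            "ability": ability,
            "gain_modifier": gain,
            "piv_raw": piv_raw,
            "piv_std": piv_std,
            "midparent_piv_std": mid[fam_index],
            "parental_education": (pairs.mother_edu[fam_index] + pairs.father_edu[fam_index]) / 2.0,
            "parental_earnings": pairs.mother_earn[fam_index] + pairs.father_earn[fam_index],
            "mother_age_at_birth": mother_age,
            "father_age_at_birth": father_age,
        }
    )
    parents = pd.DataFrame(
        {
            "id": np.concatenate([[f"fam{f}_m" for f in range(n_fam)],
                                  [f"fam{f}_f" for f in range(n_fam)]]),
            "family_id": np.concatenate([fam_ids, fam_ids]),
            "family_index": np.concatenate([np.arange(n_fam)] * 2),
            "role": ["mother"] * n_fam + ["father"] * n_fam,
            "subpop": np.concatenate([pairs.subpop] * 2),
            "piv_raw": np.concatenate([pairs.mother_piv_raw, pairs.father_piv_raw]),
            "education_years": np.concatenate([pairs.mother_edu, pairs.father_edu]),
            "earnings": np.concatenate([pairs.mother_earn, pairs.father_earn]),
        }
    )
    return Population(
        config=config, seed=config.seed, panel=panel,
        offspring=offspring, parents=parents,
        geno_offspring=geno, geno_mother=pairs.geno_mother, geno_father=pairs.geno_father,
    )


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def _subpop_offsets(spread: float, k: int) -> np.ndarray:
    if k == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, k) * (spread / 2.0)


def generate_schooling(population: Population, config: SimConfig, rng: np.random.Generator) -> None:
    """Assign integer years of schooling in [6, 23] (in place).

    The latent index centers the true genetic score empirically so the cohort
    mean stays near 13 years regardless of allele-frequency draws.
    """
    off = population.offspring
    t_score = population.geno_offspring.astype(float) @ population.panel.true_schooling_effect
    t_score = t_score - t_score.mean()
    resp = 1.0 + config.hetero_on_first_stage * off["gain_modifier"].to_numpy()
    latent = (
        13.0
        + resp * t_score
        + config.ability_on_schooling * off["ability"].to_numpy()
        + config.dynastic_on_schooling * off["midparent_piv_std"].to_numpy()
        + _subpop_offsets(config.subpop_schooling_offset, config.n_subpops)[off["subpop"].to_numpy()]
        + rng.normal(0.0, config.schooling_noise_sd, size=len(off))
    )
    off["schooling_years"] = np.clip(np.round(latent), SCHOOL_MIN, SCHOOL_MAX).astype(int)


def generate_earnings_panel(population: Population, config: SimConfig, rng: np.random.Generator) -> None:
    """Assign the age 17-62 earnings matrix (in place).

    Earnings are zero before labor-market entry (age = schooling + 7) and
    log-normal afterwards, with a concave potential-experience profile. The
    individual return is ``beta_true`` plus the gain-modifier and sex terms.
    """
    if config.mincer_curvature < 0:
        raise ConfigurationError("mincer_curvature must be >= 0 (concave profile)")
    off = population.offspring
    if "schooling_years" not in off:
        raise InputError("schooling must be generated before the earnings panel")
    n = len(off)
    s = off["schooling_years"].to_numpy()
    beta_i = (
        config.beta_true
        + config.hetero_kappa * off["gain_modifier"].to_numpy()
        + config.sex_return_gap * off["sex"].to_numpy()
    )
    pleio = population.geno_offspring.astype(float) @ population.panel.true_direct_effect
    pleio = pleio - pleio.mean()
    person = (
        beta_i * s
        + config.ability_on_earnings * off["ability"].to_numpy()
        + config.dynastic_on_earnings * off["midparent_piv_std"].to_numpy()
        + pleio
        + _subpop_offsets(config.subpop_earnings_offset, config.n_subpops)[off["subpop"].to_numpy()]
        + rng.normal(0.0, config.earnings_person_sd, size=n)
    )
    x = AGES[None, :] - (s[:, None] + ENTRY_LAG)  # potential experience
    logy = (
        config.mincer_intercept
        + person[:, None]
        + config.mincer_slope * x
        - config.mincer_curvature * x ** 2
        + rng.normal(0.0, config.earnings_noise_sd, size=(n, len(AGES)))
    )
    y = np.exp(logy)
    y[x < 0] = 0.0
    population.earnings = y


def simulate_population(config: SimConfig) -> Population:
    """Run the full generator: panel, parents, transmission, phenotypes."""
    rng = np.random.default_rng(config.seed)
    panel = draw_snp_panel(config, rng)
    pairs = simulate_parent_pairs(config, panel, rng)
    pop = _assemble_offspring(config, panel, pairs, rng)
    generate_schooling(pop, config, rng)
    generate_earnings_panel(pop, config, rng)
    return pop
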