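"""Simulation configuration for the family-genetics + earnings-panel generator.

The configuration gathers every knob of the data-generating process: the SNP
panel, the strength of the polygenic instrument's first stage, the causal
return to a year of schooling, and the confounding channels (individual
ability, dynastic/genetic-nurture effects, assortative mating, population
stratification, pleiotropy, heterogeneous returns) whose consequences the
estimator suite is designed to expose or remove.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    # population structure
    n_families: int = 5000
    #: probabilities of 1, 2 or 3 offspring per family
    offspring_dist: tuple[float, float, float] = (0.40, 0.45, 0.15)
    #: probability that a family's first two offspring are a twin pair
    twin_prob: float = 0.02
    #: probability that a twin pair is monozygotic (rest dizygotic)
    mz_share: float = 0.5

    # genetics
    n_snps: int = 335
    allele_freq_range: tuple[float, float] = (0.10, 0.90)
    #: SD of the raw per-allele schooling effects before rescaling to pi
    snp_effect_sd: float = 1.0
    #: sampling SE of the published discovery-GWAS per-allele effects
    #: (years/allele); the default emulates a multi-million-sample discovery
    discovery_gwas_se: float = 0.0022
    #: stratification contamination of the published weights: component of the
    #: weight proportional to the between-subpopulation allele-frequency
    #: contrast, emulating a discovery GWAS confounded by stratification
    weight_strat_contamination: float = 0.0

    # causal structure
    #: return per year of schooling, log-earnings units
    beta_true: float = 0.08
    #: years of schooling per 1 SD of the polygenic instrument
    pi_first_stage: float = 0.26

    # individual-level (non-shared) confounding
    ability_sd: float = 1.0
    ability_on_schooling: float = 0.0
    ability_on_earnings: float = 0.0

    # dynastic ("genetic nurture") channel: loadings on standardized
    # mid-parental polygenic score
    dynastic_on_schooling: float = 0.0
    dynastic_on_earnings: float = 0.0

    #: target spousal polygenic-score correlation, [0, 1)
    rho_assortative: float = 0.0

    # population stratification
    n_subpops: int = 1
    #: maximum allele-frequency offset between extreme subpopulations
    subpop_freq_offset: float = 0.0
    #: schooling-years offset between extreme subpopulations
    subpop_schooling_offset: float = 0.0
    #: log-earnings intercept offset between extreme subpopulations
    subpop_earnings_offset: float = 0.0
    #: orient subpop frequency offsets along the schooling-increasing allele
    #: (classic stratification confounding); False draws random orientations
    subpop_align_effects: bool = True

    # pleiotropy (direct SNP -> earnings effects, exclusion violations)
    pleio_fraction: float = 0.0
    pleio_effect_sd: float = 0.0
    #: directional component, aligned with the schooling-increasing allele
    pleio_effect_mean: float = 0.0

    # heterogeneous returns
    #: loading of the latent gain modifier on the individual return beta_i
    hetero_kappa: float = 0.0
    #: loading of the same latent on first-stage responsiveness (compliers)
    hetero_on_first_stage: float = 0.0
    #: extra return per year of schooling for women (log points)
    sex_return_gap: float = 0.0

    # Mincer earnings profile: log y = intercept + slope*x - curvature*x^2 + ...
    # slope/curvature are calibrated jointly so that (i) age-specific returns
    # turn positive near age 27 (slope - beta = 2*curvature*(27-20)) and (ii)
    # the experience term is orthogonal to schooling in the prime-age window
    # (slope = 2*curvature*(30 - E[S])), making prime-age earnings identify
    # beta_true
    mincer_intercept: float = 11.5
    mincer_slope: float = 0.136
    mincer_curvature: float = 0.004

    # noise
    schooling_noise_sd: float = 2.5
    earnings_noise_sd: float = 0.30
    #: persistent individual component of log earnings
    earnings_person_sd: float = 0.20

    # parental phenotypes (dynastic channel source, covariates)
    parent_edu_piv_loading: float = 0.8
    parent_edu_noise_sd: float = 2.3
    parent_earn_edu_loading: float = 0.06
    parent_earn_noise_sd: float = 0.5

    # genotyped ("cohort-participation") subsample, decided at family level
    genotyped_family_prob: float = 0.35
    #: logit loading of family inclusion on standardized log parental earnings
    genotyped_selection_on_parental_earnings: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.offspring_dist = tuple(float(p) for p in self.offspring_dist)
        self.allele_freq_range = tuple(float(f) for f in self.allele_freq_range)
        self.validate()

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be a positive integer")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(
                f"allele_freq_range must satisfy 0 < lo < hi < 1, got ({lo}, {hi})"
            )
        if abs(sum(self.offspring_dist) - 1.0) > 1e-8 or min(self.offspring_dist) < 0:
            raise ConfigurationError("offspring_dist must be a probability vector over {1,2,3}")
        if not 0.0 <= self.twin_prob <= 1.0 or not 0.0 <= self.mz_share <= 1.0:
            raise ConfigurationError("twin_prob and mz_share must lie in [0, 1]")
        if not 0.0 <= self.pleio_fraction <= 1.0:
            raise ConfigurationError("pleio_fraction must lie in [0, 1]")
        if not 0.0 <= self.rho_assortative < 1.0:
            raise ConfigurationError("rho_assortative must lie in [0, 1)")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if self.mincer_curvature < 0:
            raise ConfigurationError("mincer_curvature must be >= 0 (concave profile)")
        for name in (
            "snp_effect_sd", "discovery_gwas_se", "ability_sd", "pleio_effect_sd",
            "schooling_noise_sd", "earnings_noise_sd", "earnings_person_sd",
            "parent_edu_noise_sd", "parent_earn_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.genotyped_family_prob <= 1.0:
            raise ConfigurationError("genotyped_family_prob must lie in [0, 1]")

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offspring_dist"] = list(self.offspring_dist)
        d["allele_freq_range"] = list(self.allele_freq_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


#: Named scenario presets. "null" switches every confounding channel off and is
#: the parameter-recovery benchmark; the others switch on exactly the channel
#: whose consequences a given estimator is meant to expose or remove.
_PRESETS: dict[str, dict] = {
    "null": {},
    "individual_confounding": {
        "ability_on_schooling": 0.8,
        "ability_on_earnings": 0.15,
    },
    "family_confounding": {
        "dynastic_on_schooling": 0.30,
        "dynastic_on_earnings": 0.05,
        "rho_assortative": 0.40,
    },
    "stratified_weights": {
        "n_subpops": 2,
        "subpop_freq_offset": 0.05,
        "subpop_align_effects": False,
        "subpop_schooling_offset": 0.50,
        "subpop_earnings_offset": 0.02,
        "weight_strat_contamination": 0.5,
    },
    "pleiotropy_balanced": {
        "pleio_fraction": 0.40,
        "pleio_effect_sd": 0.004,
    },
    "pleiotropy_directional": {
        "pleio_fraction": 0.30,
        "pleio_effect_sd": 0.001,
        "pleio_effect_mean": 0.006,
    },
    "heterogeneous_returns": {
        "hetero_kappa": 0.02,
        "hetero_on_first_stage": 0.30,
    },
    "paper_like": {
        "ability_on_schooling": -0.80,
        "ability_on_earnings": 0.15,
        "dynastic_on_schooling": 0.50,
        "dynastic_on_earnings": 0.015,
        "rho_assortative": 0.30,
        "pleio_fraction": 0.20,
        "pleio_effect_sd": 0.001,
        "pleio_effect_mean": 0.002,
        "hetero_kappa": 0.015,
        "hetero_on_first_stage": 0.30,
        "sex_return_gap": 0.02,
    },
}


def preset(name: str, **overrides) -> SimConfig:
    """Return a named scenario configuration, optionally overridden."""
    if name not in _PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return SimConfig(**kw)


def preset_names() -> list[str]:
    return sorted(_PRESETS)
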