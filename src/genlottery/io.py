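"""Readers and writers for the package's tabular interchange formats.

Genotypes export to a PLINK ``.raw``-style additive table, score weights to
the 3-column PLINK score format, SNP summaries to a tab-delimited GWAS
summary-statistics table, and earnings panels to long-format TSV. Sample
tables round-trip through TSV with a stable column schema so the CLI can
operate on files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AnalysisSample
from .simulate import Population, SNPPanel
from .summary_mr import SUMMARY_COLUMNS


def write_plink_raw(population: Population, path) -> None:
    """Offspring genotypes as a PLINK .raw-style additive coding table."""
    off = population.offspring
    panel = population.panel
    cols = {
        "FID": off["family_id"].to_numpy(),
        "IID": off["id"].to_numpy(),
        "PAT": off["father_id"].to_numpy(),
        "MAT": off["mother_id"].to_numpy(),
        "SEX": np.where(off["sex"].to_numpy() == 1, 2, 1),  # PLINK: 1=male 2=female
        "PHENOTYPE": -9,
    }
    df = pd.DataFrame(cols)
    geno = pd.DataFrame(
        population.geno_offspring,
        columns=[f"{sid}_{ea}" for sid, ea in zip(panel.ids, panel.effect_allele)],
    )
    pd.concat([df, geno], axis=1).to_csv(path, sep="\t", index=False)


def write_score_file(panel: SNPPanel, path, weights=None) -> None:
    """3-column PLINK score format: variant id, effect allele, weight."""
    w = panel.score_weight if weights is None else weights
    pd.DataFrame({"snp": panel.ids, "ea": panel.effect_allele, "weight": w}) \
        .to_csv(path, sep="\t", index=False, header=False)


def read_score_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["snp", "effect_allele", "weight"])
    df["weight"] = df["weight"].astype(float)
    return df


def write_summary_stats(summary: pd.DataFrame, path) -> None:
    summary[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics table missing columns: {sorted(missing)}")
    return df


def write_long_panel(population: Population, path) -> None:
    """Earnings panel in long format: id, age, earnings."""
    ids = population.offspring["id"].to_numpy()
    n, a = population.earnings.shape
    pd.DataFrame({
        "id": np.repeat(ids, a),
        "age": np.tile(population.ages, n),
        "earnings": population.earnings.ravel(),
    }).to_csv(path, sep="\t", index=False)


_SAMPLE_META = ["id", "family_id", "family_index", "zygosity", "birth_year",
                "birth_order", "subpop", "schooling_years", "earnings_prime",
                "log_earnings", "parental_earnings"]


def write_sample_table(sample: AnalysisSample, path) -> None:
    cols = [c for c in _SAMPLE_META if c in sample.df.columns]
    cols += [c for c in sample.covariate_names if c not in cols]
    for extra in ("piv_std", "piv_raw", "piv_fgwas"):
        if extra in sample.df.columns:
            cols.append(extra)
    sample.df[cols].to_csv(path, sep="\t", index=False)


def read_sample_table(path, label: str | None = None) -> AnalysisSample:
    df = pd.read_csv(path, sep="\t")
    from .cohort import DEFAULT_COVARIATES

    covs = [c for c in DEFAULT_COVARIATES if c in df.columns]
    return AnalysisSample(label=label or Path(path).stem, df=df, covariate_names=covs)


def write_fgwas_weights(weights, score_path, se_path=None, panel: SNPPanel | None = None) -> None:
    """FGWAS weights in PLINK score format plus a companion SE table."""
    if panel is not None:
        alleles = dict(zip(panel.ids, panel.effect_allele))
        ea = [alleles.get(s, "A") for s in weights.snp]
    else:
        ea = ["A"] * len(weights.snp)
    pd.DataFrame({"snp": weights.snp, "ea": ea, "weight": weights.estimate}) \
        .to_csv(score_path, sep="\t", index=False, header=False)
    if se_path is not None:
        weights.to_frame().to_csv(se_path, sep="\t", index=False)
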