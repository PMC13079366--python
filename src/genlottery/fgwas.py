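"""Within-sibling family-based GWAS (FGWAS) and re-weighted instrument.

Per-SNP schooling effects are re-estimated from within-sibship genotype
variation only (family fixed effects), which is free of family-level
confounding channels (dynastic effects, assortative mating, stratification
absorbed into published discovery weights). The resulting weights build a
new polygenic instrument on a *disjoint* unrelated estimation sample —
discovery/estimation separation is enforced structurally by a family-id
intersection check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AnalysisSample
from .regress import EstimationError, demean_within, factorize_clusters


@dataclass
class FGWASWeights:
    """Per-SNP within-family effect estimates (years per effect allele)."""

    snp: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    n_sibships: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"SNP": self.snp, "BETA": self.estimate, "SE": self.se})


def within_family_snp_effects(sibling_sample: AnalysisSample) -> FGWASWeights:
    """Family-fixed-effects GWAS of schooling, one SNP at a time.

    SNPs with no within-family genotype variation anywhere are omitted (not
    zero-filled). Standard errors are clustered by family.
    """
    if sibling_sample.genotypes is None:
        raise EstimationError("FGWAS needs a genotyped sibling sample")
    fam = factorize_clusters(sibling_sample.df["family_index"].to_numpy())
    sizes = np.bincount(fam)
    if (sizes < 2).any():
        # singletons carry no within-family information; they demean to zero
        pass
    G = sibling_sample.genotypes.astype(float)
    s = sibling_sample.df["schooling_years"].to_numpy(dtype=float)
    Gw = demean_within(G, fam)
    sw = demean_within(s, fam)

    gg = np.einsum("ij,ij->j", Gw, Gw)
    usable = gg > 1e-12
    if not usable.any():
        raise EstimationError("no SNP has within-family variation (MZ-only input?)")
    if not usable.all():
        warnings.warn(f"omitting {int((~usable).sum())} SNPs without within-family variation")
    idx = np.flatnonzero(usable)
    beta = (Gw[:, idx].T @ sw) / gg[idx]

    # per-SNP cluster(family)-robust sandwich
    n = len(sw)
    n_fam = int(fam.max()) + 1
    resid = sw[:, None] - Gw[:, idx] * beta[None, :]
    scores = np.zeros((n_fam, len(idx)))
    np.add.at(scores, fam, Gw[:, idx] * resid)
    meat = np.sum(scores ** 2, axis=0)
    k_eff = 1 + n_fam
    corr = (n_fam / max(n_fam - 1, 1)) * ((n - 1) / max(n - k_eff, 1))
    se = np.sqrt(corr * meat) / gg[idx]

    return FGWASWeights(
        snp=sibling_sample.panel.ids[idx] if sibling_sample.panel is not None
        else np.array([f"snp{j}" for j in idx]),
        estimate=beta,
        se=se,
        n_sibships=int((sizes >= 2).sum()),
    )


def build_fgwas_piv(estimation_sample: AnalysisSample, weights: FGWASWeights,
                    discovery_family_ids=None) -> np.ndarray:
    """Standardized polygenic score from FGWAS weights on a disjoint sample.

    ``discovery_family_ids``: family ids of the FGWAS discovery sibships; any
    overlap with the estimation sample's families is a hard error. The score
    uses only the SNPs that survived the FGWAS and is standardized within the
    estimation sample. The result is also stored in the sample's frame as
    ``piv_fgwas``.
    """
    if discovery_family_ids is not None:
        overlap = set(estimation_sample.df["family_id"]) & set(discovery_family_ids)
        if overlap:
            raise EstimationError(
                f"discovery/estimation families overlap (e.g. {sorted(overlap)[:3]})"
            )
    if estimation_sample.genotypes is None or estimation_sample.panel is None:
        raise EstimationError("estimation sample has no genotypes")
    panel_ids = list(estimation_sample.panel.ids)
    cols = [panel_ids.index(sid) for sid in weights.snp]
    raw = estimation_sample.genotypes[:, cols].astype(float) @ weights.estimate
    sd = raw.std()
    if sd <= 0:
        raise EstimationError("FGWAS-weighted score is constant")
    piv = (raw - raw.mean()) / sd
    estimation_sample.df["piv_fgwas"] = piv
    return piv
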