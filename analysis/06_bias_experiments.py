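"""Bias-demonstration grid: which estimator fails under which channel.

Three planted-confounding scenarios, one estimator repair each:
  * individual-level ability confounding biases OLS; MR is immune;
  * dynastic effects + assortative mating bias population MR; sibling-MR
    (within-family instrument variation) recovers the truth;
  * stratification absorbed into the published score weights biases
    population MR; re-estimating the weights in a within-sibling FGWAS and
    scoring a disjoint unrelated sample recovers the truth.
"""

from pathlib import Path

import pandas as pd

import genlottery as gl
from genlottery.estimators import ModelSpec

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
BETA = 0.08
rows = []


def record(scenario, model, res):
    rows.append({"scenario": scenario, "model": model, "beta": res.beta,
                 "se": res.se, "bias": res.beta - BETA,
                 "bias_in_se": (res.beta - BETA) / res.se})


cfg = gl.preset("individual_confounding", n_families=12000, seed=7,
                genotyped_family_prob=1.0)
samples, _ = gl.build_samples(gl.simulate_population(cfg))
record("individual_confounding", "ols", gl.fit_ols(samples["full"], ModelSpec()))
record("individual_confounding", "mr",
       gl.fit_tsls(samples["genotyped"], ModelSpec(instrument="piv_std")))

cfg = gl.preset("family_confounding", n_families=12000, seed=8,
                offspring_dist=(0.0, 1.0, 0.0), twin_prob=0.0,
                genotyped_family_prob=1.0)
samples, _ = gl.build_samples(gl.simulate_population(cfg))
record("family_confounding", "population_mr",
       gl.fit_tsls(samples["genotyped"], ModelSpec(instrument="piv_std")))
record("family_confounding", "sibling_mr",
       gl.fit_sibling_mr(samples["genotyped_sibling"], ModelSpec(instrument="piv_std")))

cfg = gl.preset("stratified_weights", n_families=12000, seed=9,
                offspring_dist=(0.20, 0.65, 0.15), genotyped_family_prob=1.0)
samples, _ = gl.build_samples(gl.simulate_population(cfg))
record("stratified_weights", "population_mr",
       gl.fit_tsls(samples["genotyped"], ModelSpec(instrument="piv_std")))
sib = samples["genotyped_sibling"]
w = gl.within_family_snp_effects(sib)
unrel = samples["genotyped_unrelated"]
gl.build_fgwas_piv(unrel, w, discovery_family_ids=sib.df["family_id"].unique())
record("stratified_weights", "fgwas_mr",
       gl.fit_tsls(unrel, ModelSpec(instrument="piv_fgwas")))
record("stratified_weights", "sibling_mr",
       gl.fit_sibling_mr(sib, ModelSpec(instrument="piv_std")))

grid = pd.DataFrame(rows)
grid.to_csv(OUT / "bias_grid.csv", index=False)
print(grid.to_string(index=False))
print("\n|bias| > 3 SE marks a broken estimator; the paired repair sits within noise.")
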