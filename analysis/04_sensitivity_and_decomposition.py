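"""Exclusion-violation sensitivity (UCI) and the IV-OLS gap decomposition.

The UCI analysis asks how large a direct (pleiotropic) effect of the
instrument on earnings would have to be before the MR estimate loses
statistical significance, reported both in outcome units and as a share of
the reduced-form association. The decomposition splits the MR-OLS gap into
covariate-weighting, schooling-margin-weighting and residual (confounding +
complier-averaging) components, and the non-negativity of the IV weights is
the monotonicity check.
"""

import json
from pathlib import Path

import genlottery as gl
from genlottery.estimators import ModelSpec

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = gl.preset("paper_like", n_families=15000, seed=42, twin_prob=0.05,
                genotyped_family_prob=0.5)
samples, _ = gl.build_samples(gl.simulate_population(cfg))
gs = samples["genotyped"]

curve = gl.uci_sensitivity(gs, ModelSpec(outcome="abs", instrument="piv_std"),
                           n_grid=81)
curve.to_frame().to_csv(OUT / "uci_sensitivity_curve.csv", index=False)
share = gl.breakdown_share(curve.breakdown_delta, curve.reduced_form_beta)
print(f"Reduced-form association: NOK {curve.reduced_form_beta:,.0f} per SD of the score")
print(f"Breakdown direct effect: NOK {curve.breakdown_delta:,.0f} "
      f"({share}% of the reduced form) before the MR estimate loses significance")

d = gl.decompose_gap(gs, ModelSpec(outcome="log", instrument="piv_std"))
mono = gl.monotonicity_check(d)
d.margin_weights_ols.to_frame().join(d.margin_weights_iv).to_csv(
    OUT / "margin_weights.csv")
payload = {
    "theta_iv": d.theta_iv, "theta_ols": d.theta_ols, "gap": d.gap,
    "covariate_component": d.covariate_component,
    "margin_component": d.margin_component,
    "residual_component": d.residual_component,
    "component_shares_pct": d.component_shares,
    "monotonicity": mono,
}
(OUT / "decomposition.json").write_text(json.dumps(payload, indent=2, default=float))
print(f"\nMR-OLS gap {d.gap:+.4f} log points; shares of |gap| — "
      f"residual (confounding + complier averaging): {d.component_shares['residual']:.1f}%, "
      f"margins: {d.component_shares['margin']:.1f}%, "
      f"covariates: {d.component_shares['covariate']:.1f}%")
print(f"Monotonicity check (all IV weights >= 0): "
      f"{'pass' if mono['pass'] else 'FAIL ' + str(mono['offending_strata'])}")
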