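"""Probe the MR identifying assumptions and the power of the checks.

Two cohorts: one where the polygenic instrument is valid (all exclusion/
independence violations off), where every diagnostic should come back clean,
and one with planted directional pleiotropy, where the exclusion checks
should light up (IVW drifts, the Egger intercept turns significant) while
the pleiotropy-robust estimators stay near the truth.

Relevance: first-stage partial F. Independence: between- vs within-family
instrument-covariate balance. Exclusion: IVW + Cochran's Q, MR-Egger with
intercept test, weighted median, weighted/simple mode, core-gene trajectory,
leave-one-out screening.
"""

import json
from pathlib import Path

import pandas as pd

import genlottery as gl
from genlottery.estimators import ModelSpec

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def suite(summ, tag):
    rows = []
    for name, res in [
        ("ivw", gl.ivw(summ)),
        ("egger", gl.egger(summ)),
        ("weighted_median", gl.weighted_median(summ, n_boot=400, rng=1)),
        ("weighted_mode", gl.mode_estimator(summ, n_boot=200, rng=2)),
        ("simple_mode", gl.mode_estimator(summ, weighted=False, n_boot=200, rng=3)),
        ("corge", gl.corge(summ)),
    ]:
        rows.append({"scenario": tag, "method": name, "estimate": res.estimate,
                     "se": res.se, "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "Q": res.Q, "egger_intercept": res.egger_intercept,
                     "egger_intercept_se": res.egger_intercept_se})
    return pd.DataFrame(rows)


payload = {}
tables = []
for tag, preset in (("valid_instrument", "null"),
                    ("directional_pleiotropy", "pleiotropy_directional")):
    cfg = gl.preset(preset, n_families=15000, seed=42, genotyped_family_prob=1.0)
    samples, _ = gl.build_samples(gl.simulate_population(cfg))
    gs = samples["genotyped"]

    mr = gl.fit_tsls(gs, ModelSpec(instrument="piv_std"))
    between, joint_b = gl.balance_test(gs)
    within, joint_w = gl.balance_test(samples["genotyped_sibling"], within_family=True)
    between.assign(scope="between", scenario=tag).to_csv(
        OUT / f"balance_between_{tag}.csv", index=False)
    within.assign(scope="within", scenario=tag).to_csv(
        OUT / f"balance_within_{tag}.csv", index=False)

    summ = gl.per_snp_associations(gs)
    tab = suite(summ, tag)
    tables.append(tab)
    loo = gl.leave_one_out(summ)

    payload[tag] = {
        "first_stage_years_per_sd": mr.first_stage_beta,
        "first_stage_partial_F": mr.F_first_stage,
        "balance_joint_between": joint_b, "balance_joint_within": joint_w,
        "loo_flagged": int(loo["flagged"].sum()),
        "egger_intercept_z": float(tab.loc[tab.method == "egger", "egger_intercept"].iloc[0]
                                   / tab.loc[tab.method == "egger", "egger_intercept_se"].iloc[0]),
        "individual_level_mr": mr.beta,
    }
    print(f"[{tag}] F={mr.F_first_stage:.0f}, 2SLS={mr.beta:.4f}, "
          f"Egger intercept z={payload[tag]['egger_intercept_z']:.1f}, "
          f"LOO flags={payload[tag]['loo_flagged']}")

full = pd.concat(tables, ignore_index=True)
full.to_csv(OUT / "summary_mr_suite.csv", index=False)
(OUT / "assumption_checks.json").write_text(json.dumps(payload, indent=2, default=float))
print("\n" + full.to_string(index=False))
print("\nReading: with a valid instrument the intercept z is ~0 and all "
      "estimators agree; under planted directional pleiotropy IVW drifts "
      "upward while Egger (slope), median and core-gene stay near 0.08 and "
      "the intercept test detects the violation. Mode-based estimates are "
      "the noisiest of the suite.")
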