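"""Age-specific returns over the working life and the internal rate of return.

Returns are negative through the 20s (schooling delays entry and forgoes
earnings and experience), cross zero near the configured crossover age, and
grow through the career. Lifetime returns are the undiscounted average of
the age-specific profile; the IRR is the discount rate equating life-cycle
costs and benefits, compared with a 2.3% real market rate.
"""

from pathlib import Path

import pandas as pd

import genlottery as gl

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = gl.preset("paper_like", n_families=15000, seed=42, twin_prob=0.05,
                genotyped_family_prob=0.5)
samples, _ = gl.build_samples(gl.simulate_population(cfg))

rows = []
for est, sample, ages in (("ols", samples["full"], range(17, 63)),
                          ("mr", samples["genotyped"], range(17, 53))):
    prof = gl.age_specific_returns(sample, est, ages=ages)
    prof.to_csv(OUT / f"age_profile_{est}.csv", index=False)
    irr = gl.internal_rate_of_return(prof)
    rows.append({
        "estimator": est,
        "first_positive_age": int(prof[prof["beta"] > 0]["age"].min()),
        "lifetime_return_nok": gl.lifetime_return(prof),
        "irr_pct": 100 * irr.irr,
        "beats_market_rate": irr.profitable,
    })
summary = pd.DataFrame(rows)
summary.to_csv(OUT / "lifecycle_summary.csv", index=False)
print(summary.to_string(index=False))
print("\nEducation pays off over the life cycle whenever the IRR exceeds the "
      "2.3% real market rate.")
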