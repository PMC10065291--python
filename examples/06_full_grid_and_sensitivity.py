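"""The full analysis grid and the sensitivity-variant suite.

Outcomes (cardiovascular lag 5, respiratory lag 10) x population strata
(all, sex, age, older-by-sex) x heat-wave percentiles, then the variant grid
(quadratic b-spline lags, df 3/5, alternative lag lengths, humidity removed,
temperature cross-basis added) on a small synthetic world.
"""

import pandas as pd

import heatlag as hl
from heatlag import pipeline

pd.set_option("display.width", 160)

sim = hl.SimConfig(n_subjects=2000, years=(2012, 2013, 2014),
                   baseline_daily_hazard=2e-3, missing_rate=0.02, seed=7)
cfg = pipeline.RunConfig(sim=sim, percentiles=(90.0, 95.0))

results, desc = pipeline.run(cfg)
fitted = results[results["error"] == ""]
print(f"{len(fitted)}/{len(results)} cells fitted")
cols = ["outcome", "stratum", "percentile", "or", "ci_low", "ci_high",
        "n_strata"]
print(fitted[cols].round(3).to_string(index=False))
print("\nstudy-population descriptives (counts, % by sex/age; weather "
      "mean/sd in the hot season):")
print(desc.to_string(index=False))

sens = pipeline.sensitivity_suite(
    cfg.replace(strata_specs=("all",), percentiles=(90.0,))
)
ok = sens[sens["error"] == ""]
print("\nsensitivity variants (pooled, 90th percentile):")
print(ok[["outcome", "variant", "or", "ci_low", "ci_high"]]
      .round(3).to_string(index=False))
print("(cumulative ORs should move little across variants — the lag basis "
      "and adjustment-set choices are not doing the work)")
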