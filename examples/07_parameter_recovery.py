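"""Monte-Carlo check: does the estimator recover the injected effect?

Each replicate simulates a fresh world with a cumulative OR of 1.30 for
heat waves at the 90th-percentile definition, fits the full matched-set
model, and records the cumulative OR and its 95% interval. (The acceptance
script runs 100 replicates; 10 keep this example quick.)
"""

import heatlag as hl

df = hl.parameter_recovery(n_replicates=10, true_or=1.3, seed=2024)
print(df[["or", "ci_low", "ci_high", "covers_truth", "n_deaths"]]
      .round(3).to_string(index=False))
print(f"\nmedian OR: {df['or'].median():.3f} (truth 1.30)")
print(f"CI coverage: {df['covers_truth'].mean():.0%} "
      f"(should be near 95% in a long run)")
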