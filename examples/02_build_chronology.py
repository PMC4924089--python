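"""From otolith tables to an environment-aligned growth table.

Simulates fish whose log increment width declines with age and responds to
the previous day's temperature, applies the three-count aging rule,
back-dates every increment from the capture date, standardises growth
within each post-settlement age group (GI_s = GI_w / GI_m), and joins each
fish-day to its reef's daily environment at a one-day lag.
"""

import otogrowth as og

env = og.daily_summaries(og.simulate_environment(og.EnvSimConfig(rng_seed=7)))
profiles = og.simulate_otoliths(
    env, og.GrowthSimConfig(beta_temperature=-0.07, rng_seed=8)
)

aligned, report = og.build_chronology(profiles, env, lag_days=1, max_age=14)
print("bookkeeping:", report)
print("\nFirst rows of the aligned growth table:")
cols = ["fish_id", "age", "growth_date", "gi_w", "gi_s", "temperature", "tide"]
print(aligned[cols].head(6).to_string(index=False))

per_age = aligned.groupby("age")["gi_s"].mean()
print(f"\nmean GI_s by age: min {per_age.min():.12f}, max {per_age.max():.12f}")
print(
    "The standardised index averages to exactly 1 within every age group, "
    "removing the intrinsic age-related width decline before any modelling."
)

rel = og.somatic_relationship(profiles)
for k, v in rel.items():
    print(f"standard length ~ {k}: r^2 = {v['r_squared']:.3f}")
print("Otolith size tracks somatic size, so otolith growth proxies fish growth.")
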