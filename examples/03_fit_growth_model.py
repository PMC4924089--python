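"""Infer which abiotic factors drive daily growth.

Mean-centres the four daily covariates, screens collinearity by VIF, ranks
all 16 fixed-effect subsets of a site+date random-intercept model by ML BIC,
refits the winner by REML, and confirms significance with a three-chain
Gibbs-sampled Bayesian regression (chains of 1000, burn-in 100, thinning 5).
"""

import otogrowth as og

env = og.daily_summaries(og.simulate_environment(og.EnvSimConfig(rng_seed=7)))
profiles = og.simulate_otoliths(
    env, og.GrowthSimConfig(beta_temperature=-0.07237, rng_seed=8)
)
aligned, _ = og.build_chronology(profiles, env)
centred, centres = og.centre_predictors(aligned)

print("VIF screen (collinearity is negligible in this world):")
print(og.vif_screen(centred).round(3).to_string(index=False))

sel = og.select_model_bic(centred)
print("\nTop of the BIC ranking (ML fits):")
print(sel.table.head(4).to_string(index=False))
print(f"\nselected subset: {sel.best_subset}")
fit = sel.best_fit
for name in fit.params.index:
    print(
        f"  {name:>12s}: estimate {fit.params[name]:+.5f} "
        f"(SE {fit.bse[name]:.5f}, p {fit.pvalues[name]:.2g})"
    )
print(f"  random-effect variances: {fit.vcomp}")

mcmc = og.gibbs_regress(centred, sel.best_subset, seed=99)
print("\nPosterior summary (3 chains x 180 retained draws):")
print(mcmc.summary.round(5).to_string())
print(
    "\nThe temperature coefficient is the per-degree change in standardised "
    "growth; its 95% credible interval excluding zero marks it significant "
    "(truth used by the generator: -0.07237 per degree C on log width)."
)
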