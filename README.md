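# otogrowth

Link high-frequency environmental sensor records to the daily growth of
juvenile reef fish, and classify how co-occurring abiotic stressors combine.

Coral-reef fish deposit one growth increment per day on their otoliths
(ear stones); the width of each increment proxies that day's somatic growth.
Given (a) 10-minute logger records of turbidity (NTU), temperature (°C) and
seabed pressure, and (b) per-fish otolith tables (replicate increment
counts, a settlement mark, and the ordered post-settlement increment
widths), `otogrowth` reconstructs dated per-fish growth chronologies,
infers which daily environmental factors drive growth, and tests whether
paired stressors act additively, synergistically or antagonistically.
It is aimed at sclerochronologists and reef ecologists who want the full
inference chain as a tested, reusable Python library; because raw field
data of this kind are rarely released, a first-class synthetic-data
generator with known ground truth makes every stage testable end to end.

## The analysis chain

1. **Sensor processing** — per 10-minute burst, wave action is the RMS
   deviation of the ten rapid pressure readings about their mean (metres;
   flat sea = 0) and depth is the calibrated burst mean. Per reef and
   calendar day: means of turbidity, temperature and wave RMS over all
   bursts of both loggers, and tidal range = max − min depth.
2. **Chronology** — ages are the mean of three replicate increment counts,
   accepted only when every count is within 10% of their median. With n
   post-settlement increments, the increment at age *a* formed on
   capture − (n − a) days. Because widths decline intrinsically with age,
   growth is standardised within each post-settlement age group:

       GI_s = GI_w / GI_m

   where GI_w is the individual increment width and GI_m the mean width of
   all fish at that age (so mean GI_s = 1 per age group by construction).
   Each fish-day, ages 1–14 only, is joined to its reef's daily environment
   at a one-day lag (food eaten on day t−1 becomes growth on day t).
3. **Growth model** — GI_s ~ turbidity + temperature + tide + waves with
   crossed random intercepts for site and date; predictors mean-centred,
   collinearity screened by VIF = 1/(1 − R²); all 16 fixed-effect subsets
   ranked by BIC = −2·logLik + k·log(n) from ML fits, winner refit by REML;
   significance assessed by a three-chain semi-conjugate Gibbs sampler
   (chain length 1000, burn-in 100, thinning 5 → 540 combined draws) with
   vague priors, reporting 95% credible intervals and split-chain R̂.
4. **Cumulative impacts** — for a covariate pair, fish-days outside the
   interquartile band are binned into four quartile-corner conditions; the
   corner the fitted signs predict to maximise growth is the control.
   Differences are tested by Monte-Carlo label permutation (omnibus F,
   add-one p, Holm-adjusted pairwise tests); Cohen's d (pooled SD, positive
   when growth is depressed) is computed per condition against control and

       d_combined ≈ d_A + d_B  → additive
       d_combined >  d_A + d_B → synergistic
       d_combined <  d_A + d_B → antagonistic

   at a configurable tolerance on the d scale (default 0.1).

## Worked example

```python
import otogrowth as og

env = og.daily_summaries(og.simulate_environment(og.EnvSimConfig(rng_seed=7)))
profiles = og.simulate_otoliths(
    env, og.GrowthSimConfig(beta_temperature=-0.07237, rng_seed=8)
)
aligned, _ = og.build_chronology(profiles, env)
centred, _ = og.centre_predictors(aligned)
sel = og.select_model_bic(centred)
print(sel.best_subset)
print(og.gibbs_regress(centred, sel.best_subset, seed=99).summary.round(5))
```

prints (abridged):

```
('temperature',)
                mean       sd   ci_2.5  ci_97.5  p_opposite_sign     rhat
intercept    0.99982  0.00421  0.99177  1.00810              0.0  0.99954
temperature -0.06889  0.00257 -0.07400 -0.06403              0.0  1.00621
sigma2       0.02242  0.00093  0.02078  0.02427              0.0  1.00404
```

BIC selection keeps temperature alone out of the four candidates, and the
posterior mean −0.069 (true generating effect −0.07237 per °C on log width)
has a credible interval well clear of zero: warmer days depress the
standardised growth index. The `examples/` directory walks through each
capability (sensor simulation, chronology building, model fitting,
cumulative-impact classification, and the one-call pipeline); each script
prints what it computes and says what the numbers mean.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates the three-reef
four-month world with a known negative temperature effect and a negative
temperature×tide interaction, runs every pipeline stage (daily summaries,
chronology, VIF, BIC selection, REML refit, Gibbs chains, cumulative-impact
classification for temperature/tide and temperature/waves), prints the
fitted summaries, and writes the results JSON plus a full run report next
to it.
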