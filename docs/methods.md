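# Methods

This note documents the models and procedures `otogrowth` implements, the
choices made where the design was genuinely open, what the synthetic world
does and does not emulate, and the known limitations those choices imply.

## Sensor processing

A burst is one 10-minute logger record: one turbidity and one temperature
value, and ten rapid pressure readings taken over ten seconds.

* **Wave action** is the root-mean-square *deviation* of the ten pressure
  readings about their burst mean, in metres, so a flat sea gives exactly
  zero. Plain RMS of the raw readings (which would include the standing
  depth) is a defensible alternative reading of "root-mean-square" but does
  not express *variation* in seabed pressure; deviation-from-mean is used.
* **Depth** is an affine calibration `scale·mean(p) + offset` of the burst
  mean (identity by default).
* **Daily summaries** pool all bursts of both loggers of a reef within a
  local calendar day: arithmetic means for turbidity, temperature and wave
  RMS, and `max − min` of burst depth for tidal range. Pooling equals
  averaging per-logger means whenever burst counts match. A constant depth
  offset between a reef's two loggers inflates the pooled range; an
  optional per-logger de-meaning flag removes it. Days keep whatever bursts
  exist (`n_bursts` is reported so short days can be filtered); service
  gaps simply leave days absent. No exclusion is applied around anti-fouling
  wiper events.

## Chronology

* **Aging rule**: three replicate increment counts are accepted when every
  count deviates from their median by at most 10% of the median; the
  assigned age is then the mean of the three. The rule is deliberately
  interpreted as *any count deviating by more than 10% of the median
  excludes the fish*.
* **Back-dating**: with n post-settlement increments and capture date C,
  the age-a increment formed on `C − (n − a)` days and settlement was
  `C − n` days. Ages are indexed from the settlement mark (age 1 = first
  increment *after* settlement; whether the settlement-day increment is
  counted is unknowable from the data, day-after is assumed). Larval
  (pre-settlement) increments are out of scope.
* **Standardised growth index**: GI_s = GI_w / GI_m with GI_m the mean
  width over the pooled population (all reefs) at that age — within every
  age group mean(GI_s) = 1 to machine precision. Per-reef stratification is
  available (`by="reef"`) but pooling is the default.
* **Alignment**: only ages 1–14 are retained (the reliable reading window;
  fish with fewer increments contribute what they have — truncation, not
  exclusion). Each row joins its own reef's daily summary at
  `growth_date − lag` (default lag 1 day, the assimilation delay); rows
  whose environmental day is missing are dropped and counted.

### A caution about the standardisation

Dividing by age-group means removes any component of the environmental
signal that is shared within an age group. When a covariate is close to a
linear function of calendar date (temperature in a seasonal decline) the
fitted coefficient is attenuated by roughly
`var(settlement date) / (var(settlement date) + var(age))`. With
settlement spread over months — as in the emulated study, where fish of a
wide range of ages were captured together — the factor is ≈ 0.97 and
negligible; with a settlement window comparable to the 14-day age window it
can shrink estimates by a third. Users applying the pipeline to cohorts
with narrow settlement windows should expect this.

## Growth model

Response GI_s; candidates turbidity, temperature, tide, waves, each
grand-mean-centred (centres returned so predictions can be mapped back).
VIF_k = 1/(1 − R²_k) from regressing candidate k on the others; the default
flag threshold is 5.

The linear mixed model has crossed random intercepts for site and calendar
growth date (date treated as an unordered factor, crossed with site), fit
via the variance-components formulation of statsmodels' `MixedLM` with one
all-encompassing group. Powell optimisation is used first because it
reliably reaches boundary (zero-variance) solutions, with a gradient-based
fallback. REML is used for reported estimates; **BIC comparisons across
fixed-effect subsets use ML refits**, since REML likelihoods are not
comparable across different fixed structures. BIC = −2·logLik + k·log(n)
with k counting fixed effects, the two variance components and the
residual variance; ties break toward fewer parameters. Satterthwaite
degrees of freedom are not available in the backend; t-tests use a
residual-df approximation (n − p), recorded in the fit metadata. A variance
component estimated at zero is reported with a `singular` flag and a
warning, not an error.

**Significance** is assessed, faithfully to the emulated chain, by a
*fixed-effects-only* Bayesian linear regression: semi-conjugate Gibbs
alternation of β | σ² (Normal; flat limit, prior precision 0) and
σ² | β (inverse-gamma with shape c0/2, scale d0/2; c0 = d0 = 0.001), three
chains of length 1000, burn-in 100, thinning 5 → 180 draws per chain, 540
combined. Per-parameter split-chain R̂ is reported and R̂ > 1.1 warns.
A coefficient is called significant when its 95% credible interval excludes
zero. Ignoring the random effects here reproduces the original analysis;
it makes the posterior intervals narrower than the mixed-model intervals
and should be read accordingly.

### Known limitation: no individual-level random effect

The model contains site and date intercepts but no fish-level term, again
mirroring the emulated analysis. Increment widths of the same fish are
correlated (individual condition, maternal effects); with realistic
individual dispersion (≈ 8% CV) the model's standard errors for
date-trending covariates are some 40% too small and nominal 95% intervals
cover at roughly 80%. The package's own acceptance suite measures exactly
this: point estimates and model selection are essentially unbiased (BIC
recovers the true driver in effectively every replicate), while the
frequentist coverage criterion fails — a real anti-conservatism of the
published inference chain, deliberately not patched. Treat the reported
intervals as population-level approximations, not fish-level inference.

## Cumulative impacts

For a covariate pair (A, B): 25th/75th percentile cut points (linear-
interpolation quantile definition — cut points shift slightly under other
definitions, which is why the definition is fixed and documented); rows
inside either interquartile band are discarded; the corner the fitted
coefficient signs predict to maximise growth is the control (positive sign
→ high quantile of that covariate). Observed fish-day rows populate the
cells — the model predicts only the orientation, not the growth values; a
fully model-predicted variant is intentionally not the default. An empty
cell raises an error naming the cell, since observational covariates need
not populate all corners. Rows are pooled across reefs.

The omnibus test permutes condition labels (one-way F statistic; permuting
the pooled values against fixed contiguous segments is equivalent and
vectorises well) with the add-one estimator p = (1 + #{perm ≥ obs})/(1 + B),
so p is never exactly zero; pairwise two-group permutation tests are
Holm-adjusted. Cohen's d uses the df-weighted pooled SD and is signed so
that a growth-depressing condition has positive d. Classification compares
d_combined with d_A + d_B at a tolerance (default 0.1 on the d scale;
exact equality has probability zero, and 0.1 matches the sampling error of
a d difference at a few hundred rows per cell). Because the literature
sometimes quotes the weaker comparison — combined versus the strongest
single effect — both are computed and reported; they are not harmonised.

## Synthetic world

The environment generator states the emulated regime directly: four months
(2 April – 2 August 2013) of 10-minute bursts, three reefs × two loggers;
temperature declining linearly 28.5 → 21 °C with a ±0.3 °C diurnal
sinusoid and AR(1) noise; depth = mean depth + two cosine tidal
constituents (periods 12.42 h and 12.00 h — their beat gives the ~14.8-day
spring–neap cycle) scaled per reef (defaults spanning roughly 0.9–4.4 m
daily range, macrotidal at the third reef); wave RMS = |AR(1)| scaled to a
0–0.16 m band; turbidity = 3 NTU baseline + Poisson-arrival events
(≈ 0.07/day) with exponential-mean 35 NTU amplitudes decaying at 0.6/day —
multi-day peaks over a low background — floored at zero. The two loggers
of a reef share the reef signal and differ by independent instrument
noise. Fixed seed ⇒ bit-identical streams.

The growth generator: log width = log(6 µm) − 0.03·(age−1) + Σ β_k·x̃_k at
lag 1 day + optional interaction terms + fish + site + date + residual
Gaussian noise (all on the log scale, so widths stay positive). Dispersion
defaults (chosen once as field-realistic): sd_individual 0.08, sd_site
0.03, sd_date 0.04, sd_residual 0.12. Settlement dates are uniform over
15 April – 15 July with capture on 1 August, matching a population captured
at a wide range of ages (and keeping the standardisation attenuation
negligible, see above). Replicate increment counts are
round(Normal(true age, 0.5)) — nearly every fish passes the 10% rule while
the exclusion path still fires at scale. Interactions are stated as a
log-width penalty applied on days when both covariates of a pair exceed
their series median: a crude but monotone way to state a synergistic or
antagonistic surface without the sign ambiguity of a centred product term.
Morphometrics (standard length, otolith length/width) are linear in total
age with noise sized from the realized signal variance to hit a target
r² (default 0.9).

The generator does **not** model food availability or ration (so
temperature×food mechanisms cannot be emulated), hydrodynamic or
sediment-transport physics, wave-driven resuspension coupling, pressure
attenuation with depth, or pre-settlement growth. A green test therefore
establishes that the *statistical chain* behaves as claimed under the
stated world — not that the stated world is a faithful ocean.

`simulate_condition_groups` states four-condition worlds directly on the
d scale (control mean 1.0, each individual effect depressing by d·sd, the
combined cell by (d_A + d_B + interaction_d)·sd, default 400 values per
cell): interaction_d = 0 is exactly additive, positive synergistic,
negative antagonistic.

## Numerical conventions

* Quantiles: linear interpolation throughout.
* Permutation ties count as exceedances (≥ obs − 1e-12).
* Degenerate inputs: constant response → all slopes and variances exactly
  zero; zero pooled variance → Cohen's d undefined (error); all-identical
  permutation input → p = 1; perfectly collinear covariate → VIF = ∞,
  flagged; rank-deficient Gibbs design → error.
* One master seed expands via `SeedSequence.spawn` into per-stage seeds
  (environment, fish, MCMC chains, permutations); all derived seeds are
  kept below 2³¹.
* All dates ISO-8601; units NTU, °C, m, µm as in the field.
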