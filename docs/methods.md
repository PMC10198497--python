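# Methods

## Model

Each agent is a woman with a fixed life course sampled at birth: ages at
menarche, each birth, menopause and death, plus an exposure profile
(BRCA1 carriage, a standard-normal polygenic score, BMI category,
drinks/year, smoking, oral-contraceptive start/stop ages, hormone-therapy
duration, screenings per seven years).  Ages live on an integer annual
grid; every life event happens at an integer age and the physiology
advances one year per step.

Breast tissue is a dense susceptible pool plus six ordered classes of
transformed tissue, all in abstract volume units; class 6 is malignant.
The dense pool is not rate-driven: it follows the deterministic
trajectory 0 before menarche, a constant baseline V₀ to menopause, a 5%
point drop at menopause, then −1% per completed year.  Each model year,
in order: (1) the dense pool is set from the trajectory; (2)
transformation fluxes are drawn from start-of-year volumes (influx to
class 1 at rate τ times the dense volume, class *k* → *k*+1 at τ·v_k, the
final step at τ_f·v₅), a Jacobi update so no volume transforms twice in
one year and transformed mass is conserved within the step; (3) each
class then scales by exp(growth − loss).  Growth for classes 1–5 is
g₀·a^(k−1) times the Pike life-stage multiplier (0 / 1 / 2.2 / 0.70 /
0.105; the attenuation a defaults to 1, i.e. equal rates); the malignant
class grows at its own rate g_mal, unconstrained by hormonal life stage.
Loss is λ₀ times a per-class profile falling linearly from 1.0 (class 1)
to 0.48 (class 5), with 0.25 for the malignant class, multiplied by 100
in breastfeeding years (the single year after each birth) and by a
calibrated late-age factor from a calibrated onset age — the mechanism
behind the old-age incidence downturn.  Detection occurs when the
malignant pool reaches θ_clin, or θ_screen < θ_clin in a year the woman
is screened; after detection she leaves the risk set.

In `stochastic` mode each transformation flux moves n·q volume with
n ~ Poisson(rate·source/q), q the clone quantum; growth/loss within the
year stays deterministic, preserving a branching-process character at
O(classes) cost per woman-year.  Volume arriving in the malignant class
is additionally treated as seeded at a uniform instant within the year,
so it carries only the remaining fraction of that year's growth; without
this, single-clone tumors — seeded with exactly one quantum on an integer
year and growing deterministically — would reach the detection threshold
on an integer time lattice, and windowed trial statistics would respond
to rate changes as coarse staircases.  For the same reason the engine
records, besides the integer detection age, the within-year fraction at
which the malignant pool crossed the clinical threshold (the pool grows
exponentially inside a year, so the instant is well defined); trial
windows classify cases on that fractional time, while screen detections
occur at the screening visit.  `mean_field` mode moves expected fluxes
unmodified.

With growth and loss off and small homogeneous rates the engine reduces
to the classical k-stage hazard (∏ rates)·t^(k−1)/(k−1)!; the test suite
verifies the log–log slope of 5 for six steps, shifting to 4 as the
final step becomes instantaneous, and checks the annual-step engine
against an exact continuous-time event-driven simulator on a two-class
toy system (Kolmogorov–Smirnov agreement of first-passage times).

### Why calibration runs in stochastic mode

Detection is a threshold crossing.  In mean-field mode every woman's
outcome is then deterministic, and population onset dispersion comes
only from attribute heterogeneity — far too narrow to produce a
registry-like incidence curve (detection fractions collapse toward 0 or
1).  The Poisson clone noise *is* the model's source of onset
dispersion, so calibrations, trials and population runs all use the
stochastic engine.  To keep 1-D root finding well behaved, the Poisson
draws are implemented as the Poisson quantile function applied to
uniforms keyed by (seed, age, individual): counterfactual arms share
randomness exactly (a nullified intervention reproduces its control arm
bit-for-bit) and drawn counts respond monotonically to rate changes —
the common-random-numbers design the trials rely on.  Mean-field mode is
retained for conservation tests and fast diagnostics.

## Baseline parameters

Pre-calibration defaults (per year, abstract volume): τ = 5.1e-3,
τ_f = 0.3, g₀ = 0.08, g_mal = 1.2, λ₀ = 0.045, V₀ = 1, q = 1e-4,
θ_clin = 1, θ_screen = 0.25, late-loss onset 74 with factor 3.  The
packaged calibrated set refines τ to 4.6e-3 by the staged calibration
(`calibrate_baseline`): τ is solved against a cumulative incidence to
age 75 of 10.5% (forced survival, no screening — a plausible
contemporary-US anchor) and g₀ against a median onset near the
mid-sixties, both evaluated with the calibrated exposure effects active
(a one-round fixed point: the calibrated exposures raise population
incidence well above an exposure-neutral baseline, so the anchors are
imposed on the population as it will actually be simulated); τ_f
(incidence log-slope) and the late-loss pair (the ratio of the 85–90
rate to the peak rate) have levers exposed but keep manual defaults.  The regime is deliberately mixed: transformation-driven
(polynomial) accumulation supplies early-age incidence at registry-like
scale (~0.2% cumulative by 45), while growth amplification under the
Pike multipliers supplies the rise through the sixties and seventies to
a plateau in the early eighties; a
growth-dominated regime reproduces the post-menopausal flattening more
sharply but leaves essentially no cases before 45, which would make
young-age estimands (the oral-contraceptive during-use window)
unmeasurable.  g_mal and θ_clin/q set the subclinical sojourn:
ln(θ_clin/q)/g_mal ≈ 7.7 years from first malignant clone to clinical
size, with screening detecting ln(θ_clin/θ_screen)/g_mal ≈ 1.2 years
earlier — the lead time the screening trial probes.

## Exposure effect sizes

Each exposure multiplies one rate channel; all effect sizes are solved
one at a time by monotone 1-D search (geometric bisection with bracket
expansion) against a published anchor, holding everything else fixed,
with 100,000-woman cohorts, forced survival to 75, no screening, and
paired counterfactual arms.  Anchors and calibrated defaults:

| parameter | channel | anchor | calibrated |
|---|---|---|---|
| brca_mult | transformation (all steps) | carrier cumulative risk 0.57 by 75 | 1.57 |
| prs_scale | same channel as BRCA1, exp(scale·score) | risk ratio 1.55 per SD of the score | 0.095 |
| bf_loss_factor | loss, breastfeeding years | breastfeeding RR 0.76 at 75 | 5.09 |
| bmi_per5_growth | growth, post-menopause | +12% risk per 5 BMI units | 1.23 |
| beta_alcohol | transformation, 1 + β·g/day | +7.1% risk at 10 g/day | 0.0015 |
| sigma_smoke | transformation, from age 15 | smoker RR 1.10 at 75 | 1.021 |
| m_oc | growth, during use | during-use RR 1.24 | 1.075 |
| m_ht | growth, menopause + duration | RR 1.05 at 1-4 years' use | 1.080 |

Notes.  BRCA1 supports four alternative mechanisms (damage present at
birth, faster accumulation, reduced removal, faster growth); the default
is faster accumulation, and the polygenic score rides the same channel.
Alcohol acts on transformation (a growth-pathway switch,
`alcohol_on_growth`, is provided); drinks convert at 14 g per standard
drink, and behavioural exposures start at age 15.  BMI category
multipliers derive from one per-5-unit factor via WHO category midpoints
(underweight 17, normal 21.75, overweight 27.5, obese 33), so the
calibrated 1.23 per 5 units puts obese-vs-normal risk near 1.3, inside
the 1.2–1.4 literature band.  The breastfeeding loss elevation is a
physiological constant (×100) in the pre-calibration defaults; treating
it as calibrated (anchored to RR 0.76) yields ≈5 — a factor of 100
applied for a full year after every birth clears so much transformed
tissue that the protective effect overshoots several-fold.  Hormonal
growth modifiers (BMI, OC, HT) apply to all six classes including the
malignant pool; shortening the ~7-year growth-to-threshold sojourn is
what gives OC and HT their prompt during-use effect, and makes the
during-use relative risks very sensitive to their multipliers (a 7%
growth boost sustains the calibrated OC effect).  The smoking anchor (1.10) and
the per-SD polygenic gradient (1.55) are mid-range literature values;
neither is printed in a single canonical source.

Calibrated parameters ship in `data/calibrated_params.yaml` and are
regenerated by `mammosim calibrate` or `scripts/acceptance.py`.

## Trials

The OC, HT and screening experiments are paired counterfactual trials:
the treatment arm is the population's users (OC windows from the
four-quantile joint start/stop scheme; HT durations from duration
quantiles conditional on the menopause-age quantile, use starting at
menopause), the control arm the same women with the intervention's
multiplier nullified, all streams shared.  Windowed relative risks are
ratios of case counts (identical denominators).  The screening trial
enters everyone in an age group at the group's lower bound with forced
annual screening for five years against a never-screened control.

Case sparsity.  The OC during-use window sits mostly at ages 16–44 and
the HT 1–4-year stratum spans at most four post-menopausal years, so a
single 100,000-woman trial yields only tens of in-window cases.  The
calibration statistics therefore pool case counts over independent
population replicates (five for OC, four for HT) with horizons cut at
the oldest age the window can reach.  Even pooled, these two statistics
carry Monte-Carlo standard errors of a few hundredths, so the calibrated
m_oc and m_ht vary noticeably across seeds; the achieved relative risks
are solved to their targets at whatever seed is given, which is the
quantity the validation checks.

## Synthetic population

The packaged tables are synthetic, plausible contemporary-US values
chosen once by the authors (age pyramid 1930–2000; menarche 11–16
centred on 13; menopause 45–55 centred on 50–51; parity 0–4 with mean
≈1.8; birth ages as order statistics of N(26, 5.5²) truncated to the
reproductive span; 60% of parous women ever-breastfeeding; 15% smokers;
a zero-inflated drinks/year scale; WHO BMI categories 3/37/30/30%;
80% OC ever-use with stopping ages extending into the early-to-mid
forties, as in NHANES-era perimenopausal use; 40% HT use with duration
quartile medians near 2/5/9/16 years; BRCA1 prevalence 0.1–0.3% by
race/ethnicity; screening frequency 0–7 per 7 years by race/ethnicity ×
rural/urban; an all-cause Gompertz life table with life expectancy ≈81).
Users substitute their own survey-derived tables through the documented
CSV schemas.  What the generator does *not* emulate: secular trends and
cohort effects, correlations between exposures (smoking and drinking are
sampled independently), education effects, geographic structure beyond
the rural flag, and real survey joint distributions — so passing tests
show internal consistency and calibrated agreement with the anchors, not
fidelity to any particular registry population.

## Numerical choices

Poisson quantiles: exact CDF summation below λ = 30, a
continuity-corrected normal quantile above (error well under 1%).
Person-time: half a year in the exit year.  Cumulative incidence:
discrete product-limit with death as censoring (a proportion mode for
forced-survival cohorts).  Root finding: geometric bisection on a log
parameter scale, returning the best point seen when the statistic's
case-count granularity is coarser than the tolerance; budgets are
evaluation counts and exhaustion during bracketing is an error naming
the offending target.  Latin-hypercube designs come from
`scipy.stats.qmc`; partial correlation coefficients are correlations of
residuals after regressing parameter and outcome on the other
parameters.  Randomness is counter-based (Philox keyed by seed and age,
individual *i* consuming the *i*-th draw), so growing a cohort never
reshuffles existing histories and any run is bit-reproducible from its
seed.

## Problem sizes

Calibration and acceptance use 100,000-woman cohorts per arm (50,000 for
baseline staging), the scale at which binomial noise in cumulative
incidence is ~0.1% and each cohort simulation takes seconds; trials pool
up to five replicates for the sparse windows.  The test suite uses
20,000–100,000 depending on the statistic's noise floor.

## Known limitations

No tumor subtypes, treatment, survival or second primaries; no smoking
cessation; death is independent of cancer status; screening years are
drawn independently at frequency/7 from age 40 rather than scheduled;
the screening trial reproduces the qualitative first-year excess but is
not calibrated to the published Canadian-trial relative risks (which the
model family is known not to match); scenario magnitudes are
deliberately uncalibrated, so scenario outputs support timing
comparisons, not magnitude claims, except between equal-total seeded
volumes.  Pre-malignant (class-5) seeding saturates: a single seeded
clone converts with high probability, so class-5 scenario magnitudes
below one quantum are the informative range.
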