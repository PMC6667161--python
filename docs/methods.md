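# Methods

`lcsim` is a discrete-time, individual-level simulation of smoking and
lung cancer in four Asian populations, built to evaluate CMS-style LDCT
screening over 2020–2040. The original large policy model whose analysis
it mirrors does not publish its internal natural-history equations, so
the disease core here is a deliberately small *calibrated surrogate*: the
minimal structure that can be pinned to the published target families
(national smoking prevalence, national lung-cancer death counts, the
NLST trial effect) and that reproduces the qualitative behavior of the
published projections. This note records the model, its parameters, the
numerical choices, and what the surrogate can and cannot claim.

## Population and time

Annual cycles, integer attained ages 0–100, all age intervals closed-open
`[a, b)`. Birth cohorts 1910–2022 are simulated from birth so that
everyone alive between the calibration era (1990s–2012) and the 2040
horizon is represented. Within a year the update order is fixed:
other-cause death → cancer onset → screening → clinical surfacing →
cancer death. Ties therefore resolve toward other-cause death.

National scale enters through per-(cohort, sex) weights anchored on the
first projection year's (2020) population pyramid: the newborn-equivalent
size of a cohort is its 2020 head count divided by other-cause survival
to its 2020 age. A deterministic per-year factor then aligns the
model-implied total population (including analytically added post-2022
child cohorts) with the linearly interpolated national projection
anchors. Because the factor is shared by both arms of a paired run it
never contaminates policy contrasts. Published pyramids give totals only,
so single-year-of-age shares are synthesized from each country's median
age (a stretched-exponential age density with a small seeded
survey-noise perturbation; male fraction declining linearly with age).

Cohorts born 1925–1990 — which carry essentially all 2020–2040
lung-cancer deaths — are sampled at four times the base intensity, with
weights divided accordingly: a pure variance-reduction device that leaves
all expectations unchanged.

## Smoking histories

* **Initiation**: per-sex hazard `peak_rate × exp(−(a − peak_age)²/2w²)`
  on ages 10–39 (peak age 19, width 4.5 y); `peak_rate` is fitted per sex
  to the national adult (18+) current-smoking prevalence at the survey
  target year. One initiation per lifetime.
* **Cessation**: the published age schedule (men: 0.02/yr ages 30–65,
  0.03/yr above; women: 0.02/yr above 35), applied from the year after
  initiation; no relapse. The same schedule serves all four countries, as
  in the source analysis.
* **Intensity**: one constant CPD per smoker, drawn from the integer-CPD
  distribution implied by the country survey — coarse survey bins spread
  uniformly over the integer CPDs in their range (open-ended top bins run
  to 50), or a discretized lognormal (σ_log 0.5) where the source reports
  only mean CPD (China: male-by-age 2006 values averaging 15.0; female
  15.8). The canonical six intensity categories (1–5, 6–15, 16–25, 26–35,
  36–45, 45+) are exact aggregations of this distribution; sampling the
  integer CPD rather than a bin midpoint matters because 30-pack-year
  eligibility is extremely sensitive to intensity near 15 CPD.
* **Pack-years**: `cpd/20 × years smoked`, frozen at cessation.

Sensitivity scenarios multiply cessation probabilities (±20%) and CPD
(∓20%) for cohorts born after 1981 from calendar year 2011 onward; both
earlier cohorts and earlier calendar years are untouched, so an affected
smoker's intensity is piecewise constant with a single switch at 2011
(pack-years, eligibility timing, and the smoker mortality excess all
honor the switch).

## Natural history

* **Onset**: annual probability `baseline(age) × (1 + ERR × epy)`.
  `baseline` rises like `((age − 35)/45)^2` and plateaus at age 80
  (incidence curves flatten at the oldest ages); its per-sex scale is the
  calibrated parameter. `ERR = 0.40` per effective pack-year puts a
  40-pack-year current smoker near relative risk 17, consistent with
  high-income-country cohorts and with the small never-smoker share of
  deaths implied by the published by-smoker-type tables. Effective
  pack-years decay with a 15-year half-life after quitting.
* **Sojourn**: preclinical disease surfaces clinically after a geometric
  sojourn, mean 4 years.
* **Stage and survival**: surfacing draws early stage with probability
  0.25 (screen detection: the calibrated, larger fraction). Survival is
  mixture-cure: early-stage cases are cured with probability 0.10 and
  otherwise die at 0.135/yr (≈56% 5-year cause-specific survival);
  late-stage cases are cured with probability 0.01 and otherwise die at
  0.45/yr (≈8%). The cure component is what lets the cumulative
  mortality-reduction curve flatten rather than decay as postponed deaths
  return.
* **Other-cause mortality**: a synthetic Gompertz–Makeham reference
  schedule per sex, multiplied by a per-country ratio chosen so the
  implied life expectancy at birth matches the country's published 2020
  sex-specific values (the ratio mechanism mirrors how the source
  analysis transported a U.S. schedule). Smokers additionally carry a
  CPD-scaled all-cause excess (relative risk 2.0 at 20 CPD, post-quit
  half-life 7 y) applied as a *within-age redistribution*: per-person
  multipliers are normalized by the closed-form cohort-average
  multiplier, so the population-level schedule — and hence pyramids,
  weights, and life expectancy — is unchanged while smokers die earlier
  than never smokers. The normalization ignores mortality selection
  within a cohort, a second-order effect.

## Screening and its calibrated benefit

CMS eligibility (55–77, ≥30 pack-years, quit ≤15 y — the inclusive
reading of the published rule, with a strict-inequality toggle), annual
screens 2020–2040 at 100% adherence. All eligibility criteria are
intervals in time, so each person has a closed-form eligibility window;
screens are counted for every alive, undiagnosed, eligible person.
Detection of preclinical disease occurs per screen with sensitivity 0.9
(a fixed design scalar shared across countries) and draws the stage from
the screen-time distribution. Screening has no other pathway: a
screen-detected person's cancer-death clock still starts at the
counterfactual clinical-surfacing year, so paired arms differ only
through the stage (and cure) drawn — no lead-time bias, and screening-arm
cumulative deaths can never exceed the baseline arm's under the shared
draws.

The screen-time early-stage fraction is fitted by bisection until a
trial-like cohort — entry ages 55–74, ≥30 pack-years, quit ≤15 y, three
annual screens, seven annual cycles (~6.5 y) of follow-up, paired against
its own no-screening arm — shows a 20% lung-cancer mortality reduction.
The fitted value is validated on a held-out cohort seed. The trial's real
comparator was chest radiography, not no screening; treating the 20% as
an LDCT-versus-nothing effect is the largest approximation in the
package.

## Calibration mechanics

Stages run in order (prevalence → death counts → trial benefit), each a
deterministic 1-D search per parameter under common random numbers (the
same seed for every objective evaluation), so objectives are smooth
deterministic functions and re-running a stage reproduces its result
exactly. Prevalence uses 22 bisection steps; death counts use a
fixed-point ratio iteration (deaths are nearly proportional to the
baseline scale) stopped at 2.5% agreement or eight iterations; the
benefit fit brackets at full stage shift before bisecting. Annual death
counts at the target year are estimated as the mean over a ±4-year
centered window — the model's annual counts drift slowly there, and the
window multiplies the effective death count ninefold, which matters at
desk-scale n. Every stage serializes a machine-checkable report
(target, achieved, tolerance, pass) into the config.

## Sampling without a time loop

All event times are drawn by inverting cumulative discrete hazards
against per-person exponential thresholds, which is exactly equivalent to
running the annual Bernoulli transitions (the unit suite checks the
step kernels against closed forms). Each stochastic process draws from a
generator seeded by `(seed, purpose)`, so draws depend only on the person
index — this is what makes paired scenarios, calibration iterations, and
sensitivity scenarios share their randomness. Simulated populations are
bitwise reproducible given `(config, scenario, n, seed)`.

## Monte Carlo scale

Default `n_persons` is 5×10⁵ per run (headline analyses average three to
five paired replicates); the trial-benefit fit uses 10⁶ and the trajectory-
shape checks 1.5×10⁶, because annual (as opposed to cumulative) reduction
series need several thousand raw simulated deaths per year before their
peak location is meaningful. At these sizes the cumulative 2020–2040
reduction for one country carries a standard error of roughly 0.1–0.3
percentage points.

## What the synthetic data do and do not emulate

The generator produces configs with the same schema as the packaged
countries, pyramids consistent with total-population anchors, and
binomially noisy prevalence series for calibration tests. The toy country
stores its true parameters and derives its own targets from them
(prevalence from the exact closed-form expectation; death counts from a
simulation at known truth), so calibration tests are genuine
parameter-recovery experiments. It is deliberately cancer-dense —
roughly an order of magnitude above any real country — so single-year
death targets carry little Monte Carlo noise; properties that rely on
lung cancer being demographically negligible (e.g. the 2020 population
anchor check) are therefore tested on realistic configs instead.

## Known limitations

* Initiation has no cohort or period trend: every cohort faces the
  hazard calibrated to the single published prevalence anchor (2010).
  Countries whose older cohorts smoked far more than their 2010
  prevalence suggests — South Korea and Japan most of all — therefore
  carry too few high-exposure elderly smokers, and the model places
  South Korea *below* China/Japan in screening benefit where the
  published analysis places it on top. The published ranking appears to
  require the historical prevalence series, which the source tables do
  not print.
* CPD is constant over a career; published age-specific intensity
  declines are not represented.
* Pyramids are smooth single-parameter shapes; real baby-boom bulges
  (again most consequential for South Korea) are absent.
* No false positives, overdiagnosis, radiation harms, histology, or
  non-smoking risk factors; never smokers appear only through the
  baseline hazard.
* Life-years per death prevented runs ~8–10 here versus ~6.3–6.4 in the
  source analysis — saved lives last somewhat too long, even with the
  smoker other-cause excess.
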