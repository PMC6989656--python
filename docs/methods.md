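# Methods

This note records the models, conventions and design choices behind
`chronosurvey`, in the order the pipeline applies them.

## Time conventions

Clock times are float hours since midnight in [0, 24); mid-sleep phases are
*hours centred on midnight*, i.e. mapped to [−12, 12) so 03:07:30 is 3.125
and 23:00 is −1.0. All intervals and diary slots are half-open (a slot
contains its start, not its end). CSV files carry times as 24-hour `HH:MM`,
so all file-borne times live on a one-minute grid.

## Questionnaire scoring

Sleep onset is preparation time plus latency (latencies ≥ 6 h are rejected
as reporting errors). Durations are `(end − onset) mod 24` and must fall in
(0, 16) h — outside that, a record is quarantined rather than scored. The
sleep-debt correction subtracts half of the free-day sleep extension over
the weekly average and is applied only when free-day sleep exceeds work-day
sleep; with no workdays the weekly average equals free-day sleep and the
correction vanishes. MSFsc is only interpretable when free-day sleep is
unconstrained, so it is reported solely for respondents who need no alarm
on free days or wake before their work-day alarm (an OR of the two flags).
The best-alertness midpoint is taken along the forward arc from interval
start to end, and reported on the [0, 24) clock (its population mean sits
near noon); overnight alertness intervals are thereby legal, and a
zero-length interval returns its endpoint.

## Diary extraction

Diaries are 48 half-hour sleep flags over the window 06:00 → 06:00. The
main sleep bout is the longest maximal run of consecutive sleep slots, ties
broken by the earliest start — a deterministic rule that is robust to naps.
A bout touching either window edge is censored: its true onset or offset
fell outside the diary, and inventing it would bias mid-sleep, so censored
bouts yield no value and are counted in the exclusion log (codes
`NO_SLEEP`, `CENSORED`, `NOT_TYPICAL`; exclusions plus scores always add to
the input row count). Mid-sleeps from uncensored bouts are routed to MSF on
free days and MSW on work days, and only diaries flagged as a typical day
are scored. Rendering any true sleep interval to slots and re-extracting
moves the midpoint by at most a quarter hour (half a slot); the test suite
verifies this discretization bound against the generator's truth table.

## Age/sex normalization

Adult population mid-sleep is modelled per sex by a one-phase exponential
decay `(Y0 − Plateau)·exp(−K·age) + Plateau`, with Y0 the (extrapolated)
value at age 0 in hours, Plateau the late-life asymptote in hours, and K a
rate per year (> 0). Fitting is multi-start bounded least squares
(trust-region reflective): starts Y0 ∈ {6, 9, 12} × K ∈ {0.03, 0.07, 0.15},
Plateau started at the 10th percentile of the response among the oldest age
decile; bounds K ∈ (10⁻⁴, 1), Plateau ∈ (−12, 12); tolerances 10⁻⁸. The
model demands ≥ 30 observations spanning ≥ 20 years of age. A constant
response, or a fit pinned at the lower K bound, is refused as
unidentifiable rather than reported. Standard errors come from the
Gauss–Newton covariance at the optimum.

Normalization to the reference age of 30 is additive:
`MSFsasc = MSFsc − predict(sex, age) + ref30`. By default `ref30` is the
mean of the men's and women's curve predictions at 30, removing age and sex
effects symmetrically; a `per_sex` reference (age effect only) is available
as an option. An additive shift preserves within-stratum ordering and
spacing exactly. Extreme chronotypes are the lowest and highest deciles of
MSFsasc by average ranks (deterministic and permutation-invariant; a fully
tied sample is entirely non-extreme).

## Association battery

"Student t test" means the pooled-variance two-sample t (Welch behind a
flag). One-way ANOVA pairs with Tukey HSD post-hoc contrasts using the
studentized-range distribution with the Tukey–Kramer unequal-n adjustment
(via statsmodels). Pearson r is computed from the product-moment definition
with a two-sided p from the t transform, and is cross-checked against
scipy's implementation in the tests. Binned trend profiles use equal-count
bins with per-bin mean ± SD and a least-squares polynomial (default order
4) through the raw points. No multiple-testing correction is applied across
the battery — every p value is reported as-is, which the reader must keep
in mind when scanning many analyses. Missing data are complete-case per
analysis, with the rows used reported by every test so counts reconcile.

The biomarker contrasts compare HDL and LDL (mmol/l) across the three
chronotype categories by ANOVA + Tukey, the LDL/HDL ratio between the two
extremes by t test, and HDL between extreme and non-extreme subjects within
each sex; strata with fewer than two observations are skipped with a log
entry.

## Solar geometry

The NOAA low-precision equations (fractional-year trigonometric expansions)
give solar declination and the equation of time; sunrise/sunset are the
crossings of solar altitude through −0.833° (refraction plus the solar
half-disc), with no elevation or temperature corrections. Accuracy is about
one minute, ample for statements at the "around 8 a.m." level, and is
checked in the tests against an independent minute-stepping altitude scan
(agreement ≤ 2 min for |lat| ≤ 66°). Polar day/night return flags, not
numbers. The ST/DST comparison is modelled purely as a UTC+1 vs UTC+2 local
clock applied yearlong; transition dates are out of scope because the
policy question is yearlong-vs-yearlong.

## Synthetic survey generator

The generator emulates a two-survey national study: a household panel
providing questionnaires, alertness intervals and time-use diaries, and a
smaller arm with blood lipids. Its defaults *are* the study conditions and
live in `src/chronosurvey/config/default.yaml`.

**Latent model.** For subject *i*,
`C_i = decay(sex_i, age_i) + Σ_j β_j (x_ij − x̄_j) + δ + ε_i`. Ages are
uniform 18–85, sex 51.5% women, longitude/latitude uniform over a
12–19°E × 48.5–51.1°N box, settlement sizes log10-normal (mean 3.5, SD 1.0,
clipped to 10²–10⁶·¹²), and lifestyle covariates independent draws with
documented prevalences (partner 0.65, children 0.35, dog 0.41, smoking
0.28, high alcohol 0.15, rare fruit/veg 0.40, outdoor hours Gamma(3, 4)).
Joint covariate structure (e.g. dog ownership by settlement size) is not
modelled. Effect sizes are hours per covariate unit; the longitude
(−0.05098 h/°) and latitude (+0.09535 h/°) effects were fixed once so that,
under the default geography and a scored-MSFsc SD of 1.0844 h, the implied
Pearson correlations are −0.095 and +0.066. The remaining effect magnitudes
are not pinned by published values and were chosen once at plausible sizes
(0.18–0.30 h for binary factors) large enough for sign recovery at n ≈ 3000.

**Exact marginal calibration.** δ and the noise SD are solved at generation
time so the latent mean and SD equal the configured targets (mean 3.125 h,
SD 1.0844 h); the drawn noise is then residualized against the structural
design (intercept, decay term, each covariate) and rescaled, so the sample
moments — and the zero sample correlation between noise and every covariate
— hold *exactly*, not just in expectation. This is the empirical-calibration
device familiar from `MASS::mvrnorm(empirical = TRUE)`; it removes
first-order Monte-Carlo wobble from the calibrated quantities while leaving
per-subject randomness intact. Setting the SD target to null disables
calibration and uses an explicit noise SD (zero noise then places every
subject exactly on the decay curve).

**Questionnaire inversion.** Raw items are built so that scoring returns
`C_i`: work-day sleep duration ~ N(7.1, 0.6) h, sleep debt half-normal
(scale 0.9 h), workdays mostly 5, whence the correction `WD·debt/14`
determines MSF, and bed/wake/latency items follow; everything is snapped to
the minute grid *before* the truth table is computed, so the emitted CSVs
score back to the truth exactly. 64% of respondents are eligible for MSFsc
(55% need no free-day alarm; 20% of the rest wake before the work alarm),
echoing the ~0.64 eligible fraction of the emulated study.

**Alertness intervals.** BAmid is `target_mean + target_sd·(ρ·z_i +
√(1−ρ²)·w_i)` with z the standardized latent chronotype, ρ = 0.327, and w a
standardized skew-normal (shape 4) giving the slight rightward asymmetry of
self-assessed alertness. A skew-normal, rather than a heavier-tailed
lognormal, keeps midpoints on the clock face without distorting the SD or
the correlation through truncation; w is residualized against z and
standardized so the sample correlation and BAmid moments are exact. The
interval half-width is uniform 1–4 h around the midpoint.

**Diaries.** The reported day is a free day with probability 0.32 and
typical with probability 0.85; the sleep interval (latent mid-sleep plus
N(0, 0.3) reporting noise, duration from the questionnaire draw) is
rendered to slots by the midpoint rule. Censoring is *natural*: sleep
running past 06:00 truncates at the window edge. With realistic mid-sleeps
near 3 h and ~8 h durations this censors the majority of diaries — as in
real diary studies, where only a minority of records yield usable
mid-sleeps — and the truth table records the censoring flag for every row.

**Biomarkers and BMI.** HDL baselines 1.75 (women) / 1.35 (men) mmol/l, SD
0.32; women in the extreme latent deciles get −0.10 mmol/l and extremely
late women a further −0.12; LDL is N(3.0, 0.8) with no chronotype link. BMI
is N(25.0 or 26.5, 4.0) with a +0.35 kg/m² per hour slope in women only.
Biomarkers are emitted for a 22% subsample, mirroring the second survey
arm. These shifts produce a detectable women-specific HDL deficit in
extreme chronotypes and a null in men at the bundled sample sizes.

**Randomness.** One `SeedSequence` per bundle spawns independent substreams
for demographics, the latent draw, questionnaire mechanics, alertness,
diaries and biomarkers, so a bundle is byte-reproducible given (config,
seed) and partial regeneration leaves other files unchanged.

## What the synthetic data do and do not show

Passing the round-trip suite shows the scoring, normalization and
association machinery is correct and internally consistent at realistic
effect sizes and sample sizes. It does not validate the latent model
against real populations: real covariates are jointly distributed, real
sleep debt is not half-normal, real alertness self-assessment has
idiosyncratic biases, and real diary censoring correlates with chronotype.
Conclusions about any actual population require actual survey data run
through the same pipeline.

## Problem sizes

The bundled analyses use n = 5000 subjects for marginal checks, n = 3000
for correlation and gradient checks, and 50 replicates of n = 2000 for
decay-constant recovery — sizes comparable to the emulated surveys and
sufficient for the quoted Monte-Carlo tolerances (3 SEs for marginals,
±0.03 for correlations, 5% relative for the median decay rate).

## Known limitations

* MSW from diaries and questionnaires is exposed but not analyzed further;
  social jetlag is carried as a convenience column only.
* The decay model is the only age model offered (no splines); subjects
  under 18 are excluded from normalization by design.
* Tukey p values from statsmodels are reported to its printed precision.
* The solar module is a low-precision ephemeris; do not use it where
  sub-minute accuracy matters.
* The generator draws covariates independently; effects estimated on its
  output are unconfounded by construction, unlike in observational data.
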