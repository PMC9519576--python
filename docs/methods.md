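# Methods

## Data model and analysis window

A DAM2 monitor exports one tab-separated row per acquisition interval
(60 s by default, configurable) with 42 fields: reading index, date,
time, an acquisition status code, six reserved instrument fields (the
last carrying the light-sensor flag) and 32 per-channel beam-break
counts. Parsing is loss-free: reserved fields are preserved verbatim, so
write(read(f)) is byte-identical for files the package writes. Rows
whose status code is not 1 are retained and flagged rather than dropped.

The analysis window is the first complete lights-on-anchored stretch of
`window_days` (default 3) whole days, after an optional burn-in discard
(default 0 h — the recording protocol being emulated ran three
continuous days with no stated acclimation discard). The light vector
comes from the configured schedule (lights-on clock time, photoperiod,
default 12:12) rather than from the monitor's light sensor, which is
unreliable in practice; `light_source="file"` restores the sensor.
Timestamps are local clock times with no DST handling — windows are at
most a few days.

## Sleep scoring and phenotypes

Sleep uses the field-standard definition: a 5-minute bin with zero beam
breaks. Bins are half-open `[t, t+5)` anchored at the window start
(lights-on), and a bin's light phase is the majority phase of its
minutes (ties cannot occur with 5-min bins on a 12:12 schedule anchored
at lights-on). Three per-fly phenotypes are computed over the whole
window: total activity (sum of counts), proportion of bins asleep, and
mean awake activity in counts per 5-min awake bin (the published unit);
the identity `total = mean_awake × n_bins × (1 − prop_asleep)` holds
exactly whenever any bin is awake, and mean awake activity is undefined
(NaN, excluded from awake-activity models) when every bin sleeps.
Day/night decompositions are reported for inspection but not modelled.

QC: a fly whose terminal run of sleep-scored bins spans at least
`dead_tail_hours` (default 12 h) after earlier activity is classified
dead and excluded — the original study excluded 4 of 480 flies that died
without stating a criterion; 12 h is long enough that a genuine sleep
bout is implausible, and the threshold is configurable. Channels with no
activity at all are excluded as `all_zero`; blank control channels that
registered counts are flagged `blank_active` (monitor fault). Exclusion
counts at every step go to the run log.

## Mixed models and term tests

Activity traits are gaussian; the proportion of time asleep is binomial
with successes = sleep bins and trials = total bins on a logit link.
Each panel's primary model fits line, sex and line×sex as categorical
fixed effects. The study protocol describes "replicate nested within
block" as the random term, but with one datum per fly the innermost term
is confounded with the residual, so the default estimable structure is a
block random intercept; the combined coevolved-vs-cybrid models add a
line-within-type random intercept, and the haplogroup models add line
(haplogroup is a between-line factor, so omitting line would
pseudo-replicate flies).

Gaussian fits are REML via statsmodels MixedLM. A single grouping factor
uses the grouped representation; crossed factors enter as variance
components under one covering group. The profiled REML surface is flat
near zero-variance boundaries, where gradient-based optimisers stall, so
fitting uses Powell's derivative-free search (cross-checked against lme4
to ~4 significant figures in the test suite). A component estimated at
the boundary is returned as a flagged singular fit, not an error. With
no random terms the model degenerates to OLS with residual variance
RSS/(n−p).

The binomial GLMM uses a Laplace approximation with random-intercept
variance components: for candidate log-SDs, fixed effects and
random-effect modes are maximised jointly by damped Newton iterations
(step-halving on the penalised log-likelihood; linear predictor clipped
at ±30; weights floored at 1e-12), and the outer L-BFGS-B search on the
Laplace objective runs over the log-SDs with fixed starting values
log(0.3) and bounds (−6, 3) — the fit is fully deterministic. The
fixed-effect covariance is the inverse of the joint Hessian's
fixed-effect block (conditional on the variance estimates); against
lme4's glmer the estimates agree to ~3 decimal places on test data.
Variance components are reported on the latent logit scale. Complete
separation (a fixed-effect cell with all-0 or all-1 proportions) flags
the fit rather than failing. An observation-level random intercept for
overdispersion can be added as just another variance component but is
off by default.

Term tests are marginality-respecting (type II) Wald χ²: each term is
tested in the model that omits every term containing it, with variance
parameters held at the full-model estimates — GLS refits for gaussian
responses, penalised refits for binomial. This matches the convention of
the car::Anova ecosystem and is invariant to the factor reference level;
an independent brute-force GLS assembly of the same contrast is the
oracle in the test suite. Type III with sum-to-zero coding is available
via `anova_type=3`. Degrees of freedom equal the rank of the tested
block (rank-deficient contrasts warn and reduce df). These are
large-sample χ² tests; no Kenward–Roger/Satterthwaite small-sample
correction is attempted.

## Variance partition

Among-line variance per panel comes from a model with sex fixed and line
and block random (gaussian for the activity traits, binomial-logit for
sleep, whose variance is read on the latent scale — the published sleep
variances 0.48/0.07 are only consistent with a latent scale). Sex is
kept fixed so the sex main effect does not inflate the line component;
it can be dropped. The cybrid/original ratio is reported at full
precision with a 2-dp display column; a zero original-panel variance
leaves it undefined and flagged. The published awake-activity ratio is
not reproducible from its rounded printed components (0.15/0.02 = 7.5,
not 6.04), so the arithmetic-verification report flags it and the
package never forces the printed value.

Uncertainty is a nonparametric cluster bootstrap resampling whole lines
with replacement within each panel — lines are the unit of inference —
with percentile intervals, deterministic given a seed. Replicates with a
zero original-panel variance are dropped (and counted; more than half
triggers a wide-interval warning). With 8 lines per panel a line
variance has roughly 50% relative sampling error, so point ratios are
noisy and the interval should always accompany them.

## Synthetic experiments

Each fly's sleep/wake process is a first-order two-state Markov chain at
1-min resolution — the simplest process with controllable occupancy and
bout length. Sleep bouts leave with probability 1/`mean_bout_min`
(default 20 min, giving geometric bouts), and the wake→sleep probability
is set so the stationary sleep fraction equals the fly's occupancy.
Awake minutes emit Poisson counts at `awake_rate × diel(t)`; asleep
minutes emit zero. The diel profile is crepuscular — Gaussian bumps (SD
45 min, relative amplitude 1.5) at lights-on and lights-off, circular in
time and normalised to mean 1 over 24 h so modulation leaves expected
totals unchanged. Diel modulation applies to awake activity only; sleep
propensity has no diel term because no quantitative diel sleep profile
was available to calibrate one.

The effect hierarchy mirrors the cybrid design: per line, an mtDNA
effect (SD 0.15 on both the logit-occupancy and log-rate scales) shared
between the line's coevolved and cybrid incarnations, plus an
independent nuclear effect (SD 0.30) applied only in the coevolved
panel; block effects (SD 0.05) and per-fly effects (SD 0.15) sit below.
Effects are drawn, not fixed, so σ²_mt and σ²_nuc are meaningful
population parameters for recovery tests; the SDs were chosen to give
between-line spreads of a few percentage points of sleep and tens of
percent of activity, comparable to the published line differences.
Deaths occur with probability 4/480 per fly and truncate counts to zero
from a uniform time in the final day; one blank control occupies channel
32 of each monitor, and leftover channels are `empty`. Random streams
are hierarchical (experiment → fly), so adding a fly never perturbs
another fly's series, and everything is byte-reproducible from
(scenario, seed).

### Calibration to the published cell means

The default scenario targets the published cell-level values: sleep
55/64% (coevolved female/male) and 30/46% (cybrid), awake activity
5/5.74 and 6.3/5.6 counts per 5-min bin. Those published proportions are
themselves 5-min-scored quantities, and the scoring operator is biased
with respect to the latent chain: bout edges that share a bin with wake
activity are scored awake (undercounting sleep by 4–9 percentage points
at 20-min bouts), while quiet-wake bins score as sleep (a smaller
overcount). The generator therefore inverts the scorer during
calibration: the expected scored sleep fraction of the stationary chain
is computed exactly as a transfer-matrix product over each bin's minutes
(awake minutes contribute their Poisson zero probability), and the
latent occupancy is solved by root-finding so that this expectation
equals the target, with the latent awake rate adjusted in the same fixed
point so the expected total activity keeps the identity-consistent value
`target_rate × (1 − target_sleep) × window`. The scenario's occupancy
and rate fields always hold the published targets; the latent values
live in the ground truth. `calibrate_scoring=False` disables the
inversion and uses the targets as latent parameters directly.

What the generator does not emulate: overdispersed (bursty) beam-break
counts beyond Poisson (a negative-binomial option would sit naturally at
the emission step), heavy-tailed bout-length distributions, diel sleep
architecture (night vs day bouts), circadian free-running, position or
multi-beam data, and monitor faults other than silent channels. Passing
recovery tests therefore show the analysis is correct for data meeting
its own assumptions, not that real data meet them.

## Test and verification sizes

The suite's statistical checks run at deliberately chosen sizes: term-
test calibration uses 500 null experiments at the study's size (n = 480,
16 lines × 2 sexes × 15 flies over 5 blocks) generated at the phenotype
level — the model sees identical data either way, and the per-fly series
step is exercised separately; variance-ratio recovery simulates one full
matched-panel experiment with generative σ²_mt/(σ²_mt+σ²_nuc) = 0.2 and
checks coverage with 200 line-bootstrap replicates; scorer closure uses
the full 480-fly calibrated experiment over 3 days; the scorer oracle
compares 100 simulated flies against the exact transfer-matrix
expectation. Mixed-model estimates are cross-checked against lme4
(lmer/glmer via Rscript) on fixed datasets, and against closed-form
method-of-moments variance estimators on balanced designs.
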