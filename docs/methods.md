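# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Study design being modeled

Seven GPS-collared brown bears are followed at 30-min fixes for four weeks
spanning the opening of the Swedish bear hunting season: two weeks without
hunting risk (7–20 August, "prehunting") and the first two weeks with it
(21 August – 3 September, "hunting"). Risk varies on two scales: between
periods, and within the day — legal hunting runs from 1 h before sunrise
to 2 h before sunset, with effort (and kills) concentrated in the morning.
The day is split at the 10:00 activity minimum into two 12-h bouts
(morning 22:00→10:00, afternoon 10:00→22:00); all analyses run per bout.

## Trajectory segmentation

A step is the Euclidean displacement between consecutive fixes; steps
whose duration is outside 30 ± 5 min (missed fixes) are invalid and break
runs. The 5-min tolerance absorbs ordinary GPS schedule jitter. Foraging
is a maximal run of valid steps with every length in the closed interval
[25, 300] m and at least `min_run = 3` steps; other maximal runs spanning
at least three positions are labeled "other", shorter fragments are
dropped. Both interval endpoints are inclusive (the plain reading of
"25–300 m") and `min_run` is configurable because the step-vs-position
counting of the run rule is genuinely ambiguous: three 30-min *intervals*
(1.5 h of movement) means 3 steps / 4 positions, while a three-*position*
minimum means 2 steps. The default follows the interval reading.

Per-fix labels follow an outgoing-step convention: a fix carries the label
of the trajectory owning the step that leaves it, and the final fix of a
run takes the label of the trajectory it terminates. This makes the
labeled-fix table an exact partition (no fix in two trajectories) even
though two abutting trajectories share a boundary position in their
position lists, where positions are counted as steps + 1.

Classification is invariant to translation and rotation (it uses only
step lengths and times); the test suite checks this property directly.

## Solar computation

Sunrise/sunset use the standard NOAA solar-position equations at the
apparent-horizon zenith 90.833° ("meteorological" sunrise in the hunting
regulation is taken as this standard convention — it reproduces the
printed 04:30–18:30 window on the first hunting day); nautical twilight
bounds use 96° and 102°. The Julian century is re-evaluated at the event
time (one refinement pass), giving agreement within ~1–2 min of an
independent almanac computation. When the sun's culmination only grazes a
twilight threshold (within 5×10⁻³ in the hour-angle cosine — the
situation at the study site in the first days of August, when the sun
barely reaches 12° below the horizon), the event is pinned to the
culmination rather than erroring; genuinely unreachable elevations raise
an explicit undefined-event error instead of clamping. The local clock is
a fixed UTC+2 (CEST; no DST transition falls inside the study window).

Window rounding is to the nearest grid point (default 30 min), half-up at
exact midpoints — whether the regulation times were rounded or quoted is
unknowable from the printed values alone, so the grid is a config knob
validated against the 04:30/18:30 anchor.

## Availability baselines

Berry counts on 1-m² plots are zero-truncated NB2 with log link,
predictors habitat (mature forest reference vs clearcut) and Julian date
(no interaction; the two main effects only). NB2 was chosen as the
standard ecological parameterization (variance μ + μ²/θ). The likelihood
is maximized in (coefficients, log θ) space by Nelder–Mead with BFGS
polish from a method-of-moments start plus fixed starts θ ∈ {0.5, 2, 10};
the dispersion saturates at θ = e¹⁴ so equidispersed (Poisson-like) data
leave a flat plateau rather than a numerical cliff. The parameter
covariance comes from the inverse numerical Hessian at the optimum.
Julian date is centered at its sample mean internally (stored in the fit
for prediction).

"Expected" forage is by default the truncated mean μ/(1 − (θ/(θ+μ))^θ),
because the field protocol (and the fit) condition on plots holding at
least one berry; the untruncated μ is available behind a flag since either
reading of "expected number" is defensible. Sugar is an OLS fit on the
same predictors with residual SD as scale.

## Efficiency, quality, and the cell summaries

Efficiency = observed − expected count; quality = observed − expected
sugar. For skewed efficiencies a square-root transform is applied after
adding c = ⌈|min|⌉ + 1 (the constant any negative-valued dataset needs; it
is recorded in the output so back-transformation t² − c is exact to
machine precision).

Cell (period × bout) means are reported with a 95% interval that adds the
delta-method variance of the baseline prediction — averaged over the cell
— to the within-cell variance of the mean. The baseline error is *shared*
by all observations in a cell, so omitting it makes nominal intervals
undercover whenever the random-plot sample is modest (the study sizes are
154 count plots against ~180 observations per cell); including it restores
nominal coverage, which the 100-seed recovery experiment confirms.

The sampling-lag validation regresses efficiency on the days elapsed
between the bear's visit and field sampling (1–9 days), per period, and
checks the 95% CI covers zero.

## Mixed models and AICc selection

Six candidates per response and bout (interaction with and without the
hunting main effect, additive, time-only, hunting-only, intercept), all
with a bear-id random intercept, fitted by maximum likelihood:

* **Binomial** (per-fix foraging indicator): the random intercept is
  integrated out by adaptive Gauss–Hermite quadrature — per group the
  integrand is recentered at the joint-density mode (damped Newton) and
  rescaled by its curvature; 9 nodes agree with 25 nodes to <10⁻³ and
  with brute-force grid integration to <10⁻⁴ on test problems. Outer
  optimization is BFGS over (β, log σ_b) warm-started from a plain
  logistic fit.
* **Normal** (efficiency/quality): fixed effects are profiled out by GLS
  in closed form (Woodbury identities per group) and the two variance
  components optimized by Nelder–Mead; results match an independent
  mixed-model implementation to ~10⁻⁹ in log-likelihood.

A fit drifting to σ_b = 0 is compared against the exact boundary fit
(GLM/OLS) and reported as a boundary fit, not an error.

The time effect is an *unpenalized* cubic regression spline of fixed
dimension k = 6 (B-spline basis, knots at quantiles of the observed bout
hours, first column dropped against the intercept since the basis sums to
one). Penalized smooths have data-driven effective df, which would make
AICc's parameter count ill-defined; a fixed basis gives every candidate a
deterministic df at the cost of not reproducing penalized-smooth estimates
exactly. df = fixed coefficients + 1 (random-intercept variance), plus 1
more (residual variance) for the normal family; with this convention the
six candidates have strictly decreasing df in the order listed. The
interaction-without-main-effect model ("daytime³:hunt") is separate spline
coefficients per period under a common intercept; the full interaction
adds the hunting intercept shift. Bout hours are mapped to a continuous
0–12 axis (morning crosses midnight: 22:00→0, 10:00→12) so the spline
never sees a wrapped axis.

Ranking: Δᵢ = AICcᵢ − min AICc, Akaike weights wᵢ ∝ exp(−Δᵢ/2); the
selected model has the fewest df among {Δ ≤ 2}, ties broken by smaller
AICc. Models fitted to different n are refused (likelihoods not
comparable). Foraging-probability models are fix-level Bernoulli (no
aggregation), matching the bout sample sizes in the thousands.

## The synthetic-data generator

What it emulates, and how:

* **Schedule.** Per-period, per-hour foraging probabilities, sharply
  bimodal: 0.9 in the 02–07 and 13–20 peaks, 0.25 shoulders adjacent to
  the peaks, near-zero (0.02–0.06) in the midday trough and deep night.
  The hunting period lowers the morning peak by 0.10 (the reduced morning
  foraging under risk); the afternoon is unchanged. States are drawn per
  clock hour (both fixes in an hour share the state) from a
  Gaussian-copula AR(1) latent with ρ = 0.85: the per-hour marginals equal
  the schedule *exactly* while behavior persists across hours. The
  persistence is what makes foraging episodes long relative to the 3-step
  rule — with independent hourly draws a meaningful share of true foraging
  would sit in sub-threshold episodes and no segmentation rule could
  recover it. Real activity profiles are smoother than this
  near-rectangular schedule; the sharpness is an idealization that keeps
  behavioral episodes well separated from the classifier's thresholds.
* **Movement.** Uniform step lengths within disjoint per-state bands
  (rest < 20 m, forage 30–260 m, travel > 330 m — inside, below, and above
  the 25/300 m classifier thresholds), isotropic headings, planar
  random-walk accumulation in an abstract metric CRS. No home ranges,
  habitat selection, or autocorrelated headings. Fix dropout is
  independent Bernoulli (2% default).
* **Berry field.** Habitat Bernoulli(½), date uniform over the study
  window, NB2 counts with log-mean rising through the season (mature
  forest ≈ 12, clearcuts ≈ 30 berries/m² at the window start; slope
  0.015/day; θ = 2.5), zero-truncated by rejection (only plots holding
  berries enter the baseline, mirroring the ZTNB family; a flag emits the
  zeros for robustness checks). Sugar is linear with Gaussian noise
  (≈ 7.5/8.5 %Brix, +0.03/day, SD 1.2); a ~71% subsample carries sugar,
  matching the 110-of-154 measurement ratio of the field protocol.
* **Foraging observations.** At each sampled position: observed count ~
  NB2 with mean = true truncated-mean availability + the (period, bout)
  selection offset (34 / 10 / 20 / 20 berries/m²), dispersion θ = 6;
  sugar analogous with Gaussian noise and offsets taken from the
  fitted-coefficient scale of the quality analysis (−0.35 / −0.99 /
  −0.09 / −0.09 %Brix). A noise-free mode returns expectation + offset
  exactly. Sampling lags are drawn 1–9 days with geometrically decaying
  weights (median 3).
* **Kill times.** A two-component normal mixture on the hour axis
  (morning weight 0.65, means 09:30/17:00, SD 2 h), rejection-sampled into
  the legal window and rounded to the full hour — the recording convention
  for kill registers; draws whose rounded hour would exit the window are
  rejected too, so the bounds hold exactly.
* **Plot offsets.** The deterministic field rule displacing a sample plot
  from the GPS position: magnitude = last digit of Y (0–9 m), direction =
  last digit of X mod 4 → {0: N, 1: E, 2: S, 3: W}. The digit→direction
  mapping is not dictated by the protocol description; the mod-4 map is
  uniform over directions for uniform digits and is configurable.

Because the generator's movement, schedule, and noise are idealized,
passing recovery tests demonstrates the *pipeline's* correctness — that
segmentation, baselines, indices, and selection recover known structure —
not that real bear data meet these assumptions (real step-length
distributions overlap across behaviors, berry abundance is spatially
autocorrelated, and activity profiles are smoother).

## Problem sizes and numerical conventions

Simulation experiments use the study-scale configuration (7 bears × 28
days at 30-min fixes; 154 random plots; ~700 foraging observations per
run). The coverage and selection-consistency experiments use 100 seeds;
selection experiments use n = 2400 fix-level observations per seed,
matching the bout sample sizes of the design. Optimizer tolerances:
Nelder–Mead fatol 10⁻¹⁰–10⁻¹²; BFGS gtol 10⁻⁶–10⁻⁷ with a
gradient-norm acceptance relative to the objective magnitude; quadrature
default 9 nodes. Ties and degenerate inputs error loudly (duplicate
timestamps name the animal and time; rank-deficient designs name the
collinearity; zero counts in the ZTNB likelihood instruct truncation
upstream).

## Known limitations

* Penalized-GAMM smooth estimates are *not* reproduced; the fixed-basis
  df accounting intentionally differs from penalized effective df, and
  only the complexity ordering of the candidate table is asserted.
* The solar module is not a general polar solution; grazing twilight is
  pinned to culmination and polar day/night raise.
* No spatial landscape: habitat at foraging positions is assigned
  independently, and no spatial autocorrelation of berry abundance is
  modeled (the field protocol handled it by sampling design).
* The binomial mixed model supports a single random intercept (the
  design's only random effect), not nested or crossed effects.
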