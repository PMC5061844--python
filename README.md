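# foragerisk

Tools for asking whether an apex predator foregoes foraging when human
hunting makes foraging risky. The motivating system is the Scandinavian
brown bear (*Ursus arctos*) in autumn hyperphagia: bears feed almost
exclusively on bilberries while the hunting season opens mid-period, legal
hunting is confined to daylight (1 h before sunrise to 2 h before sunset),
and risk is concentrated in the morning hours. The package implements the
full analysis pipeline for this question and a synthetic-data generator
with known ground truth, so every stage is testable without field data.

## What the pipeline computes

1. **Trajectory segmentation** (`foragerisk.trajectory`). From 30-min GPS
   fixes, steps are straight-line displacements between consecutive
   positions. Berry foraging is slow, continuous movement: a maximal run of
   valid steps, each 25–300 m, spanning at least 3 steps (1.5 h). Other
   runs of ≥3 positions are "other" behavior; shorter fragments are
   discarded. Field-sampling positions follow the anti-autocorrelation
   rule (second position of each foraging trajectory; second-to-last too
   when the trajectory exceeds 7 positions).
2. **Solar annotation** (`foragerisk.solar`). NOAA-style sunrise/sunset and
   nautical twilight (sun 6–12° below the horizon), the legal hunting
   window (sunrise − 1 h to sunset − 2 h, rounded to the half hour), and
   the split of the day into two 12-h activity bouts at the 10:00 activity
   minimum (morning = 22:00→10:00, afternoon = 10:00→22:00).
3. **Availability baselines** (`foragerisk.baselines`). Random berry plots
   give the forage expected by habitat and date: ripe-berry counts follow
   a zero-truncated negative binomial (NB2, log link),

       P(Y = y | Y ≥ 1) = NB(y; μ, θ) / (1 − (θ/(θ+μ))^θ),
       log μ = β₀ + β₁·clearcut + β₂·julian_date,

   fitted by maximum likelihood with multi-start optimization; sugar
   content (%Brix) is an OLS fit on the same predictors.
4. **Efficiency and quality indices** (`foragerisk.indices`). Foraging
   efficiency = observed berries at a used location − expected berries for
   that habitat and day (berries/m²); forage quality is the analogue on
   the sugar scale. A square-root transform with a recorded additive
   constant handles skew; a lag regression validates that the 1–9 day
   sampling delay does not bias the index.
5. **Candidate-model selection** (`foragerisk.selection`,
   `foragerisk.mixed`). Six models per response and bout — cubic-spline
   time-of-day effects crossed/nested/added with the hunting-period factor,
   down to an intercept-only model, all with a bear-id random intercept —
   are fitted by maximum likelihood (binomial responses via adaptive
   Gauss–Hermite quadrature, normal responses via profiled GLS) and ranked
   by AICc:

       AICc = −2 logL + 2 df + 2 df (df+1) / (n − df − 1),

   selecting the model with fewest df within 2 AICc units of the best.
6. **Synthetic data** (`foragerisk.synthetic`). Tracks with a bimodal
   circadian foraging schedule (peaks 02–07 and 13–20, trough near 10:00;
   the hunting period lowers the morning peak), disjoint per-state
   step-length bands, berry fields with over-dispersed phenology,
   selection offsets of 34 / 10 / 20 / 20 berries/m² for the
   (prehunting/hunting × morning/afternoon) cells, and morning-skewed
   kill times inside the legal window.

## Worked example

```python
from dataclasses import replace
from foragerisk.config import SimConfig
from foragerisk.pipeline import simulate_study, efficiency_recovery

study = simulate_study(config=replace(SimConfig(), seed=7))
table, summary = efficiency_recovery(study)
print(summary[["period", "bout", "n", "mean", "ci_low", "ci_high"]])
```

prints (seed 7):

```
       period       bout    n       mean     ci_low    ci_high
0     hunting  afternoon  194  22.649775  16.582242  28.717308
1     hunting    morning  159  11.464917   5.898124  17.031710
2  prehunting  afternoon  198  20.600447  15.279891  25.921003
3  prehunting    morning  186  35.273233  29.419300  41.127165
```

Each row is one period × bout cell: the mean foraging efficiency (berries
per m² above the availability baseline) with a 95% CI that includes the
baseline-prediction uncertainty. The intervals recover the injected
offsets (34, 10, 20, 20): morning efficiency collapses by a factor ~3 when
hunting starts, while afternoon efficiency is unchanged — the
risk-allocation signature. `examples/` holds one short script per
capability (solar window, segmentation, activity/risk profiles, indices,
model selection); each prints its numbers with a line on what they mean.

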