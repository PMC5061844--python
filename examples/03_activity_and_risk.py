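"""Foraging activity profiles and the circadian distribution of kill risk.

Builds the pooled foraging activity profile per period (prehunting vs
hunting) and the hour-of-day density of simulated legal kills, then
summarises where activity peaks relative to risk.
"""

from dataclasses import replace
from datetime import date

import pandas as pd

from foragerisk import synthetic, trajectory
from foragerisk.config import SimConfig
from foragerisk.solar import hunting_window, solar_times

cfg = replace(SimConfig(), seed=2)
fixes, truth = synthetic.generate_tracks(cfg)
steps = trajectory.build_steps(fixes)
_, labeled = trajectory.classify_foraging(steps)

period = pd.to_datetime(labeled["timestamp"]).dt.date.map(cfg.period_of)
profile = trajectory.activity_profile(labeled, period)

for per in ("prehunting", "hunting"):
    sub = profile[(profile["period"] == per) & (profile["n_fixes"] > 0)]
    peak = sub.loc[sub["p_forage"].idxmax()]
    trough = sub.loc[sub["p_forage"].idxmin()]
    print(f"{per}: peak p(forage) {peak['p_forage']:.2f} at {peak['hour']:.1f} h, "
          f"trough {trough['p_forage']:.2f} at {trough['hour']:.1f} h")

st = solar_times(61.5, 15.05, date(2014, 8, 28), 2.0)
hours = synthetic.generate_kill_times(680, hunting_window(st), seed=3)
dens = trajectory.risk_density(hours)
print(f"\nkill-time density: {100 * dens.iloc[:12].sum():.0f}% of kills before noon "
      f"(modal hour {int(dens.idxmax()):02d}:00)")
print("the morning activity peak overlaps the high-risk morning hours — "
      "the trade-off the hunting-period schedule shift reflects.")
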