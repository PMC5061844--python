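"""Solar events and the legal hunting window at the study site.

Computes sunrise, sunset, nautical twilight, and the legal hunting window
(sunrise - 1 h to sunset - 2 h, rounded to the half hour) for the first
day of the Swedish bear hunting season at the study area in central
Sweden, then shows the shrinking daylength across the four study weeks.
"""

from datetime import date, timedelta

from foragerisk.solar import hunting_window, solar_times, twilight_periods

LAT, LON, TZ = 61.5, 15.05, 2.0  # study-area centroid, local clock UTC+2

st = solar_times(LAT, LON, date(2014, 8, 21), TZ)
w = hunting_window(st)
(dawn, _), (_, dusk_end) = twilight_periods(st)

print(f"first hunting day ({st.date}):")
print(f"  nautical dawn starts {st.nautical_dawn_start:%H:%M}, sunrise {st.sunrise:%H:%M}")
print(f"  sunset {st.sunset:%H:%M}, nautical dusk ends {st.nautical_dusk_end:%H:%M}")
print(f"  legal hunting window {w.start:%H:%M}-{w.end:%H:%M} "
      f"({w.length_hours:.1f} h: daylength minus the two offsets)")

print("\ndaylength over the study period (h):")
for i in (0, 7, 14, 21, 27):
    d = date(2014, 8, 7) + timedelta(days=i)
    print(f"  {d}: {solar_times(LAT, LON, d, TZ).daylength_hours:.2f}")
print("days shorten throughout; bears that avoid daylight lose foraging time.")
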