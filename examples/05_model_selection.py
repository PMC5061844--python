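"""AICc selection among the six candidate mixed models.

Simulates per-fix foraging indicators from a known additive structure
(smooth time-of-day effect plus a hunting-period intercept shift, bear-id
random intercept), fits all six candidates for the morning bout, and
prints the ranked table with Akaike weights and the
fewest-df-within-2-AICc choice.
"""

from foragerisk.selection import run_candidate_set
from foragerisk.synthetic import generate_bout_binomial

data = generate_bout_binomial(n=2400, seed=11)  # truth: daytime + hunt
table, selected = run_candidate_set(data, "forage", "morning", "binomial", k=6)

cols = ["model", "df", "logLik", "AICc", "deltaAICc", "weight"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nselected (fewest df within 2 AICc of the best): {selected}")
print("the additive model wins: richer interaction models cost df without "
      "likelihood gain, and dropping the hunting term loses real fit.")
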