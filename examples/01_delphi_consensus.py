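"""Two Delphi rounds over the risk-item catalog.

Simulates a ten-member panel rating every catalog item on the 1-5 Likert
scale, applies the round-2 convergence step, and summarises each item by its
Median Opinion, 95% confidence interval and consensus flag.
"""

import turbt_complexity as tc
from turbt_complexity.delphi import summarize_matrix

catalog = tc.load_default_catalog()
noise = tc.PanelNoiseModel(noise_sd=0.6, convergence=0.5, seed=7)

round1 = tc.simulate_item_responses(tc.truths_from_catalog(catalog), 10, noise)
round2 = tc.simulate_round2(round1, noise)

for label, responses in [("round 1", round1), ("round 2", round2)]:
    rate, consensual, _ = tc.consensus_rate(summarize_matrix(responses))
    print(f"{label}: consensus on {len(consensual)}/{len(responses.columns)} items "
          f"({rate:.0%})")

example = tc.summarize_item(round2["loc_dome"].to_numpy(), item_id="loc_dome")
print(f"dome: MO {example.median_opinion}, "
      f"95% CI ({example.ci_low:g}, {example.ci_high:g}), "
      f"consensus {example.consensus}")
# The consensus fraction rises between rounds because each panelist moves
# toward the round-1 median; an item is consensual when its CI spans at most
# two adjacent Likert scores.
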