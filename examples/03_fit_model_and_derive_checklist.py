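"""From panel verdicts to a fitted model and a derived checklist.

Screens the five predictor domains by Mann-Whitney tests (entry at p < 0.1),
fits the logistic complexity model, and simplifies it into weight-adjusted
checklist scores (coefficient x Median Opinion, rounded).
"""

import turbt_complexity as tc
from turbt_complexity.scenario_builder import domain_score_frame

catalog = tc.load_default_catalog()
scenarios = tc.generate_scenarios(
    catalog, 400, rules=tc.default_consistency_rules(), seed=5
)
published = tc.load_published_model()
truth = tc.GeneratingModel(
    intercept=published.intercept,
    domain_coefficients=dict(published.coefficients),
    seed=6,
)
outcomes = tc.simulate_outcomes(scenarios, truth)
scores = domain_score_frame(scenarios)

results, kept = tc.screen_from_scores(scores, outcomes.to_numpy(), alpha=0.1)
for domain, r in results.items():
    print(f"  {domain:<10} U={r.statistic:7.1f}  p={r.p_value:.2e}")
print("entering the model:", sorted(kept))

model = tc.fit_logistic(scores[sorted(kept)], outcomes.to_numpy(), domains=sorted(kept))
print("fitted intercept %.2f (truth %.2f)" % (model.intercept, published.intercept))
for d in model.domains:
    print(f"  {d:<10} {model.coefficients[d]:5.2f} (SE {model.std_errors[d]:.2f}, "
          f"truth {published.coefficients[d]:.2f})")

table = tc.derive_checklist(model, catalog)
print(f"derived checklist: {len(table.rows)} rows, e.g.")
for row in table.items_in("location")[:3]:
    print(f"  location  {row.label:<20} weight {row.weight:g}")
# Fitted coefficients land near the generating values, so the derived
# weights approximate the published checklist.
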