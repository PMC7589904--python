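"""Score a clinical case on the published Bladder Complexity Checklist.

The worked case: a patient with a thin bladder wall and a single 3 cm tumour
of the dome, otherwise unremarkable.
"""

import turbt_complexity as tc

checklist = tc.load_published_checklist()
model = tc.load_published_model()
catalog = tc.load_default_catalog()

case = tc.CaseProfile(
    {
        "history": "No relevant history",
        "access": "Thin bladder wall",
        "number": "1-3 tumours",
        "size": "3-5 cm",
        "location": "Dome",
    }
)
result = tc.score_case(checklist, case)
for domain, weight in result.components.items():
    print(f"  {domain:<10} {weight:g}")
print(f"BCCS = {result.value:g}")

scores = {d: catalog.find(item, domain=d).median_opinion
          for d, item in case.selections.items()}
print(f"p(complex) = {tc.predict_probability(model, scores):.3f}")
# The checklist sum of 15 sits in the upper range (5.5-22 are attainable);
# the logistic model maps the same selections to a complexity probability.
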