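# Methods

## Overview

The package reconstructs, as reusable and tested code, a three-step
consensus methodology for quantifying the difficulty of transurethral
bladder-tumour resection: (1) a working definition of a *complex* resection
(incomplete resection, surgery beyond one hour, or a Clavien-Dindo ≥ 3
complication); (2) Delphi scoring of the clinical characteristics that drive
complexity; (3) a logistic model of panel-judged complexity over random
clinical scenarios, simplified into an additive checklist (the Bladder
Complexity Checklist Sum, BCCS) and validated for discrimination and
calibration. The original panel's responses were never deposited, so a
synthetic panel generator reproduces the statistical structure of the study;
everything downstream of the generator is the analysis a real dataset would
receive.

## Delphi aggregation

Panelists rate items on a five-point Likert scale (1 = very unlikely to
impact surgery … 5 = very likely). Each item is summarised by:

- **Median Opinion (MO)** — the sample median; an even panel can produce a
  half-integer, which is rounded *up*, the conservative direction for a
  complexity score.
- **95% confidence interval** — by default the exact distribution-free
  order-statistic interval for the median: the deepest symmetric pair of
  order statistics (x₍ₗ₎, x₍ₙ₊₁₋ₗ₎) whose binomial coverage
  1 − 2·F(l−1; n, ½) is at least 95%. For n = 10 this is (x₍₂₎, x₍₉₎).
  For n < 6 no interior pair reaches 95% and the full range is used. An
  empirical percentile interval (2.5–97.5, linear interpolation) is offered
  as an alternative, because "the 95% CI of a panel's distribution" admits
  both readings; neither is asserted as the original intent.
- **Consensus** — the CI lies within two consecutive integer scores
  (formally: within [k, k+1] for some integer k).

Round two of a Delphi survey feeds the panel's distribution back to the
members. The simulator models the behavioural response as attraction: each
response moves a fraction `convergence` of its distance toward the item's
round-1 median before re-rounding. No behavioural data exist to fit this;
the attraction form is a deliberate stand-in with the right qualitative
property (per-item spread cannot grow, so consensus is monotone across
rounds).

## Scenario construction and classification

A scenario is a vignette: sex, age band, one item per predictor domain
(history, access, number, size, location), and two unscored descriptor slots
(tumour structure, bladder anatomy) kept for presentation realism. Sex
counts follow largest-remainder apportionment of the configured ratio
(2:1 male:female by default, matching bladder-cancer epidemiology; 150
scenarios → exactly 100/50). Clinical-consistency rules (no prostate items
in female scenarios, no prolapse in male ones) are enforced by rejection
sampling with a 1000-attempt cap — rules are sparse, so rejection is cheap
and exact.

Within a domain, items are drawn with half the probability mass on the
domain's baseline item (no relevant history, no access problems, 1–3
tumours, < 3 cm; lowest MO breaks ties) and the remainder uniform
(`baseline_weight = 0.5`; `None` gives fully uniform allocation). The
baseline-weighted default is a deliberate choice: unremarkable findings
dominate real presentations, and fully uniform draws over a catalog of
predominantly high-risk items yield a scenario population in which nearly
every case is complex (prevalence > 0.9), which neither resembles clinical
reality nor supports stable model fitting. Under the default the complex
prevalence among conclusive scenarios is ≈ 0.45 and the conclusive fraction
≈ 0.85, the regime the original study reports (44.2% and 87.3%).

A panel-rated scenario is classified from the 95% CI of its ratings:
**not complex** when the upper bound is at most 2 ("unlikely"), **complex**
when the lower bound is at least 3 ("may occasionally"), **inconclusive**
otherwise. Inconclusive scenarios are dropped before modelling.

## The scenario-rating generator

The generative truth is the published logistic model: with domain scores
x_d ∈ {1..5},

    p = expit(β₀ + Σ_d β_d x_d),  β₀ = −13.34,
    β = (0.99, 0.96, 1.44, 1.04, 1.10) for history, number, location,
    size, access.

A panelist's rating discretises a noisy copy of p through cutpoints
(0.05, 0.2, 0.5, 0.8) on the probability scale, chosen so that the middle
band ("may occasionally", 3) straddles intermediate probabilities. Noise has
two Gaussian components:

- `rating_noise_sd` (default 0.06) — panelist-specific disagreement;
- `scenario_noise_sd` (default 0.2) — a scenario-level offset shared by the
  whole panel, representing case features the five modelled domains do not
  capture.

The scenario-level component is essential, not cosmetic. Consensus
classification thresholds the panel's pooled judgement, so with
panelist-only noise the dichotomized outcome is a nearly deterministic
function of the score vector: the two classes separate completely in
predictor space, maximum-likelihood logistic fits diverge, and discrimination
is trivially perfect. Shared heterogeneity lets scenarios with identical
scores receive different verdicts, which is exactly what an AUC of ≈ 0.92
(rather than 1.0) implies about the real panel. The defaults were set
against the three population quantities the study reports — conclusive
fraction ≈ 0.87, complex prevalence ≈ 0.44, model AUC ≈ 0.92 — and are
configurable.

Two outcome routes are provided and deliberately distinct:

- **Panel route** (`simulate_scenario_ratings` → classify → dichotomize) —
  the structural emulation used by the end-to-end pipeline. Its effective
  link is a noisy threshold, *not* the logistic law, so refitting recovers
  steeper coefficients than the generating ones; this mirrors the original
  design, where the fitted coefficients simply describe the panel's
  behaviour.
- **Bernoulli route** (`simulate_outcomes`) — one draw per scenario at its
  latent probability. This is the scheme under which maximum-likelihood
  refitting is consistent, and it is what the parameter-recovery and
  calibration tests use (n = 4000 recovers β₀ and all five coefficients
  within 3 estimated standard errors in ≥ 19/20 seeds).

## Univariate screening and model fitting

Each predictor domain is screened by a two-tailed Mann–Whitney U test of its
scores between not-complex and complex scenarios, with midranks for ties.
For combined samples of ≤ 12 observations the p-value enumerates all
C(n, n_x) assignments of the pooled ranks (a permutation test on U, exact
under ties); larger samples use the tie-corrected normal approximation with
continuity correction. The normal approximation tracks enumeration to within
0.05 for distinct values with at least two observations per group; with a
singleton group or heavy ties the discrete exact distribution is lumpy and
deviations up to ≈ 0.24 occur, which is why the small-sample path defaults
to enumeration. Domains with p strictly below 0.1 enter the multivariable
model.

The logistic model is fitted by Newton/IRLS (statsmodels) to tight tolerance
(≤ 100 iterations), with standard errors from the inverse observed
information and no regularisation. Complete separation by a single domain is
detected beforehand and reported with the offending domain's name;
multivariate separation surfaces as a fitting error or a diverged solution
(|coefficient| > 50) and is also raised as a separation error. Degenerate
(single-class) outcomes are rejected.

## Checklist derivation and scoring

An item's checklist weight is its domain coefficient times its MO, rounded
to the nearest multiple of a per-domain granularity with ties rounded up.
The granularity is 0.5 for tumour location and 1.0 elsewhere: no single
rounding rule reproduces the published table (1.44×3 → 4.5 needs half-units
while 1.10×3 → 3 needs whole units), and this per-domain map regenerates
every published weight from the published coefficients and the catalog MOs
(verified row for row in the tests). A derived weight that rounds to zero
(possible for a small positive coefficient at MO 1) is floored at one
granularity step, matching the published convention that even baseline items
carry the minimal tick. The published checklist ships as a normative
fixture; two of its weight-6 rows ("anticipate obturator jerk",
"diverticulum") sit ambiguously in the printed layout and are recorded under
the location domain.

Scoring a case selects one item per domain (by id or case-insensitive
label) and sums the weights; the BCCS ranges from 5.5 to 22 under the
published table. Over the full 5⁵ grid of score combinations the BCCS and
the logistic probability agree in ranking with Kendall τ ≥ 0.95.

## Validation

- **ROC/AUC** — curve over all distinct thresholds; the trapezoid area
  equals the tie-adjusted concordance probability (tested against exhaustive
  pair enumeration at 1e-12). AUC variance and the paired test of two scores
  on the same cases use the DeLong placement-value construction; a seeded
  bootstrap (2000 resamples) is available as a cross-check. The asymptotic
  normal 95% CI is reported and labelled as such.
- **Calibration** — slope is the coefficient of the model's own logit in a
  logistic refit; CITL is the intercept of a logistic fit with the logit as
  a fixed offset. An in-sample ML fit recalibrates to slope 1 and CITL 0 to
  numerical precision (the ML score equations), which is the sanity identity
  the pipeline reports. Deciles-of-risk bins (merged below 5 observations)
  are returned for plotting.
- **Predictive values** — PPV = P(complex | score ≥ t) and
  NPV = P(not complex | score < t) per threshold; an empty side is reported
  as undefined with its counts, never as zero.

## Numerical conventions

- Likert rounding is half-up everywhere (toward higher complexity).
- All randomness flows from one seed through named SHA-256-keyed substreams,
  so pipeline stages are independently reproducible and a rerun produces a
  byte-identical manifest.
- Fitted probabilities that round to exactly 0 or 1 in floating point are
  nudged inside (0, 1) before the pipeline's recalibration report;
  `calibration_metrics` itself rejects boundary values.
- CSV dialect: comma-separated UTF-8 with a header row; response matrices
  are panelists × items with integer cells validated on read (violations
  reported with row and column).

## Scope and limitations

- The synthetic generator emulates the *structure* of the study — panel
  sizes, consensus behaviour, prevalence, discrimination — not its data.
  Passing tests show the pipeline's statistics are correct and that the
  study's design parameters yield its reported structure; they cannot
  validate the clinical content of the checklist.
- Catalog MOs were reconstructed by inverting the published weight
  arithmetic; the descriptor-domain items and their MOs are synthetic
  stand-ins for unpublished item lists.
- Panelist-specific bias/leniency, inter-rater reliability statistics, more
  than two Delphi rounds, and natural-language vignette rendering are out of
  scope.
- The univariate screen operates on per-scenario domain scores; published
  per-domain summary medians aggregate items and scenarios in a way that is
  not fully specified, so no numerical agreement with them is asserted.
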