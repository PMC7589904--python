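"""Synthetic expert-panel simulator.

The study data behind the consensus — ten urologists rating ~85 risk items on
a 1-5 Likert scale over two convergent Delphi rounds, then rating 150 clinical
scenarios — was never deposited. This module generates panel responses and
scenario ratings with the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable end to end.

Three generative pieces:

* items: each item has a latent "true" complexity position on the Likert
  scale; a panelist's response is the latent value plus Gaussian noise,
  rounded and clamped to 1..5;
* round two: every response is attracted toward its item's round-1 median by
  a convergence factor, emulating the controlled feedback of a Delphi round;
* scenarios: a latent probability of complex surgery comes from a logistic
  model of the five domain scores; panelists map a noisy copy of that
  probability onto the Likert scale through fixed cutpoints. An optional
  scenario-level noise component (shared by all panelists) represents case
  features the five modelled domains do not capture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import round_half_up
from .catalog import ItemCatalog
from .errors import InvalidInputError
from .scenario_builder import Scenario

#: Likert-band cutpoints on the probability scale. "May occasionally" (3)
#: straddles p = 0.5: a case is rated 3 for latent probabilities in [0.2, 0.5).
DEFAULT_CUTPOINTS: tuple[float, float, float, float] = (0.05, 0.2, 0.5, 0.8)


@dataclass(frozen=True)
class ItemTruth:
    """Latent position of one item on the Likert complexity scale."""

    item_id: str
    latent_complexity: float

    def __post_init__(self):
        if not 1.0 <= self.latent_complexity <= 5.0:
            raise InvalidInputError(
                f"latent_complexity of {self.item_id!r} must be in [1, 5]"
            )


@dataclass(frozen=True)
class PanelNoiseModel:
    """Response noise and round-2 convergence behaviour of the panel.

    ``noise_sd`` perturbs the latent item value before rounding; ``convergence``
    is the fraction of the distance toward the round-1 median that each
    panelist concedes in round two (0 = no adjustment, 1 = full adoption).
    """

    noise_sd: float = 0.6
    convergence: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be nonnegative")
        if not 0.0 <= self.convergence <= 1.0:
            raise InvalidInputError("convergence must be in [0, 1]")


@dataclass(frozen=True)
class GeneratingModel:
    """Logistic generative truth for scenario ratings.

    The latent probability of a complex resection is
    ``expit(intercept + sum_d coef_d * score_d)``. Ratings discretise a noisy
    copy of that probability through ``cutpoints``. ``rating_noise_sd`` is
    panelist-specific noise; ``scenario_noise_sd`` is shared across the panel
    within a scenario and represents unmodelled case features.
    """

    intercept: float
    domain_coefficients: Mapping[str, float]
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    rating_noise_sd: float = 0.06
    scenario_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) != 4 or any(not 0.0 < c < 1.0 for c in cp) or any(
            a >= b for a, b in zip(cp, cp[1:])
        ):
            raise InvalidInputError(
                "cutpoints must be 4 strictly increasing values in (0, 1)"
            )
        object.__setattr__(self, "cutpoints", cp)
        if self.rating_noise_sd < 0 or self.scenario_noise_sd < 0:
            raise InvalidInputError("noise standard deviations must be nonnegative")

    def latent_probability(self, domain_scores: Mapping[str, float]) -> float:
        """Probability of complex surgery for one vector of domain scores."""
        lp = self.intercept
        for domain, coef in self.domain_coefficients.items():
            if domain not in domain_scores:
                raise InvalidInputError(f"scenario is missing a score for domain {domain!r}")
            lp += coef * float(domain_scores[domain])
        return float(expit(lp))


def truths_from_catalog(catalog: ItemCatalog) -> list[ItemTruth]:
    """Use catalog Median Opinions as the latent item positions."""
    return [ItemTruth(it.item_id, float(it.median_opinion)) for it in catalog]


def simulate_item_responses(
    truths: Sequence[ItemTruth],
    n_panelists: int,
    noise: PanelNoiseModel,
) -> pd.DataFrame:
    """Simulate a first Delphi round: panelists x items Likert matrix."""
    truths = list(truths)
    if not truths:
        raise InvalidInputError("truths must be non-empty")
    if n_panelists < 1:
        raise InvalidInputError("n_panelists must be >= 1")
    rng = np.random.default_rng(noise.seed)
    latent = np.array([t.latent_complexity for t in truths])
    raw = latent[None, :] + rng.normal(0.0, noise.noise_sd, size=(n_panelists, len(truths)))
    responses = np.clip(round_half_up(raw), 1, 5).astype(int)
    return pd.DataFrame(
        responses,
        index=[f"P{i + 1:02d}" for i in range(n_panelists)],
        columns=[t.item_id for t in truths],
    )


def simulate_round2(round1: pd.DataFrame, noise: PanelNoiseModel) -> pd.DataFrame:
    """Second Delphi round: responses move toward the round-1 median.

    Each response is shifted by ``convergence`` of its distance to the item's
    round-1 median, then re-rounded (halves up) and clamped. With
    ``convergence = 0`` the output equals ``round1``.
    """
    values = round1.to_numpy()
    if not np.all((values >= 1) & (values <= 5) & (values == np.round(values))):
        raise InvalidInputError("round1 must contain integer Likert responses in 1..5")
    medians = np.median(values, axis=0)
    shifted = values + noise.convergence * (medians[None, :] - values)
    adjusted = np.clip(round_half_up(shifted), 1, 5).astype(int)
    return pd.DataFrame(adjusted, index=round1.index, columns=round1.columns)


def simulate_scenario_ratings(
    scenarios: Sequence[Scenario],
    model: GeneratingModel,
    n_panelists: int,
) -> pd.DataFrame:
    """Panel ratings of clinical scenarios from the logistic generative truth.

    Returns a panelists x scenarios integer matrix. A panelist's rating is the
    Likert band of ``p + scenario noise + panelist noise`` under the model's
    cutpoints, clamped to 1..5.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise InvalidInputError("scenarios must be non-empty")
    if n_panelists < 1:
        raise InvalidInputError("n_panelists must be >= 1")
    p = np.array([model.latent_probability(s.domain_scores) for s in scenarios])
    rng = np.random.default_rng(model.seed)
    noisy = p[None, :].repeat(n_panelists, axis=0)
    if model.scenario_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, model.scenario_noise_sd, size=(1, len(scenarios)))
    if model.rating_noise_sd > 0:
        noisy = noisy + rng.normal(
            0.0, model.rating_noise_sd, size=(n_panelists, len(scenarios))
        )
    cutpoints = np.asarray(model.cutpoints)
    ratings = np.searchsorted(cutpoints, noisy, side="right") + 1
    return pd.DataFrame(
        ratings.astype(int),
        index=[f"P{i + 1:02d}" for i in range(n_panelists)],
        columns=[s.scenario_id for s in scenarios],
    )


def latent_probabilities(
    scenarios: Sequence[Scenario], model: GeneratingModel
) -> pd.Series:
    """Latent complex-surgery probability of each scenario under the model."""
    return pd.Series(
        [model.latent_probability(s.domain_scores) for s in scenarios],
        index=[s.scenario_id for s in scenarios],
        name="latent_p",
    )


def simulate_outcomes(
    scenarios: Sequence[Scenario],
    model: GeneratingModel,
    seed: int | None = None,
) -> pd.Series:
    """Draw binary complexity outcomes directly from the logistic truth.

    One Bernoulli draw per scenario at its latent probability. This is the
    sampling scheme under which refitting the logistic model is consistent,
    and is what parameter-recovery studies should use; the panel-rating route
    (:func:`simulate_scenario_ratings` plus consensus classification) applies
    a threshold-type link instead and does not recover the coefficients.
    """
    p = latent_probabilities(scenarios, model)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    return pd.Series(
        (rng.random(len(p)) < p.to_numpy()).astype(int),
        index=p.index,
        name="complex",
    )
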