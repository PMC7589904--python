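"""Random clinical-scenario construction and panel-based classification.

A scenario is a clinical vignette: sex, an age band, one item per predictor
domain (history, access, tumour number, size, location) and two unscored
descriptor slots (tumour structure, bladder anatomy) kept for presentation
realism. Items are drawn within their domains — by default with half the probability
mass on the domain's baseline item (no relevant history, no access problems,
1-3 tumours, < 3 cm, trigon) and the rest spread uniformly, reflecting that
unremarkable findings dominate clinical presentations; fully uniform
allocation is available via ``baseline_weight=None``. Draws are subject to
clinical consistency rules (e.g. no prostate-related items in female
scenarios), with twice as many male as female scenarios by default, matching
bladder-cancer epidemiology.

A panel-rated scenario is classified from the 95% confidence interval of its
ratings: not complex when the upper bound does not exceed "unlikely" (2),
complex when the lower bound reaches at least "may occasionally" (3), and
inconclusive otherwise. Inconclusive scenarios are dropped before modelling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import substream
from .catalog import DESCRIPTOR_DOMAINS, PREDICTOR_DOMAINS, ItemCatalog
from .delphi import _interval, _validate_scores
from .errors import GenerationExhaustedError, InsufficientDataError, InvalidInputError

#: Default age bands with uniform sampling weights. Age carries a median
#: opinion of 1 ("very unlikely" to impact surgery) and is reported, not scored.
DEFAULT_AGE_BANDS: tuple[str, ...] = ("<60", "60-70", "70-80", ">80")

MAX_ATTEMPTS_PER_SCENARIO = 1000


class ScenarioClass(enum.Enum):
    """Panel verdict on a scenario."""

    NOT_COMPLEX = "not_complex"
    COMPLEX = "complex"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class Scenario:
    """One clinical vignette with its per-domain score vector."""

    scenario_id: str
    sex: str
    age_band: str
    selections: Mapping[str, str]
    domain_scores: Mapping[str, int]
    descriptors: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        missing = [d for d in PREDICTOR_DOMAINS if d not in self.selections]
        if missing:
            raise InvalidInputError(
                f"scenario {self.scenario_id!r} is missing predictor domains: {missing}"
            )
        for d in PREDICTOR_DOMAINS:
            if d not in self.domain_scores:
                raise InvalidInputError(
                    f"scenario {self.scenario_id!r} has no score for domain {d!r}"
                )


@dataclass(frozen=True)
class ConsistencyRule:
    """Clinical-consistency constraint on a scenario draw.

    ``predicate(sex, selections)`` returns True when the combination is
    clinically allowed.
    """

    name: str
    predicate: Callable[[str, Mapping[str, str]], bool]

    def allows(self, sex: str, selections: Mapping[str, str]) -> bool:
        return bool(self.predicate(sex, selections))


#: Items anatomically impossible in female patients.
_FEMALE_FORBIDDEN = frozenset(
    {
        "hist_radical_prostatectomy",
        "acc_large_prostate",
        "acc_very_large_prostate",
        "acc_median_lobe",
        "loc_prostatic_urethra",
    }
)

#: Items anatomically impossible in male patients.
_MALE_FORBIDDEN = frozenset({"acc_prolapse"})


def default_consistency_rules() -> list[ConsistencyRule]:
    """Sex-anatomy rules for the packaged default catalog."""
    return [
        ConsistencyRule(
            "female_no_prostate_items",
            lambda sex, sel: sex != "female"
            or not (_FEMALE_FORBIDDEN & set(sel.values())),
        ),
        ConsistencyRule(
            "male_no_prolapse",
            lambda sex, sel: sex != "male" or not (_MALE_FORBIDDEN & set(sel.values())),
        ),
    ]


def _sex_counts(n: int, sex_ratio: tuple[int, int]) -> tuple[int, int]:
    """Largest-remainder apportionment of n scenarios to (male, female)."""
    m_share, f_share = sex_ratio
    if m_share <= 0 or f_share <= 0:
        raise InvalidInputError("sex_ratio parts must be positive integers")
    total = m_share + f_share
    quotas = (n * m_share / total, n * f_share / total)
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(n - sum(counts)):
        # ties favour the first (male) slot
        idx = 0 if remainders[0] >= remainders[1] else 1
        counts[idx] += 1
        remainders[idx] = -1.0
    return counts[0], counts[1]


def _domain_sampler(
    catalog: ItemCatalog, domain: str, baseline_weight: float | None
) -> tuple[list[str], np.ndarray]:
    """Item ids and draw probabilities for one domain.

    With ``baseline_weight`` set, the domain's lowest-MO item (its clinical
    baseline) receives that probability mass and the remaining items share
    the rest uniformly; ``None`` gives fully uniform allocation.
    """
    items = catalog.items_in(domain)
    ids = [it.item_id for it in items]
    if baseline_weight is None or len(items) == 1:
        return ids, np.full(len(items), 1.0 / len(items))
    if not 0.0 < baseline_weight < 1.0:
        raise InvalidInputError("baseline_weight must be in (0, 1) or None")
    base = int(np.argmin([it.median_opinion for it in items]))
    probs = np.full(len(items), (1.0 - baseline_weight) / (len(items) - 1))
    probs[base] = baseline_weight
    return ids, probs


def generate_scenarios(
    catalog: ItemCatalog,
    n: int,
    sex_ratio: tuple[int, int] = (2, 1),
    rules: Sequence[ConsistencyRule] = (),
    seed: int = 0,
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS,
    baseline_weight: float | None = 0.5,
) -> list[Scenario]:
    """Construct ``n`` random scenarios by per-domain random item allocation.

    Rule-violating draws are rejected and resampled, up to
    :data:`MAX_ATTEMPTS_PER_SCENARIO` attempts per scenario.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    for domain in PREDICTOR_DOMAINS:
        if not catalog.items_in(domain):
            raise InvalidInputError(f"catalog has no items in predictor domain {domain!r}")
    n_male, n_female = _sex_counts(n, sex_ratio)
    rng = substream(seed, "generate_scenarios") if isinstance(seed, int) else seed
    sexes = np.array(["male"] * n_male + ["female"] * n_female)
    rng.shuffle(sexes)

    samplers = {
        d: _domain_sampler(catalog, d, baseline_weight) for d in PREDICTOR_DOMAINS
    }
    descriptor_domains = [d for d in DESCRIPTOR_DOMAINS if catalog.items_in(d)]
    scenarios: list[Scenario] = []
    for i, sex in enumerate(sexes):
        for _ in range(MAX_ATTEMPTS_PER_SCENARIO):
            selections = {
                d: ids[rng.choice(len(ids), p=probs)]
                for d, (ids, probs) in samplers.items()
            }
            if all(rule.allows(sex, selections) for rule in rules):
                break
        else:
            raise GenerationExhaustedError(
                f"could not draw a rule-consistent {sex} scenario in "
                f"{MAX_ATTEMPTS_PER_SCENARIO} attempts"
            )
        descriptors = {
            d: catalog.items_in(d)[rng.integers(len(catalog.items_in(d)))].item_id
            for d in descriptor_domains
        }
        scenarios.append(
            Scenario(
                scenario_id=f"S{i + 1:03d}",
                sex=str(sex),
                age_band=str(age_bands[rng.integers(len(age_bands))]),
                selections=selections,
                domain_scores={
                    d: catalog.get(item).median_opinion for d, item in selections.items()
                },
                descriptors=descriptors,
            )
        )
    return scenarios


def classify_scenario(
    ratings: Sequence[int], ci_method: str = "order_statistic"
) -> ScenarioClass:
    """Consensus classification of one scenario from its panel ratings.

    Not complex when the 95% CI upper bound is at most "unlikely" (2);
    complex when the lower bound is at least "may occasionally" (3);
    inconclusive otherwise.
    """
    arr = _validate_scores(ratings)
    lo, hi = _interval(arr, ci_method)
    if hi <= 2.0:
        return ScenarioClass.NOT_COMPLEX
    if lo >= 3.0:
        return ScenarioClass.COMPLEX
    return ScenarioClass.INCONCLUSIVE


def classify_matrix(
    ratings: pd.DataFrame, ci_method: str = "order_statistic"
) -> pd.Series:
    """Classify every scenario (column) of a panelists x scenarios matrix."""
    if len(ratings.index) < 2:
        raise InsufficientDataError("classification requires at least 2 panelists")
    return pd.Series(
        {
            col: classify_scenario(ratings[col].to_numpy(), ci_method=ci_method)
            for col in ratings.columns
        },
        name="class",
    )


def dichotomize(classes: pd.Series | Mapping[str, ScenarioClass]) -> pd.Series:
    """Binary outcome for modelling: complex -> 1, not complex -> 0.

    Inconclusive scenarios are dropped, mirroring the study design in which
    only consensually judged scenarios entered the analyses.
    """
    series = pd.Series(dict(classes)) if not isinstance(classes, pd.Series) else classes
    kept = series[series != ScenarioClass.INCONCLUSIVE]
    return kept.map({ScenarioClass.COMPLEX: 1, ScenarioClass.NOT_COMPLEX: 0}).astype(int)


# ---------------------------------------------------------------------- I/O


def scenarios_to_frame(scenarios: Iterable[Scenario]) -> pd.DataFrame:
    scenarios = list(scenarios)
    records = []
    for s in scenarios:
        row: dict[str, object] = {
            "scenario_id": s.scenario_id,
            "sex": s.sex,
            "age_band": s.age_band,
        }
        row.update({d: s.selections[d] for d in PREDICTOR_DOMAINS})
        row.update(s.descriptors)
        records.append(row)
    return pd.DataFrame(records)


def scenarios_from_frame(frame: pd.DataFrame, catalog: ItemCatalog) -> list[Scenario]:
    missing = {"scenario_id", "sex", "age_band", *PREDICTOR_DOMAINS} - set(frame.columns)
    if missing:
        raise InvalidInputError(f"scenario table missing columns: {sorted(missing)}")
    descriptor_cols = [d for d in DESCRIPTOR_DOMAINS if d in frame.columns]
    out = []
    for row in frame.itertuples(index=False):
        selections = {d: str(getattr(row, d)) for d in PREDICTOR_DOMAINS}
        out.append(
            Scenario(
                scenario_id=str(row.scenario_id),
                sex=str(row.sex),
                age_band=str(row.age_band),
                selections=selections,
                domain_scores={
                    d: catalog.get(item).median_opinion for d, item in selections.items()
                },
                descriptors={d: str(getattr(row, d)) for d in descriptor_cols},
            )
        )
    return out


def write_scenarios(scenarios: Iterable[Scenario], path: str | Path) -> None:
    scenarios_to_frame(scenarios).to_csv(path, index=False)


def read_scenarios(path: str | Path, catalog: ItemCatalog) -> list[Scenario]:
    return scenarios_from_frame(pd.read_csv(path), catalog)


def domain_score_frame(scenarios: Iterable[Scenario]) -> pd.DataFrame:
    """Scenarios x predictor-domains matrix of MO scores (model design matrix)."""
    scenarios = list(scenarios)
    return pd.DataFrame(
        {d: [s.domain_scores[d] for s in scenarios] for d in PREDICTOR_DOMAINS},
        index=[s.scenario_id for s in scenarios],
    )
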