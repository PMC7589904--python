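"""The Bladder Complexity Checklist and its sum (BCCS).

Each checklist item carries a weight-adjusted score: the regression
coefficient of its domain multiplied by the item's Median Opinion, rounded to
a convenient granularity (half-unit steps for tumour location, whole units
elsewhere — the per-domain map that reproduces every published weight). A
case is scored by selecting the most significant item per domain and summing
the five weights; under the published checklist the sum ranges from 5.5
(nothing remarkable, trigonal tumour) to 22.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_to_multiple
from .catalog import PREDICTOR_DOMAINS, ItemCatalog
from .complexity_model import FittedModel
from .errors import InvalidInputError

#: Rounding granularity per domain. Location weights move in half-unit steps;
#: all other domains in whole units.
DEFAULT_GRANULARITY: Mapping[str, float] = {"location": 0.5}
FALLBACK_GRANULARITY = 1.0


def granularity_for(domain: str, granularity_map: Mapping[str, float] | None) -> float:
    mapping = DEFAULT_GRANULARITY if granularity_map is None else granularity_map
    return float(mapping.get(domain, FALLBACK_GRANULARITY))


@dataclass(frozen=True)
class ChecklistRow:
    domain: str
    item_id: str
    label: str
    weight: float

    def __post_init__(self):
        if not self.weight > 0:
            raise InvalidInputError(
                f"checklist weight of {self.item_id!r} must be positive"
            )


@dataclass(frozen=True)
class CaseProfile:
    """A clinical case: the most significant item selected per domain."""

    selections: Mapping[str, str]

    def __post_init__(self):
        missing = [d for d in PREDICTOR_DOMAINS if d not in self.selections]
        if missing:
            raise InvalidInputError(f"case is missing domains: {missing}")


@dataclass(frozen=True)
class BCCS:
    """Bladder Complexity Checklist Sum with its per-domain components."""

    value: float
    components: Mapping[str, float]


class ChecklistTable:
    """Domain -> (item, weight-adjusted score) rows; summing selected rows
    gives the BCCS."""

    def __init__(self, rows: Iterable[ChecklistRow], provenance: str = "derived"):
        if provenance not in ("published", "derived"):
            raise InvalidInputError(f"unknown provenance {provenance!r}")
        self.rows: list[ChecklistRow] = list(rows)
        self.provenance = provenance
        self._by_id: dict[str, ChecklistRow] = {}
        for row in self.rows:
            if row.item_id in self._by_id:
                raise InvalidInputError(f"duplicate checklist item {row.item_id!r}")
            self._by_id[row.item_id] = row
        if not self.rows:
            raise InvalidInputError("checklist has no rows")
        if provenance == "published":
            present = {row.domain for row in self.rows}
            missing = [d for d in PREDICTOR_DOMAINS if d not in present]
            if missing:
                raise InvalidInputError(
                    f"published checklist is missing predictor domains: {missing}"
                )

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for row in self.rows:
            seen.setdefault(row.domain, None)
        return tuple(seen)

    def items_in(self, domain: str) -> list[ChecklistRow]:
        return [row for row in self.rows if row.domain == domain]

    def find(self, key: str, domain: str | None = None) -> ChecklistRow:
        """Look a row up by item id or case-insensitive label."""
        if key in self._by_id:
            row = self._by_id[key]
            if domain is None or row.domain == domain:
                return row
        folded = key.strip().lower()
        pool = self.rows if domain is None else self.items_in(domain)
        for row in pool:
            if row.label.strip().lower() == folded:
                return row
        where = f" in domain {domain!r}" if domain else ""
        raise InvalidInputError(f"no checklist item matches {key!r}{where}")

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "domain": [r.domain for r in self.rows],
                "item_id": [r.item_id for r in self.rows],
                "label": [r.label for r in self.rows],
                "weight": [r.weight for r in self.rows],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "derived") -> "ChecklistTable":
        required = {"domain", "item_id", "label", "weight"}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidInputError(f"checklist table missing columns: {sorted(missing)}")
        rows = [
            ChecklistRow(
                domain=str(r.domain),
                item_id=str(r.item_id),
                label=str(r.label),
                weight=float(r.weight),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(rows, provenance=provenance)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "derived") -> "ChecklistTable":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)


def weight_adjusted_score(
    coefficient: float, median_opinion: int, granularity: float = 1.0
) -> float:
    """Checklist weight of an item: coefficient x MO, rounded (ties up).

    ``granularity`` is the rounding step (0.5 or 1.0 in the published table).
    """
    if not coefficient > 0:
        raise InvalidInputError("coefficient must be positive")
    if not 1 <= int(median_opinion) <= 5:
        raise InvalidInputError("median_opinion must be in 1..5")
    if granularity <= 0:
        raise InvalidInputError("granularity must be positive")
    return round_to_multiple(coefficient * int(median_opinion), granularity)


def derive_checklist(
    model: FittedModel,
    catalog: ItemCatalog,
    granularity_map: Mapping[str, float] | None = None,
) -> ChecklistTable:
    """Regenerate the checklist from a fitted model and an item catalog.

    One row per catalog item in each of the model's domains the catalog
    covers, weighted by :func:`weight_adjusted_score` at the domain's
    granularity.
    """
    rows = []
    covered = [d for d in model.domains if catalog.items_in(d)]
    if not covered:
        raise InvalidInputError(
            f"catalog covers none of the model domains {list(model.domains)}"
        )
    for domain in covered:
        items = catalog.items_in(domain)
        g = granularity_for(domain, granularity_map)
        coef = model.coefficients[domain]
        for item in items:
            # even baseline items carry the minimal tick on the published
            # checklist, so rounded-to-zero weights are floored at one step
            weight = max(weight_adjusted_score(coef, item.median_opinion, g), g)
            rows.append(
                ChecklistRow(
                    domain=domain,
                    item_id=item.item_id,
                    label=item.label,
                    weight=weight,
                )
            )
    return ChecklistTable(rows, provenance="derived")


def score_case(checklist: ChecklistTable, case: CaseProfile) -> BCCS:
    """Bladder Complexity Checklist Sum of one case.

    Selections may reference items by id or by the checklist's free-text
    labels (case-insensitive). The BCCS is the sum of the selected weights
    over the checklist's domains.
    """
    components: dict[str, float] = {}
    for domain in checklist.domains:
        if domain not in case.selections:
            raise InvalidInputError(f"case is missing a selection for domain {domain!r}")
        row = checklist.find(str(case.selections[domain]), domain=domain)
        components[domain] = row.weight
    return BCCS(value=float(sum(components.values())), components=components)
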