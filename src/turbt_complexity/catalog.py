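"""Risk-item catalog: the clinical characteristics that drive TURBT complexity.

Items are grouped into domains. Five domains (patient history, access to the
bladder cavity, tumour number, size and location) act as predictors in the
complexity model; each item carries the panel's Median Opinion (MO, 1-5) and,
where available, a published weight-adjusted checklist score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import InvalidInputError

#: Domains that enter the logistic complexity model as predictors.
PREDICTOR_DOMAINS: tuple[str, ...] = ("history", "access", "number", "size", "location")

#: Domains generated for scenario realism but never scored or modelled.
DESCRIPTOR_DOMAINS: tuple[str, ...] = ("tumour_structure", "bladder_anatomy")

#: All recognised domains, including those excluded from scenarios.
ALL_DOMAINS: tuple[str, ...] = PREDICTOR_DOMAINS + DESCRIPTOR_DOMAINS + (
    "patient_characteristics",
    "environment",
)


@dataclass(frozen=True)
class CatalogItem:
    """One clinical characteristic with its panel Median Opinion.

    Parameters
    ----------
    item_id:
        Stable identifier, unique within the catalog.
    domain:
        One of :data:`ALL_DOMAINS`.
    label:
        Human-readable description as it appears on the checklist.
    median_opinion:
        Panel median Likert score (1-5) for the item's contribution to
        complexity.
    weight:
        Optional published weight-adjusted checklist score.
    """

    item_id: str
    domain: str
    label: str
    median_opinion: int
    weight: float | None = None

    def __post_init__(self):
        if self.domain not in ALL_DOMAINS:
            raise InvalidInputError(f"unknown domain {self.domain!r} for item {self.item_id!r}")
        if not 1 <= int(self.median_opinion) <= 5:
            raise InvalidInputError(
                f"median_opinion of {self.item_id!r} must be in 1..5, got {self.median_opinion}"
            )
        if self.weight is not None and not self.weight > 0:
            raise InvalidInputError(f"weight of {self.item_id!r} must be positive")


class ItemCatalog:
    """Collection of :class:`CatalogItem` with id/label lookup by domain."""

    def __init__(self, items: Iterable[CatalogItem]):
        self._items: list[CatalogItem] = list(items)
        ids = [it.item_id for it in self._items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidInputError(f"duplicate item ids in catalog: {dupes}")
        self._by_id = {it.item_id: it for it in self._items}

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[CatalogItem]:
        return iter(self._items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def domains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self._items:
            seen.setdefault(it.domain, None)
        return tuple(seen)

    def get(self, item_id: str) -> CatalogItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise InvalidInputError(f"unknown item id {item_id!r}") from None

    def items_in(self, domain: str) -> list[CatalogItem]:
        return [it for it in self._items if it.domain == domain]

    def find(self, key: str, domain: str | None = None) -> CatalogItem:
        """Look an item up by id or by case-insensitive label."""
        if key in self._by_id:
            item = self._by_id[key]
            if domain is None or item.domain == domain:
                return item
        folded = key.strip().lower()
        pool = self._items if domain is None else self.items_in(domain)
        for it in pool:
            if it.label.strip().lower() == folded:
                return it
        where = f" in domain {domain!r}" if domain else ""
        raise InvalidInputError(f"no catalog item matches {key!r}{where}")

    def subset(self, item_ids: Iterable[str]) -> "ItemCatalog":
        keep = set(item_ids)
        return ItemCatalog([it for it in self._items if it.item_id in keep])

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self._items],
                "domain": [it.domain for it in self._items],
                "label": [it.label for it in self._items],
                "median_opinion": [it.median_opinion for it in self._items],
                "weight": [it.weight for it in self._items],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemCatalog":
        required = {"item_id", "domain", "label", "median_opinion"}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidInputError(f"catalog table missing columns: {sorted(missing)}")
        items = []
        for row in frame.itertuples(index=False):
            weight = getattr(row, "weight", None)
            if weight is not None and pd.isna(weight):
                weight = None
            items.append(
                CatalogItem(
                    item_id=str(row.item_id),
                    domain=str(row.domain),
                    label=str(row.label),
                    median_opinion=int(row.median_opinion),
                    weight=None if weight is None else float(weight),
                )
            )
        return cls(items)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ItemCatalog":
        return cls.from_frame(pd.read_csv(path))
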