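"""Packaged fixtures: the published regression, checklist and item catalog.

All three are loaded and schema-validated at import time of the package, so a
corrupted installation fails fast.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import pandas as pd

from .catalog import PREDICTOR_DOMAINS, ItemCatalog
from .checklist import ChecklistTable
from .complexity_model import FittedModel
from .errors import InvalidInputError


def _data_path(name: str):
    return resources.files("turbt_complexity") / "_data" / name


@lru_cache(maxsize=None)
def load_published_model() -> FittedModel:
    """The published five-domain logistic model (intercept -13.34).

    Only the standard errors were published; the fixture's covariance matrix
    is diagonal.
    """
    payload = json.loads(_data_path("published_model.json").read_text())
    model = FittedModel.from_dict(payload)
    if set(model.domains) != set(PREDICTOR_DOMAINS):
        raise InvalidInputError("published model fixture does not cover the five predictor domains")
    if not all(c > 0 for c in model.coefficients.values()):
        raise InvalidInputError("published model fixture must have positive coefficients")
    return model


@lru_cache(maxsize=None)
def load_published_checklist() -> ChecklistTable:
    """The published Bladder Complexity Checklist (weights 1 to 6).

    'Anticipate obturator jerk' and 'Diverticulum' share the dome's weight-6
    row; the fixture records them under the location domain.
    """
    with resources.as_file(_data_path("published_checklist.csv")) as path:
        table = ChecklistTable.read_csv(path, provenance="published")
    bad = [r.item_id for r in table.rows if (2 * r.weight) != int(2 * r.weight)]
    if bad:
        raise InvalidInputError(f"checklist weights must be multiples of 0.5: {bad}")
    return table


@lru_cache(maxsize=None)
def load_default_catalog() -> ItemCatalog:
    """The default item catalog with Median Opinions and published weights."""
    with resources.as_file(_data_path("default_catalog.csv")) as path:
        catalog = ItemCatalog.read_csv(path)
    for domain in PREDICTOR_DOMAINS:
        if not catalog.items_in(domain):
            raise InvalidInputError(f"default catalog has no items in domain {domain!r}")
    return catalog


def validate_fixtures() -> None:
    """Load every packaged fixture, raising on any schema violation."""
    load_published_model()
    load_published_checklist()
    load_default_catalog()
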