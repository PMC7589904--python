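"""Delphi aggregation of Likert panel responses.

Each item rated by the panel is summarised by its Median Opinion (MO) and a
95% confidence interval for the median. An item reaches consensus when that
interval is bounded within two consecutive Likert scores, i.e. the panel's
opinions effectively concentrate on one score or two adjacent ones.

Two interval conventions are offered, because "a 95% confidence interval of
the distribution" of ten ordinal scores admits more than one reading:

``order_statistic`` (default)
    The exact distribution-free confidence interval for the population
    median: the widest symmetric pair of order statistics whose binomial
    coverage is at least 95%. For n = 10 this is (x(2), x(9)).
``percentile``
    The empirical 2.5th-97.5th percentile interval of the responses
    (linear-interpolation quantiles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

CI_METHODS = ("order_statistic", "percentile")


@dataclass(frozen=True)
class ItemSummary:
    """Panel summary for one rated item."""

    item_id: str
    median_opinion: int
    ci_low: float
    ci_high: float
    consensus: bool
    n_responses: int


def _validate_scores(scores: Sequence[int]) -> np.ndarray:
    arr = np.asarray(list(scores))
    if arr.size < 2:
        raise InsufficientDataError(
            f"at least 2 responses are required, got {arr.size}"
        )
    if not np.all((arr == np.round(arr)) & (arr >= 1) & (arr <= 5)):
        raise InvalidInputError("Likert responses must be integers in 1..5")
    return arr.astype(int)


def median_opinion(scores: Sequence[int]) -> int:
    """Sample median, with half-integers rounded up (toward higher complexity)."""
    med = float(np.median(_validate_scores(scores)))
    return int(math.floor(med + 0.5))


@lru_cache(maxsize=None)
def _order_statistic_depth(n: int) -> int:
    """Largest symmetric order-statistic depth with >= 95% binomial coverage.

    Coverage of (x(l), x(n+1-l)) for the median is
    ``1 - 2 * BinomCDF(l - 1; n, 1/2)``. When no interior pair achieves 95%
    (n < 6) the full range (depth 1) is used.
    """
    depth = 1
    for l in range(1, n // 2 + 1):
        if stats.binom.cdf(l - 1, n, 0.5) <= 0.025:
            depth = l
        else:
            break
    return depth


def _order_statistic_ci(sorted_scores: np.ndarray) -> tuple[float, float]:
    """Exact binomial order-statistic interval for the median at >= 95% coverage."""
    n = sorted_scores.size
    depth = _order_statistic_depth(n)
    return float(sorted_scores[depth - 1]), float(sorted_scores[n - depth])


def _percentile_ci(scores: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(scores, [2.5, 97.5])
    return float(lo), float(hi)


def _interval(scores: np.ndarray, ci_method: str) -> tuple[float, float]:
    if ci_method == "order_statistic":
        return _order_statistic_ci(np.sort(scores))
    if ci_method == "percentile":
        return _percentile_ci(scores)
    raise InvalidInputError(f"unknown ci_method {ci_method!r}; expected one of {CI_METHODS}")


def _is_consensus(ci_low: float, ci_high: float) -> bool:
    # bounded within [k, k+1] for some integer k
    return ci_high <= math.floor(ci_low) + 1.0 + 1e-12


def summarize_item(
    scores: Sequence[int],
    ci_method: str = "order_statistic",
    item_id: str = "",
) -> ItemSummary:
    """Summarise one item's panel responses: MO, 95% CI, consensus flag."""
    arr = _validate_scores(scores)
    lo, hi = _interval(arr, ci_method)
    return ItemSummary(
        item_id=item_id,
        median_opinion=median_opinion(arr),
        ci_low=lo,
        ci_high=hi,
        consensus=_is_consensus(lo, hi),
        n_responses=int(arr.size),
    )


def summarize_matrix(
    responses: pd.DataFrame, ci_method: str = "order_statistic"
) -> list[ItemSummary]:
    """Summarise every item (column) of a panelists x items response matrix."""
    return [
        summarize_item(responses[col].to_numpy(), ci_method=ci_method, item_id=str(col))
        for col in responses.columns
    ]


def consensus_rate(
    summaries: Iterable[ItemSummary],
) -> tuple[float, list[str], list[str]]:
    """Fraction of items reaching consensus, with the two id lists.

    Returns ``(fraction, consensual_ids, non_consensual_ids)``; the id lists
    partition the input in order.
    """
    summaries = list(summaries)
    if not summaries:
        raise InvalidInputError("consensus_rate requires at least one item summary")
    yes = [s.item_id for s in summaries if s.consensus]
    no = [s.item_id for s in summaries if not s.consensus]
    return len(yes) / len(summaries), yes, no


def summaries_to_frame(summaries: Iterable[ItemSummary]) -> pd.DataFrame:
    summaries = list(summaries)
    return pd.DataFrame(
        {
            "item_id": [s.item_id for s in summaries],
            "median_opinion": [s.median_opinion for s in summaries],
            "ci_low": [s.ci_low for s in summaries],
            "ci_high": [s.ci_high for s in summaries],
            "consensus": [s.consensus for s in summaries],
            "n_responses": [s.n_responses for s in summaries],
        }
    )
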