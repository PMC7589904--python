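"""Univariate screening and logistic modelling of scenario complexity.

The model regresses the binary panel verdict (complex / not complex) on the
five predictor-domain scores, each coded as the Median Opinion (1-5) of the
scenario's selected item, treated as numeric. The probability of a complex
resection is

    p(complex) = 1 / (1 + exp(-(b0 + sum_d b_d * score_d)))

The published fit (five positive coefficients, intercept -13.34) ships as a
packaged fixture and can be loaded with :func:`load_published_model`.

Domains enter the multivariable model after a two-tailed Mann-Whitney U
screen at p < 0.1. The U test uses midranks for ties; p-values come from
exhaustive enumeration of rank assignments for small samples (combined
n <= 12) and from the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .catalog import PREDICTOR_DOMAINS
from .errors import (
    DegenerateOutcomeError,
    InsufficientDataError,
    InvalidInputError,
    SeparationError,
)

EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its two-tailed p-value."""

    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class FittedModel:
    """Logistic model of complexity: intercept plus per-domain coefficients.

    ``covariance`` is ordered (intercept, *domains) with domains in the order
    of ``coefficients``.
    """

    intercept: float
    coefficients: Mapping[str, float]
    std_errors: Mapping[str, float]
    covariance: np.ndarray
    converged: bool
    n_obs: int
    intercept_std_error: float = float("nan")

    def __post_init__(self):
        if set(self.coefficients) != set(self.std_errors):
            raise InvalidInputError("coefficient and std_error domains differ")
        cov = np.asarray(self.covariance, dtype=float)
        k = len(self.coefficients) + 1
        if cov.shape != (k, k):
            raise InvalidInputError(
                f"covariance must be {k}x{k} (intercept + domains), got {cov.shape}"
            )
        object.__setattr__(self, "covariance", cov)

    @property
    def domains(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def linear_predictor(self, domain_scores: Mapping[str, float]) -> float:
        lp = self.intercept
        for domain, coef in self.coefficients.items():
            if domain not in domain_scores:
                raise InvalidInputError(f"missing score for domain {domain!r}")
            lp += coef * float(domain_scores[domain])
        return lp

    # ------------------------------------------------------------------ I/O

    def to_dict(self) -> dict:
        order = list(self.coefficients)
        return {
            "intercept": self.intercept,
            "intercept_std_error": self.intercept_std_error,
            "domain_order": order,
            "coefficients": {d: self.coefficients[d] for d in order},
            "std_errors": {d: self.std_errors[d] for d in order},
            "covariance": np.asarray(self.covariance).tolist(),
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FittedModel":
        order = list(payload.get("domain_order", payload["coefficients"]))
        coefficients = {d: float(payload["coefficients"][d]) for d in order}
        std_errors = {d: float(payload["std_errors"][d]) for d in order}
        if "covariance" in payload and payload["covariance"] is not None:
            covariance = np.asarray(payload["covariance"], dtype=float)
        else:
            diag = [float(payload.get("intercept_std_error", np.nan)) ** 2]
            diag += [std_errors[d] ** 2 for d in order]
            covariance = np.diag(diag)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients=coefficients,
            std_errors=std_errors,
            covariance=covariance,
            converged=bool(payload.get("converged", True)),
            n_obs=int(payload.get("n_obs", 0)),
            intercept_std_error=float(payload.get("intercept_std_error", np.nan)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of the first sample, from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], method: str | None = None
) -> StatResult:
    """Two-tailed Mann-Whitney U test with midranks for ties.

    For combined samples of at most :data:`EXACT_ENUMERATION_MAX_N`
    observations the p-value enumerates every assignment of the pooled values
    to the two groups (a permutation test on U, exact under ties). Larger
    samples use the tie-corrected normal approximation with continuity
    correction. ``method`` forces ``"exact_enumeration"`` or
    ``"normal_tie_corrected"`` regardless of sample size.
    """
    if method not in (None, "exact_enumeration", "normal_tie_corrected"):
        raise InvalidInputError(f"unknown method {method!r}")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    u_obs = _rank_sum_u(x, y)
    mu = n_x * n_y / 2.0

    use_exact = (
        method == "exact_enumeration"
        or (method is None and n_x + n_y <= EXACT_ENUMERATION_MAX_N)
    )
    if use_exact:
        if n_x + n_y > 2 * EXACT_ENUMERATION_MAX_N:
            raise InvalidInputError("exact enumeration is limited to small samples")
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = n_x * (n_x + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n_x + n_y), n_x):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return StatResult(u_obs, hits / total, "exact_enumeration")

    n = n_x + n_y
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return StatResult(u_obs, 1.0, "normal_tie_corrected")
    z = max(abs(u_obs - mu) - 0.5, 0.0) / math.sqrt(sigma2)
    return StatResult(u_obs, float(2 * stats.norm.sf(z)), "normal_tie_corrected")


def screen_domains(
    domain_pvalues: Mapping[str, float], alpha: float = 0.1
) -> set[str]:
    """Domains entering the multivariable model: strict p < alpha."""
    for domain, p in domain_pvalues.items():
        if not 0.0 <= p <= 1.0:
            raise InvalidInputError(f"p-value for {domain!r} outside [0, 1]: {p}")
    return {d for d, p in domain_pvalues.items() if p < alpha}


def screen_from_scores(
    scores: pd.DataFrame, outcome: Sequence[int], alpha: float = 0.1
) -> tuple[dict[str, StatResult], set[str]]:
    """Mann-Whitney screen of every score column against the binary outcome."""
    y = np.asarray(list(outcome))
    results = {
        str(col): mann_whitney(
            scores[col].to_numpy()[y == 0], scores[col].to_numpy()[y == 1]
        )
        for col in scores.columns
    }
    kept = screen_domains({d: r.p_value for d, r in results.items()}, alpha=alpha)
    return results, kept


def _check_separation(scores: np.ndarray, y: np.ndarray, domains: Sequence[str]) -> None:
    """Raise when a single domain separates the classes completely."""
    for j, domain in enumerate(domains):
        x0, x1 = scores[y == 0, j], scores[y == 1, j]
        if x0.max() < x1.min() or x1.max() < x0.min():
            raise SeparationError(
                f"domain {domain!r} completely separates the outcome classes",
                domain=domain,
            )


def fit_logistic(
    scores: pd.DataFrame | np.ndarray,
    outcome: Sequence[int],
    domains: Sequence[str] | None = None,
) -> FittedModel:
    """Maximum-likelihood logistic fit of complexity on domain scores.

    Newton iterations (IRLS) to tight tolerance; standard errors from the
    inverse observed information. Raises :class:`DegenerateOutcomeError` for a
    single-class outcome and :class:`SeparationError` on detected complete
    separation.
    """
    if isinstance(scores, pd.DataFrame):
        if domains is None:
            domains = [str(c) for c in scores.columns]
        x = scores[list(domains)].to_numpy(dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
        if domains is None:
            domains = list(PREDICTOR_DOMAINS[: x.shape[1]])
    y = np.asarray(list(outcome), dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise InvalidInputError("scores and outcome have incompatible shapes")
    if x.shape[0] < 10:
        raise InsufficientDataError("logistic fit requires at least 10 observations")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        if classes.size == 1:
            raise DegenerateOutcomeError("outcome contains a single class")
        raise InvalidInputError("outcome must be coded 0/1")
    _check_separation(x, y.astype(int), domains)

    exog = sm.add_constant(x, has_constant="add")
    try:
        result = sm.Logit(y, exog).fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        if "separation" in str(exc).lower() or "Singular matrix" in str(exc):
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        raise
    params = np.asarray(result.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params[1:])) > 50:
        raise SeparationError("logistic fit diverged: quasi-complete separation")
    bse = np.asarray(result.bse)
    return FittedModel(
        intercept=float(params[0]),
        coefficients={d: float(params[1 + j]) for j, d in enumerate(domains)},
        std_errors={d: float(bse[1 + j]) for j, d in enumerate(domains)},
        covariance=np.asarray(result.cov_params()),
        converged=bool(result.mle_retvals.get("converged", False)),
        n_obs=int(y.size),
        intercept_std_error=float(bse[0]),
    )


def predict_probability(
    model: FittedModel, domain_scores: Mapping[str, float]
) -> float:
    """Probability of a complex resection for one case's domain scores."""
    return float(expit(model.linear_predictor(domain_scores)))


def predict_probabilities(model: FittedModel, scores: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`predict_probability` over a scenarios x domains frame."""
    missing = [d for d in model.domains if d not in scores.columns]
    if missing:
        raise InvalidInputError(f"score table missing domains: {missing}")
    lp = model.intercept + sum(
        model.coefficients[d] * scores[d].to_numpy(dtype=float) for d in model.domains
    )
    return pd.Series(expit(lp), index=scores.index, name="p_complex")
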