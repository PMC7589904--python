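"""Discrimination, calibration and predictive-value analysis.

Discrimination is quantified by the ROC curve and its area, with the AUC
equal to the tie-adjusted concordance probability; its variance and the
paired comparison of two scores on the same cases use the DeLong
placement-value construction. Calibration follows the standard recalibration
framework: the calibration slope is the coefficient of the model's own logit
in a logistic refit, and calibration-in-the-large (CITL) is the intercept of
a logistic fit with the logit entered as a fixed offset. Predictive values
sweep a threshold over the score: PPV = P(complex | score >= t),
NPV = P(not complex | score < t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .complexity_model import StatResult
from .errors import DegenerateOutcomeError, InvalidInputError


@dataclass(frozen=True)
class ROCResult:
    """ROC curve with trapezoid AUC and asymptotic (DeLong) 95% CI."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci: tuple[float, float]


@dataclass(frozen=True)
class CalibrationResult:
    """Recalibration slope, CITL, and deciles-of-risk bins for plotting."""

    slope: float
    citl: float
    bins: list[tuple[float, float, int]]


@dataclass(frozen=True)
class PredictiveValueTable:
    """PPV/NPV per threshold; a side with no observations is None, not 0."""

    rows: list[tuple[float, float | None, float | None, int, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["threshold", "ppv", "npv", "n_above", "n_below"]
        )


def _validate_labels(labels: Sequence[int]) -> np.ndarray:
    y = np.asarray(list(labels))
    if not np.all(np.isin(y, [0, 1])):
        raise InvalidInputError("labels must be coded 0/1")
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("both outcome classes must be present")
    return y.astype(int)


# ------------------------------------------------------------------- DeLong


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the positive/negative placement values (DeLong V10, V01)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return float(auc), v10, v01


def delong_covariance(
    score_sets: Sequence[Sequence[float]], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k scores on shared cases."""
    y = _validate_labels(labels)
    aucs, v10s, v01s = [], [], []
    for scores in score_sets:
        s = np.asarray(list(scores), dtype=float)
        if s.size != y.size:
            raise InvalidInputError("scores and labels must have equal length")
        auc, v10, v01 = _placements(s, y)
        aucs.append(auc)
        v10s.append(v10)
        v01s.append(v01)
    v10s_arr = np.vstack(v10s)
    v01s_arr = np.vstack(v01s)
    m = v10s_arr.shape[1]
    n = v01s_arr.shape[1]
    s10 = np.cov(v10s_arr, ddof=1) if m > 1 else np.zeros((len(score_sets),) * 2)
    s01 = np.cov(v01s_arr, ddof=1) if n > 1 else np.zeros((len(score_sets),) * 2)
    s10 = np.atleast_2d(s10)
    s01 = np.atleast_2d(s01)
    return np.asarray(aucs), s10 / m + s01 / n


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve over all distinct thresholds with trapezoid AUC and 95% CI."""
    y = _validate_labels(labels)
    s = np.asarray(list(scores), dtype=float)
    if s.size != y.size:
        raise InvalidInputError("scores and labels must have equal length")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    aucs, cov = delong_covariance([s], y)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, auc_ci=ci)


def compare_auc(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> StatResult:
    """Paired two-tailed test of equal AUCs (DeLong construction).

    The statistic is the z-score of the AUC difference; identical or
    rank-equivalent scores give a difference of 0 and p = 1.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size != b.size:
        raise InvalidInputError("scores_a and scores_b must have equal length")
    aucs, cov = delong_covariance([a, b], labels)
    diff = aucs[0] - aucs[1]
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 1e-15:
        return StatResult(0.0, 1.0 if abs(diff) < 1e-12 else 0.0, "delong")
    z = diff / np.sqrt(var)
    return StatResult(float(z), float(2 * stats.norm.sf(abs(z))), "delong")


def compare_auc_bootstrap(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> StatResult:
    """Bootstrap cross-check of :func:`compare_auc` (percentile two-sided p)."""
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    y = _validate_labels(labels)
    if a.size != b.size or a.size != y.size:
        raise InvalidInputError("inputs must have equal length")
    rng = np.random.default_rng(seed)
    obs = _placements(a, y)[0] - _placements(b, y)[0]
    diffs = []
    n = y.size
    while len(diffs) < n_boot:
        idx = rng.integers(n, size=n)
        if np.unique(y[idx]).size < 2:
            continue
        diffs.append(_placements(a[idx], y[idx])[0] - _placements(b[idx], y[idx])[0])
    diffs_arr = np.asarray(diffs)
    # two-sided p from the bootstrap null of zero difference
    p = 2 * min(np.mean(diffs_arr <= 0) + 1 / n_boot, np.mean(diffs_arr >= 0) + 1 / n_boot)
    return StatResult(float(obs), float(min(p, 1.0)), "bootstrap")


# -------------------------------------------------------------- calibration


def _risk_bins(
    predicted: np.ndarray, y: np.ndarray, n_bins: int, min_bin: int
) -> list[tuple[float, float, int]]:
    """Deciles-of-risk bins, merging bins with fewer than ``min_bin`` cases."""
    order = np.argsort(predicted, kind="stable")
    edges = np.linspace(0, predicted.size, n_bins + 1).astype(int)
    groups = [order[lo:hi] for lo, hi in zip(edges[:-1], edges[1:]) if hi > lo]
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and len(merged[-1]) < min_bin:
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    if len(merged) > 1 and len(merged[-1]) < min_bin:
        tail = merged.pop()
        merged[-1] = np.concatenate([merged[-1], tail])
    return [
        (float(predicted[g].mean()), float(y[g].mean()), int(g.size)) for g in merged
    ]


def calibration_metrics(
    predicted: Sequence[float],
    outcomes: Sequence[int],
    n_bins: int = 10,
    min_bin: int = 5,
) -> CalibrationResult:
    """Calibration slope, CITL and deciles-of-risk bins.

    ``predicted`` must lie strictly inside (0, 1); a perfectly calibrated
    in-sample maximum-likelihood fit recalibrates to slope 1 and CITL 0.
    """
    p = np.asarray(list(predicted), dtype=float)
    y = _validate_labels(outcomes)
    if p.size != y.size:
        raise InvalidInputError("predicted and outcomes must have equal length")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise InvalidInputError("predicted probabilities must be strictly in (0, 1)")
    lp = np.log(p / (1.0 - p))
    if np.ptp(lp) == 0.0:
        raise InvalidInputError("constant predicted probability: recalibration undefined")
    slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit(
        tol=1e-12
    )
    citl_fit = sm.GLM(
        y, np.ones((y.size, 1)), family=sm.families.Binomial(), offset=lp
    ).fit(tol=1e-12)
    return CalibrationResult(
        slope=float(slope_fit.params[1]),
        citl=float(citl_fit.params[0]),
        bins=_risk_bins(p, y, n_bins, min_bin),
    )


# --------------------------------------------------------- predictive values


def predictive_values(
    scores: Sequence[float], labels: Sequence[int], thresholds: Sequence[float]
) -> PredictiveValueTable:
    """PPV and NPV at each threshold; empty sides reported as undefined."""
    thresholds = list(thresholds)
    if not thresholds:
        raise InvalidInputError("thresholds must be non-empty")
    s = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(labels))
    if not np.all(np.isin(y, [0, 1])):
        raise InvalidInputError("labels must be coded 0/1")
    if s.size != y.size:
        raise InvalidInputError("scores and labels must have equal length")
    rows = []
    for t in thresholds:
        above = s >= t
        n_above = int(above.sum())
        n_below = int(s.size - n_above)
        ppv = float(y[above].mean()) if n_above else None
        npv = float((1 - y[~above]).mean()) if n_below else None
        rows.append((float(t), ppv, npv, n_above, n_below))
    return PredictiveValueTable(rows=rows)


# ------------------------------------------------------------------- plots


def plot_validation(
    roc_model: ROCResult,
    roc_score: ROCResult,
    calibration: CalibrationResult,
    pv_table: PredictiveValueTable,
    out_prefix,
) -> list[str]:
    """Write ROC, calibration and PPV/NPV sweep figures; returns the paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = str(out_prefix)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc_model.fpr, roc_model.tpr, label=f"model (AUC={roc_model.auc:.3f})")
    ax.plot(roc_score.fpr, roc_score.tpr, label=f"checklist sum (AUC={roc_score.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    path = f"{out_prefix}_roc.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)

    fig, ax = plt.subplots(figsize=(5, 5))
    mean_pred = [b[0] for b in calibration.bins]
    obs = [b[1] for b in calibration.bins]
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.plot(mean_pred, obs, "o-")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed fraction complex")
    ax.set_title(f"slope={calibration.slope:.2f}, CITL={calibration.citl:.2f}")
    fig.tight_layout()
    path = f"{out_prefix}_calibration.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)

    frame = pv_table.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["threshold"], frame["ppv"], "o-", color="tab:red", label="PPV")
    ax.plot(frame["threshold"], frame["npv"], "o-", color="tab:blue", label="NPV")
    ax.set_xlabel("checklist-sum threshold")
    ax.set_ylabel("predictive value")
    ax.legend()
    fig.tight_layout()
    path = f"{out_prefix}_predictive_values.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)
    return paths
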