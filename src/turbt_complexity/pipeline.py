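"""End-to-end synthetic study pipeline.

Reproduces the structure of the consensus study on synthetic data: a
ten-member panel rates the risk-item catalog over two Delphi rounds, 150
random clinical scenarios (2:1 male:female) are rated under the published
logistic truth, consensually judged scenarios are dichotomized, screened by
Mann-Whitney tests, refitted by logistic regression, simplified into a
checklist, and validated (ROC of model vs checklist sum, calibration,
predictive values).

All randomness flows from a single seed through named substreams, so each
stage is independently reproducible. Artifacts are CSV/JSON files plus a
manifest recording every stage, parameter and file hash; a rerun at the same
seed produces a byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import delphi, io, scenario_builder, synthetic_panel
from ._util import substream
from .catalog import PREDICTOR_DOMAINS, ItemCatalog
from .checklist import CaseProfile, ChecklistTable, derive_checklist, score_case
from .complexity_model import (
    FittedModel,
    fit_logistic,
    predict_probabilities,
    screen_from_scores,
)
from .errors import ConfigurationError
from .fixtures import load_default_catalog, load_published_model
from .synthetic_panel import DEFAULT_CUTPOINTS, GeneratingModel, PanelNoiseModel
from .validation import (
    calibration_metrics,
    compare_auc,
    plot_validation,
    predictive_values,
    roc_auc,
)


@dataclass
class PipelineConfig:
    """Design constants of a synthetic study run.

    Defaults reproduce the consensus study's stated design: a 10-member
    panel, 150 scenarios with a 2:1 male:female ratio, a p < 0.1 univariate
    entry rule, and half-unit weight rounding for tumour location.
    """

    seed: int = 0
    panel_size: int = 10
    n_scenarios: int = 150
    sex_ratio: tuple[int, int] = (2, 1)
    alpha_screen: float = 0.1
    ci_method: str = "order_statistic"
    granularity_map: Mapping[str, float] | None = None
    noise_sd: float = 0.6
    convergence: float = 0.5
    rating_noise_sd: float = 0.06
    scenario_noise_sd: float = 0.2
    baseline_weight: float | None = 0.5
    cutpoints: tuple[float, float, float, float] = DEFAULT_CUTPOINTS
    catalog_path: str | None = None
    synthetic: bool = True
    make_plots: bool = False

    def __post_init__(self):
        if self.panel_size < 2:
            raise ConfigurationError("panel_size must be >= 2")
        if self.n_scenarios < 1:
            raise ConfigurationError("n_scenarios must be >= 1")
        if not self.synthetic and self.catalog_path is None:
            raise ConfigurationError("non-synthetic mode requires a catalog path")


@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run."""

    config: PipelineConfig
    catalog: ItemCatalog
    round1: pd.DataFrame
    round2: pd.DataFrame
    summaries_round1: list
    summaries_round2: list
    consensus_round1: float
    consensus_round2: float
    scenarios: list
    ratings: pd.DataFrame
    classes: pd.Series
    outcomes: pd.Series
    screen_results: dict
    screened_domains: set
    model: FittedModel
    probabilities: pd.Series
    checklist: ChecklistTable
    bccs: pd.Series
    report: dict
    manifest: dict = field(default_factory=dict)


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study; optionally write artifacts to ``out_dir``."""
    catalog = (
        ItemCatalog.read_csv(config.catalog_path)
        if config.catalog_path
        else load_default_catalog()
    )

    # --- Delphi rounds over the item catalog -----------------------------
    noise = PanelNoiseModel(
        noise_sd=config.noise_sd,
        convergence=config.convergence,
        seed=int(substream(config.seed, "panel_round1").integers(2**31)),
    )
    truths = synthetic_panel.truths_from_catalog(catalog)
    round1 = synthetic_panel.simulate_item_responses(truths, config.panel_size, noise)
    round2 = synthetic_panel.simulate_round2(round1, noise)
    summaries1 = delphi.summarize_matrix(round1, ci_method=config.ci_method)
    summaries2 = delphi.summarize_matrix(round2, ci_method=config.ci_method)
    rate1, _, _ = delphi.consensus_rate(summaries1)
    rate2, consensual_ids, _ = delphi.consensus_rate(summaries2)

    # Scenario construction uses the items that reached consensus; a domain
    # whose items all failed falls back to its full item list.
    consensual = catalog.subset(consensual_ids)
    scenario_catalog_items = []
    for domain in catalog.domains:
        kept = consensual.items_in(domain)
        scenario_catalog_items.extend(kept if kept else catalog.items_in(domain))
    scenario_catalog = ItemCatalog(scenario_catalog_items)

    # --- scenarios and panel ratings --------------------------------------
    scenarios = scenario_builder.generate_scenarios(
        scenario_catalog,
        config.n_scenarios,
        sex_ratio=config.sex_ratio,
        rules=scenario_builder.default_consistency_rules(),
        seed=substream(config.seed, "scenarios"),
        baseline_weight=config.baseline_weight,
    )
    published = load_published_model()
    generator = GeneratingModel(
        intercept=published.intercept,
        domain_coefficients=dict(published.coefficients),
        cutpoints=config.cutpoints,
        rating_noise_sd=config.rating_noise_sd,
        scenario_noise_sd=config.scenario_noise_sd,
        seed=int(substream(config.seed, "ratings").integers(2**31)),
    )
    ratings = synthetic_panel.simulate_scenario_ratings(
        scenarios, generator, config.panel_size
    )
    classes = scenario_builder.classify_matrix(ratings, ci_method=config.ci_method)
    outcomes = scenario_builder.dichotomize(classes)

    # --- screening and model fit ------------------------------------------
    scores = scenario_builder.domain_score_frame(scenarios).loc[outcomes.index]
    screen_results, screened = screen_from_scores(
        scores, outcomes.to_numpy(), alpha=config.alpha_screen
    )
    model_domains = [d for d in PREDICTOR_DOMAINS if d in screened]
    if not model_domains:
        raise ConfigurationError("no domain passed the univariate screen")
    model = fit_logistic(scores[model_domains], outcomes.to_numpy(), domains=model_domains)
    probabilities = predict_probabilities(model, scores)

    # --- checklist and validation ------------------------------------------
    # only positively weighted domains can appear on a checklist whose rows
    # add risk; a domain fitted with a nonpositive coefficient is left off
    checklist_model = model
    while any(c <= 0 for c in checklist_model.coefficients.values()):
        keep = [d for d, c in checklist_model.coefficients.items() if c > 0]
        if not keep:
            raise ConfigurationError("no domain carries positive checklist weight")
        checklist_model = fit_logistic(scores[keep], outcomes.to_numpy(), domains=keep)
    checklist = derive_checklist(checklist_model, scenario_catalog, config.granularity_map)
    scenario_by_id = {s.scenario_id: s for s in scenarios}
    bccs = pd.Series(
        {
            sid: score_case(
                checklist,
                CaseProfile(selections=dict(scenario_by_id[sid].selections)),
            ).value
            for sid in outcomes.index
        },
        name="bccs",
    )

    y = outcomes.to_numpy()
    roc_model = roc_auc(probabilities.to_numpy(), y)
    roc_bccs = roc_auc(bccs.to_numpy(), y)
    comparison = compare_auc(probabilities.to_numpy(), bccs.to_numpy(), y)
    # steep fits can round predicted probabilities to exactly 0/1 in floating
    # point; nudge them inside (0, 1) for the recalibration report
    clipped = np.clip(probabilities.to_numpy(), 1e-12, 1 - 1e-12)
    calibration = calibration_metrics(clipped, y)
    pv = predictive_values(
        bccs.to_numpy(), y, thresholds=sorted(set(bccs.to_numpy()))
    )

    report = {
        "n_scenarios": config.n_scenarios,
        "n_conclusive": int(outcomes.size),
        "prevalence_complex": float(np.mean(y)),
        "consensus_rate_round1": rate1,
        "consensus_rate_round2": rate2,
        "screen_p_values": {d: r.p_value for d, r in screen_results.items()},
        "screened_domains": sorted(screened),
        "model": model.to_dict(),
        "auc_model": roc_model.auc,
        "auc_model_ci": list(roc_model.auc_ci),
        "auc_bccs": roc_bccs.auc,
        "auc_bccs_ci": list(roc_bccs.auc_ci),
        "auc_difference": roc_model.auc - roc_bccs.auc,
        "compare_auc_p": comparison.p_value,
        "calibration_slope": calibration.slope,
        "citl": calibration.citl,
        "calibration_bins": [list(b) for b in calibration.bins],
        "predictive_values": [list(r) for r in pv.rows],
    }

    result = PipelineResult(
        config=config,
        catalog=catalog,
        round1=round1,
        round2=round2,
        summaries_round1=summaries1,
        summaries_round2=summaries2,
        consensus_round1=rate1,
        consensus_round2=rate2,
        scenarios=scenarios,
        ratings=ratings,
        classes=classes,
        outcomes=outcomes,
        screen_results=screen_results,
        screened_domains=screened,
        model=model,
        probabilities=probabilities,
        checklist=checklist,
        bccs=bccs,
        report=report,
    )

    if out_dir is not None:
        result.manifest = _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config

    io.write_panel_responses(result.round1, out_dir / "round1_responses.csv")
    io.write_panel_responses(result.round2, out_dir / "round2_responses.csv")
    delphi.summaries_to_frame(result.summaries_round2).to_csv(
        out_dir / "item_summaries.csv", index=False
    )
    scenario_builder.write_scenarios(result.scenarios, out_dir / "scenarios.csv")
    io.write_ratings(result.ratings, out_dir / "scenario_ratings.csv")
    classes = pd.DataFrame(
        {
            "scenario_id": result.classes.index,
            "class": [c.value for c in result.classes],
        }
    )
    classes.to_csv(out_dir / "scenario_classes.csv", index=False)
    result.model.to_json(out_dir / "model.json")
    result.checklist.to_csv(out_dir / "checklist.csv")
    result.bccs.rename_axis("scenario_id").to_csv(out_dir / "bccs.csv")
    (out_dir / "validation.json").write_text(json.dumps(result.report, indent=1))
    if config.make_plots:
        plot_validation(
            roc_auc(result.probabilities.to_numpy(), result.outcomes.to_numpy()),
            roc_auc(result.bccs.to_numpy(), result.outcomes.to_numpy()),
            calibration_metrics(
                result.probabilities.to_numpy(), result.outcomes.to_numpy()
            ),
            predictive_values(
                result.bccs.to_numpy(),
                result.outcomes.to_numpy(),
                thresholds=sorted(set(result.bccs.to_numpy())),
            ),
            out_dir / "validation",
        )

    artifacts = [
        "round1_responses.csv",
        "round2_responses.csv",
        "item_summaries.csv",
        "scenarios.csv",
        "scenario_ratings.csv",
        "scenario_classes.csv",
        "model.json",
        "checklist.csv",
        "bccs.csv",
        "validation.json",
    ]
    cfg = dataclasses.asdict(config)
    cfg["sex_ratio"] = list(config.sex_ratio)
    cfg["cutpoints"] = list(config.cutpoints)
    cfg["granularity_map"] = (
        dict(config.granularity_map) if config.granularity_map else None
    )
    manifest = {
        "config": cfg,
        "stages": [
            {"stage": "delphi_round1", "consensus_rate": result.consensus_round1},
            {"stage": "delphi_round2", "consensus_rate": result.consensus_round2},
            {"stage": "scenarios", "n": len(result.scenarios)},
            {"stage": "classification", "n_conclusive": int(result.outcomes.size)},
            {"stage": "model_fit", "domains": list(result.model.domains)},
            {"stage": "validation", "auc_model": result.report["auc_model"]},
        ],
        "artifacts": {
            name: _file_sha256(out_dir / name) for name in artifacts
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
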