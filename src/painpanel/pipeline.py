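"""End-to-end orchestration: cohort -> filters -> fits -> functionals -> costs.

``run_pipeline`` sequences the analysis stages, writing machine-readable JSON
(and CSV pathway curves) plus human-readable text to an output directory,
with a run manifest recording the configuration hash, seed and library
versions so that identical configuration and seed reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .costs import (
    CostingAssumptions,
    CostSchedule,
    full_cost_report,
    report_to_json,
    report_to_text,
)
from .episodes import (
    Episode,
    FilterCriteria,
    apply_inclusion_filters,
    impute_baseline,
    read_episodes_csv,
)
from .model import ModelSpec, PainPanelModel
from .pathways import (
    faster_relief_test,
    predict_pathway,
    scenario_from_results,
    severe_exit_estimate,
    trough_level,
    trough_time_estimate,
)
from .simulate import CohortConfig, generate_cohort

logger = logging.getLogger("painpanel")


class PipelineConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_csv: str | None = None
    cohort: CohortConfig | None = None
    comparisons: tuple[str, ...] = ("entonox",)
    spec: ModelSpec = field(default_factory=ModelSpec)
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    schedule: CostSchedule = field(default_factory=CostSchedule)
    assumptions: CostingAssumptions = field(default_factory=CostingAssumptions)
    output_dir: str = "painpanel_run"
    seed: int = 0
    per_protocol: bool = False

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise PipelineConfigError("at least one comparison is required")
        if self.input_csv is None and self.cohort is None:
            self.cohort = CohortConfig(
                arms=("methoxyflurane",) + tuple(self.comparisons), seed=self.seed
            )

    def digest(self) -> str:
        blob = json.dumps(
            {
                "input_csv": self.input_csv,
                "comparisons": list(self.comparisons),
                "seed": self.seed,
                "n_per_arm": self.cohort.n_per_arm if self.cohort else None,
                "n_categories": self.spec.n_categories,
                "per_protocol": self.per_protocol,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def summarize_sample(episodes: list[Episode]) -> dict:
    """Per-arm descriptive table of baseline (S0) and final (ST) scores.

    Episodes must be baseline-imputed. Reports n, mean/sd of S0 and ST, the
    per-score percentage distribution of each, and mean/sd/range of the
    first-to-baseline lead time and baseline-to-final duration. Standard
    deviations are reported as missing for single-episode arms; empty arms
    are omitted.
    """
    out: dict[str, dict] = {}
    by_arm: dict[str, list[Episode]] = {}
    for ep in episodes:
        by_arm.setdefault(ep.arm, []).append(ep)
    for arm, eps in by_arm.items():
        if not eps:
            logger.warning("arm %s has no episodes; omitted from summary", arm)
            continue
        s0 = np.array([ep.baseline_score() for ep in eps], dtype=float)
        st = np.array([ep.observations[-1].score for ep in eps], dtype=float)
        leads = np.array(
            [
                ep.baseline_lead_time_min
                if ep.baseline_lead_time_min is not None
                else -min(0.0, ep.observations[0].time_min)
                for ep in eps
            ]
        )
        durations = np.array([ep.observations[-1].time_min for ep in eps])

        def _stats(x: np.ndarray) -> dict:
            return {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else None,
                "range": [float(np.min(x)), float(np.max(x))],
            }

        def _dist(x: np.ndarray) -> dict:
            return {
                str(k): round(100.0 * float(np.mean(x == k)), 1) for k in range(11)
            }

        out[arm] = {
            "n": len(eps),
            "S0": {**_stats(s0), "percent_by_score": _dist(s0)},
            "ST": {**_stats(st), "percent_by_score": _dist(st)},
            "first_to_baseline_min": _stats(leads),
            "baseline_to_final_min": _stats(durations),
        }
    return out


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs; returns the run report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage: load/generate episodes")
    if config.input_csv is not None:
        episodes = read_episodes_csv(config.input_csv)
    else:
        episodes = generate_cohort(config.cohort)
    logger.info("  %d episodes in", len(episodes))

    logger.info("stage: inclusion filters")
    retained, attrition = apply_inclusion_filters(episodes, config.filter_criteria)
    logger.info("  %d episodes retained", attrition.n_retained)
    (out / "attrition.json").write_text(attrition.to_json() + "\n")
    (out / "attrition.txt").write_text(attrition.to_text() + "\n")

    logger.info("stage: baseline imputation")
    imputed = [impute_baseline(ep) for ep in retained]

    summary = summarize_sample(imputed)
    _json_dump(summary, out / "sample_summary.json")

    report: dict = {
        "manifest": {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config_digest": config.digest(),
            "seed": config.seed,
        },
        "attrition": attrition.to_dict(),
        "comparisons": {},
    }

    for comparator in config.comparisons:
        logger.info("stage: fit methoxyflurane vs %s", comparator)
        sample = [
            ep for ep in imputed if ep.arm in ("methoxyflurane", comparator)
        ]
        if config.per_protocol:
            from .episodes import per_protocol_sample

            sample, pp_report = per_protocol_sample(sample)
            logger.info("  per-protocol removal: %s", pp_report)
        results = PainPanelModel(sample, config.spec).fit()
        _json_dump(results.to_dict(), out / f"fit_{comparator}.json")

        scenario = scenario_from_results(results)
        functionals: dict = {}
        for arm in results.arms:
            tt = trough_time_estimate(results, arm)
            functionals[arm] = {
                "trough_time_min": tt.to_dict(),
                "trough_level_latent": trough_level(scenario, arm).to_dict(),
                "severe_exit_min": severe_exit_estimate(
                    results, arm, scenario
                ).to_dict(),
            }
        try:
            functionals["faster_relief_p"] = faster_relief_test(results).p_value
        except ValueError as err:
            functionals["faster_relief_p"] = None
            logger.warning("faster-relief test unavailable: %s", err)
        _json_dump(functionals, out / f"functionals_{comparator}.json")

        curves = predict_pathway(results, scenario, transform_to_vnps=True)
        curves.to_csv(out / f"pathway_curves_{comparator}.csv", index=False)

        report["comparisons"][comparator] = {
            "fit": results.to_dict(),
            "functionals": functionals,
        }

    logger.info("stage: costs")
    cost_report = full_cost_report(config.schedule, config.assumptions)
    (out / "costs.json").write_text(report_to_json(cost_report) + "\n")
    (out / "costs.txt").write_text(report_to_text(cost_report) + "\n")
    report["costs"] = cost_report

    _json_dump(report["manifest"], out / "manifest.json")
    logger.info("pipeline complete: %s", out)
    return report
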