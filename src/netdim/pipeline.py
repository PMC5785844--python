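"""End-to-end dimensionality workflow and report rendering.

Runs the full comparison on one dataset: exploratory factoring with
eigenvalue-based counts, a one-factor confirmatory fit, bootstrap
exploratory graph analysis, a confirmatory fit of the structure the
bootstrap proposes, and a nested chi-square comparison between the two.
Given a seed, the numeric content of the report is fully deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .community import EGASettings, bootstrap_ega, modal_partition
from .factors import (
    CFAFit,
    FactorModelSpec,
    builtin_spec,
    cfa_fit_correlation,
    compare_models,
    efa_fit,
    parallel_analysis,
    scree_elbow,
)
from .network import nearest_positive_definite, pearson_correlation, polychoric_correlation
from .scale import DS_ES_32, ItemResponseMatrix, load_responses
from .simulate import SCENARIOS, scenario_config, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "render_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full run.

    Exactly one of ``input_path`` (responses CSV) or ``preset`` (named
    simulation scenario) must be given.
    """

    input_path: str | None = None
    preset: str | None = None
    n: int | None = None  # sample size for preset data
    seed: int = 0
    corr_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    steps: int = 4
    bootstrap_B: int = 1000
    estimator: str = "ml"
    extra_specs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("give exactly one of input_path or preset")
        if self.preset is not None and self.preset not in SCENARIOS:
            raise ValueError(f"unknown preset {self.preset!r}; available: {SCENARIOS}")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return {
            "input_path": self.input_path,
            "preset": self.preset,
            "n": self.n,
            "seed": self.seed,
            "corr_method": self.corr_method,
            "gamma": self.gamma,
            "n_lambda": self.n_lambda,
            "steps": self.steps,
            "bootstrap_B": self.bootstrap_B,
            "estimator": self.estimator,
            "extra_specs": list(self.extra_specs),
        }


@dataclass
class PipelineReport:
    config: PipelineConfig
    stages: dict[str, Any]
    warnings: list[str]
    timestamp: str
    version: str


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _spec_from_membership(
    membership: np.ndarray,
    pcor: np.ndarray,
    scale,
) -> tuple[FactorModelSpec, list[str]]:
    """Concrete confirmatory spec from a community membership vector.

    Isolated items (label 0) are excluded.  Singleton communities are not
    identified as factors, so each is merged into the community to which
    its item has the largest total absolute partial correlation; merges are
    logged and returned.
    """
    notes: list[str] = []
    labels = membership.copy()
    ids = np.asarray(scale.item_ids)
    for _ in range(scale.p):  # at most p merges
        uniq, counts = np.unique(labels[labels > 0], return_counts=True)
        singles = uniq[counts == 1]
        if singles.size == 0 or uniq.size == 1:
            break
        s = int(singles[0])
        i = int(np.flatnonzero(labels == s)[0])
        best_c, best_w = None, -1.0
        for c in uniq:
            if c == s:
                continue
            w = float(np.sum(np.abs(pcor[i, labels == c])))
            if w > best_w:
                best_w, best_c = w, int(c)
        labels[i] = best_c
        notes.append(
            f"singleton community of item {ids[i]} merged into community {best_c}"
        )
    assignments: dict[str, tuple[int, ...]] = {}
    for c in sorted(set(labels[labels > 0])):
        assignments[f"dimension_{c}"] = tuple(int(i) for i in ids[labels == c])
    spec = FactorModelSpec(name="ega_derived", assignments=assignments,
                           correlated_factors=True)
    return spec, notes


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run EFA -> one-factor CFA -> bootstrap EGA -> EGA-derived CFA ->
    model comparison, collecting per-stage results and warnings."""
    collector = _WarningCollector()
    logging.getLogger("netdim").addHandler(collector)
    stages: dict[str, Any] = {}
    try:
        # --- data ---
        if config.preset is not None:
            sim_config = scenario_config(config.preset, n=config.n, seed=config.seed)
            dataset = simulate_dataset(sim_config)
            matrix = dataset.responses
            stages["data"] = {
                "source": f"preset:{config.preset}",
                "n": matrix.n,
                "p": matrix.p,
                "true_membership": dataset.true_membership.tolist(),
            }
        else:
            matrix = load_responses(config.input_path)
            stages["data"] = {
                "source": str(config.input_path),
                "n": matrix.n,
                "p": matrix.p,
                "dropped_rows": matrix.dropped_rows,
            }

        corr = pearson_correlation(matrix)
        corr_pd = nearest_positive_definite(corr)

        # --- exploratory factoring ---
        try:
            efa1 = efa_fit(corr_pd, k=1)
            pa_count = parallel_analysis(matrix, seed=config.seed)
            stages["efa"] = {
                "eigenvalues": [round(float(e), 6) for e in efa1.eigenvalues],
                "scree_count": scree_elbow(efa1.eigenvalues),
                "parallel_analysis_count": pa_count,
                "one_factor_variance_explained": round(float(efa1.variance_explained[0]), 6),
                "one_factor_loadings": [round(float(l), 6) for l in efa1.loadings[:, 0]],
                "heywood": efa1.heywood,
            }
        except Exception as exc:  # independent stage: record and continue
            stages["efa"] = {"error": str(exc)}

        # --- one-factor CFA ---
        one_factor = builtin_spec("one_factor_32") if matrix.p == 32 else FactorModelSpec(
            name="one_factor", assignments={"general": tuple(matrix.scale.item_ids)})
        try:
            fit1 = cfa_fit_correlation(corr_pd.matrix, corr_pd.n, one_factor,
                                       estimator="ml", scale=matrix.scale)
            stages["cfa_one_factor"] = _fit_to_dict(fit1)
        except Exception as exc:
            stages["cfa_one_factor"] = {"error": str(exc)}
            fit1 = None

        # --- bootstrap EGA ---
        settings = EGASettings(corr_method=config.corr_method, gamma=config.gamma,
                               n_lambda=config.n_lambda, steps=config.steps)
        boot = bootstrap_ega(matrix, B=config.bootstrap_B, seed=config.seed,
                             settings=settings)
        stages["bootstrap_ega"] = {
            "B": boot.B,
            "median_dimensions": boot.median_dimensions,
            "n_dimensions": boot.n_dimensions,
            "frequency_table": {str(k): round(v, 6) for k, v in boot.frequency_table.items()},
            "sample_membership": boot.sample_result.membership.tolist(),
            "sample_n_dimensions": boot.sample_result.n_dimensions,
            "isolated_items": list(boot.sample_result.isolated_nodes),
            "edge_count": boot.sample_result.network.edge_count,
            "lambda_selected": round(float(boot.sample_result.network.lambda_selected), 8),
            "replicates_failed": boot.n_failed,
        }

        # --- EGA-derived CFA + comparison ---
        partition = modal_partition(boot)
        ega_spec, merge_notes = _spec_from_membership(
            partition, boot.sample_result.network.partial_correlations, matrix.scale)
        stages["bootstrap_ega"]["modal_partition"] = partition.tolist()
        if ega_spec.k == 1:
            stages["cfa_ega"] = {"skipped": "EGA-derived model is the one-factor model"}
            stages["comparison"] = {"skipped": "models identical"}
        else:
            try:
                fit_ega = cfa_fit_correlation(corr_pd.matrix, corr_pd.n, ega_spec,
                                              estimator="ml", scale=matrix.scale)
                d = _fit_to_dict(fit_ega)
                d["merge_notes"] = merge_notes
                d["assignments"] = {k: list(v) for k, v in ega_spec.assignments.items()}
                stages["cfa_ega"] = d
                # nested comparison needs both models on the same item set
                one_same_items = FactorModelSpec(
                    name="one_factor_same_items",
                    assignments={"general": tuple(ega_spec.item_ids)})
                fit1_same = cfa_fit_correlation(corr_pd.matrix, corr_pd.n, one_same_items,
                                                estimator="ml", scale=matrix.scale)
                comp = compare_models(fit1_same, fit_ega)
                stages["comparison"] = {
                    "restricted": comp.restricted,
                    "general": comp.general,
                    "delta_chi_square": round(comp.delta_chi_square, 6),
                    "delta_df": comp.delta_df,
                    "p_value": float(comp.p_value),
                    "preferred": comp.preferred,
                }
            except Exception as exc:
                stages["cfa_ega"] = {"error": str(exc)}
                stages["comparison"] = {"skipped": f"EGA-derived CFA failed: {exc}"}
    finally:
        logging.getLogger("netdim").removeHandler(collector)

    return PipelineReport(
        config=config,
        stages=stages,
        warnings=collector.messages,
        timestamp=datetime.now(timezone.utc).isoformat(),
        version=__version__,
    )


def _fit_to_dict(fit: CFAFit) -> dict[str, Any]:
    return {
        "model": fit.spec.name,
        "estimator": fit.estimator,
        "chi_square": round(float(fit.chi_square), 6),
        "df": fit.df,
        "cfi": round(float(fit.cfi), 6),
        "rmsea": round(float(fit.rmsea), 6),
        "srmr": round(float(fit.srmr), 6),
        "converged": fit.converged,
        "loadings": {str(k): round(v, 6) for k, v in fit.loading_estimates.items()},
        "factor_correlations": np.round(fit.factor_correlation_estimates, 6).tolist(),
        "factor_labels": list(fit.factor_labels),
    }


def render_report(report: PipelineReport, format: str = "json") -> str:
    """Serialize a pipeline report.  ``json`` is machine-readable (numeric
    content deterministic given the seed); ``markdown`` is a human summary
    with loadings, fit-index lines and the bootstrap frequency table."""
    body = {
        "config": report.config.to_dict(),
        "stages": report.stages,
        "warnings": report.warnings,
        "provenance": {"version": report.version, "timestamp": report.timestamp},
    }
    if format == "json":
        return json.dumps(body, indent=2)
    if format != "markdown":
        raise ValueError("format must be 'json' or 'markdown'")

    lines = ["# Dimensionality report", ""]
    lines.append(f"Config: `{json.dumps(report.config.to_dict())}`")
    lines.append("")
    for warning in report.warnings:
        lines.append(f"> **Warning:** {warning}")
    if report.warnings:
        lines.append("")
    s = report.stages
    if "data" in s:
        d = s["data"]
        lines += [f"## Data", "",
                  f"Source: {d['source']} — n = {d['n']}, p = {d['p']}", ""]
    if "efa" in s:
        d = s["efa"]
        lines.append("## Exploratory factor analysis")
        lines.append("")
        if "error" in d:
            lines.append(f"Stage failed: {d['error']}")
        else:
            lines.append(f"Scree elbow suggests {d['scree_count']} factor(s); "
                         f"parallel analysis retains {d['parallel_analysis_count']}.")
            lines.append(f"One factor explains "
                         f"{100 * d['one_factor_variance_explained']:.0f}% of the variance.")
            lines.append("")
            lines.append("| Item | Loading |")
            lines.append("|------|---------|")
            for i, l in enumerate(d["one_factor_loadings"], start=1):
                lines.append(f"| {i} | {l:.2f} |")
        lines.append("")
    for key, title in [("cfa_one_factor", "Confirmatory factor analysis (one factor)"),
                       ("cfa_ega", "Confirmatory factor analysis (EGA structure)")]:
        if key in s:
            d = s[key]
            lines.append(f"## {title}")
            lines.append("")
            if "skipped" in d:
                lines.append(f"Skipped: {d['skipped']}")
            elif "error" in d:
                lines.append(f"Stage failed: {d['error']}")
            else:
                lines.append(
                    f"chi-square({d['df']}) = {d['chi_square']:.2f} "
                    f"(CFI = {d['cfi']:.3f}, RMSEA = {d['rmsea']:.3f}, "
                    f"SRMR = {d['srmr']:.3f})"
                )
            lines.append("")
    if "bootstrap_ega" in s:
        d = s["bootstrap_ega"]
        lines.append("## Bootstrap exploratory graph analysis")
        lines.append("")
        lines.append(f"B = {d['B']} parametric replicates; median community solution: "
                     f"{d['median_dimensions']} -> {d['n_dimensions']} dimensions.")
        lines.append("")
        lines.append("| Dimensions | Proportion of replicates |")
        lines.append("|------------|--------------------------|")
        for kk, v in d["frequency_table"].items():
            lines.append(f"| {kk} | {v:.3f} |")
        lines.append("")
    if "comparison" in s:
        d = s["comparison"]
        lines.append("## Model comparison")
        lines.append("")
        if "skipped" in d:
            lines.append(f"Skipped: {d['skipped']}")
        else:
            lines.append(
                f"Delta chi-square({d['delta_df']}) = {d['delta_chi_square']:.2f}, "
                f"p = {d['p_value']:.3g}; preferred model: **{d['preferred']}**."
            )
        lines.append("")
    return "\n".join(lines)
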