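"""End-to-end study pipeline on synthetic cohorts.

Orchestrates: simulate three cohorts -> inclusion filtering -> sex-stratified
k-means (k = 5) -> archetype naming -> pairwise cross-cohort validation ->
composite endpoint derivation -> per-cohort one-vs-rest Cox -> random-effects
meta-analysis. Every stage seed is derived deterministically from the single
pipeline seed, so identical inputs and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .archetypes import ConfusionResult, cross_validate, name_archetypes
from .clustering import ClusterModel, derive_seed, fit_sex_stratified
from .data_model import ARCHETYPES, Cohort, InclusionReport, apply_inclusion_criteria
from .endpoint import EndpointConfig, endpoint_table
from .survival import HazardEstimate, InestimableError, cox_one_vs_rest, survival_table
from .synthetic import FollowupConfig, MixtureConfig, TruthLabels, simulate_followup, simulate_cross_section

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "simulate_study"]


@dataclass
class PipelineConfig:
    """Reproducible pipeline settings; unknown YAML keys are rejected."""

    seed: int = 0
    k: int = 5
    n_restarts: int = 100
    n_subjects: int = 3000
    cohort_ids: tuple[str, ...] = ("synth_a", "synth_b", "synth_c")
    separation: float = 1.0
    gap_b: int = 50
    gap_kmax: int = 7
    gad_policy: str = "exclude_only_positive"
    endpoint: EndpointConfig = field(default_factory=EndpointConfig)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for name in ("n_restarts", "n_subjects", "gap_b", "gap_kmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "endpoint" in raw:
            ep_known = {f.name for f in dataclasses.fields(EndpointConfig)}
            ep_unknown = set(raw["endpoint"]) - ep_known
            if ep_unknown:
                raise ValueError(
                    f"unknown endpoint config key(s): {', '.join(sorted(ep_unknown))}")
            raw["endpoint"] = EndpointConfig(**raw["endpoint"])
        if "cohort_ids" in raw:
            raw["cohort_ids"] = tuple(raw["cohort_ids"])
        return cls(**raw)


@dataclass
class CohortBundle:
    cohort: Cohort
    labels: TruthLabels
    longitudinal: list
    inclusion: InclusionReport


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundles: dict[str, CohortBundle]
    models: dict[str, ClusterModel]
    archetype_labels: dict[str, dict[str, str]]   # cohort -> subject -> archetype
    confusions: dict[tuple[str, str], ConfusionResult]
    endpoints: dict[str, pd.DataFrame]
    hazard_estimates: list[HazardEstimate]
    meta_table: pd.DataFrame


def simulate_study(config: PipelineConfig) -> dict[str, CohortBundle]:
    """Generate the three synthetic cohorts with follow-up and apply inclusion."""
    bundles: dict[str, CohortBundle] = {}
    for cid in config.cohort_ids:
        mix = MixtureConfig(
            n_subjects=config.n_subjects,
            seed=derive_seed(config.seed, "simulate", cid),
            separation=config.separation,
        )
        cohort, labels = simulate_cross_section(mix, cid)
        cohort, report = apply_inclusion_criteria(cohort, gad_policy=config.gad_policy)
        followup = FollowupConfig(seed=derive_seed(config.seed, "followup", cid))
        records = simulate_followup(cohort, labels, followup)
        bundles[cid] = CohortBundle(cohort, labels, records, report)
    return bundles


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full study pipeline and return all stage outputs."""
    bundles = simulate_study(config)

    models: dict[str, ClusterModel] = {}
    archetype_labels: dict[str, dict[str, str]] = {}
    for cid, bundle in bundles.items():
        model = fit_sex_stratified(
            bundle.cohort, k=config.k, n_restarts=config.n_restarts,
            seed=derive_seed(config.seed, "fit", cid))
        name_archetypes(model)
        models[cid] = model
        archetype_labels[cid] = {
            sid: model.archetypes[c]
            for sid, c in model.training_assignment.items()
        }

    confusions: dict[tuple[str, str], ConfusionResult] = {}
    ids = list(config.cohort_ids)
    for a in ids:
        for b in ids:
            if a != b:
                confusions[(a, b)] = cross_validate(
                    bundles[a].cohort, models[a], models[b])

    endpoints: dict[str, pd.DataFrame] = {}
    estimates: list[HazardEstimate] = []
    for cid, bundle in bundles.items():
        table = endpoint_table(bundle.longitudinal, config.endpoint)
        endpoints[cid] = table
        for archetype in ARCHETYPES:
            try:
                estimates.append(cox_one_vs_rest(
                    table, archetype_labels[cid], archetype, cohort_id=cid))
            except InestimableError:
                continue

    meta = survival_table(estimates)
    return PipelineResult(
        config=config,
        bundles=bundles,
        models=models,
        archetype_labels=archetype_labels,
        confusions=confusions,
        endpoints=endpoints,
        hazard_estimates=estimates,
        meta_table=meta,
    )
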