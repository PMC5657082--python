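"""End-to-end orchestration: split -> strategy -> evaluation.

Two strategies produce a semantic bicluster system from a training matrix:

``enrich``
    Greedy cost-based biclustering followed by bi-directional enrichment;
    the resulting soft system is scored on test cells over a grid of
    (theta_G, theta_S) match thresholds.

``rules`` / ``tree``
    Unroll the training matrix into one instance per cell, select
    features, learn a rule list or decision tree, and score test cells by
    sweeping a confidence threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import evaluation, io, learners
from .core import (
    AnnotationRelation,
    ExpressionMatrix,
    SemanticBiclusterSystem,
    induce_system,
    training_accuracy,
)
from .enrichment import EnrichmentResult, PermutationConfig, annotate_system, annotation_closure
from .errors import ParameterError
from .evaluation import DEFAULT_THETA_GRID, EvaluationSplit, ROCResult
from .learners import DecisionTree, LearnConfig, RuleList
from .search import SearchConfig, greedy_search, select_rho

__all__ = ["RunConfig", "StrategyResult", "run_strategy", "evaluate_split", "run_all"]

STRATEGIES = ("enrich", "rules", "tree")


@dataclass
class RunConfig:
    """File paths and parameters of a full pipeline run."""

    matrix_path: str | None = None
    gene_annotation_path: str | None = None
    situation_annotation_path: str | None = None
    gene_ontology_path: str | None = None
    situation_ontology_path: str | None = None
    output_dir: str = "sembic_out"
    strategy: str = "enrich"
    element_fraction: float = 0.7
    rho: float | None = None
    rho_candidates: tuple[float, ...] = (0.5, 1.0, 2.0)
    max_biclusters: int = 50
    alpha_genes: float = 0.05
    alpha_situations: float = 0.1
    calibrate_alpha: bool = True  # permutation-based threshold calibration
    target_fdr: float = 0.05
    theta_grid_g: tuple[float, ...] = DEFAULT_THETA_GRID
    theta_grid_s: tuple[float, ...] = DEFAULT_THETA_GRID
    min_fraction: float = 0.001
    n_perms: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ParameterError(f"strategy must be one of {STRATEGIES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("rho_candidates", "theta_grid_g", "theta_grid_s"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class StrategyResult:
    """A learned semantic system plus strategy-specific artifacts."""

    strategy: str
    semantic_system: SemanticBiclusterSystem
    model: RuleList | DecisionTree | None = None
    enrichment: EnrichmentResult | None = None
    ordinary_system: Any = None  # BiclusterSystem for the enrich strategy
    rho: float | None = None
    info: dict[str, Any] = field(default_factory=dict)


def _closed_annotations(
    relation: AnnotationRelation, ontology_path: str | None
) -> AnnotationRelation:
    if ontology_path is None:
        return relation
    return annotation_closure(relation, io.read_obo(ontology_path))


def run_strategy(
    train: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    config: RunConfig,
) -> StrategyResult:
    """Learn a semantic bicluster system from a training matrix."""
    if config.strategy == "enrich":
        rho = config.rho
        if rho is None:
            rho = select_rho(
                train, list(config.rho_candidates), SearchConfig(max_biclusters=config.max_biclusters)
            )
        system = greedy_search(
            train, SearchConfig(rho=rho, max_biclusters=config.max_biclusters, seed=config.seed)
        )
        perm = (
            PermutationConfig(config.n_perms, config.target_fdr, config.seed)
            if config.calibrate_alpha
            else None
        )
        semantic, enr = annotate_system(
            system,
            train,
            gene_annotations,
            situation_annotations,
            alpha_genes=config.alpha_genes,
            alpha_situations=config.alpha_situations,
            permutation=perm,
        )
        return StrategyResult(
            "enrich",
            semantic,
            enrichment=enr,
            ordinary_system=system,
            rho=rho,
            info={"n_ordinary_biclusters": len(system)},
        )

    gene_vocab = sorted(gene_annotations.all_terms())
    sit_vocab = sorted(situation_annotations.all_terms())
    data = learners.unroll(train, gene_annotations, situation_annotations, gene_vocab, sit_vocab)
    data = learners.select_features(data, config.min_fraction)
    lcfg = LearnConfig(seed=config.seed)
    if config.strategy == "rules":
        model: RuleList | DecisionTree = learners.learn_rules(data, lcfg)
        rules = list(model)
    else:
        model = learners.learn_tree(data, lcfg)
        rules = learners.tree_to_rules(model)
    semantic = learners.rules_to_semantic_biclusters(rules)
    return StrategyResult(
        config.strategy,
        semantic,
        model=model,
        info={"n_rules": len(rules), "n_features": data.n_features, "n_instances": data.n_rows},
    )


def evaluate_split(
    split: EvaluationSplit,
    result: StrategyResult,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    config: RunConfig,
) -> dict[str, Any]:
    """Score a learned system on the test cells of a rectangular split."""
    if result.strategy == "enrich":

        def roc_fn(cells: Sequence[evaluation.TestCell]) -> ROCResult:
            return evaluation.roc_grid(
                result.semantic_system,
                gene_annotations,
                situation_annotations,
                cells,
                config.theta_grid_g,
                config.theta_grid_s,
            )

    else:

        def roc_fn(cells: Sequence[evaluation.TestCell]) -> ROCResult:
            return evaluation.roc_confidence(
                result.model, gene_annotations, situation_annotations, cells
            )

    overall = roc_fn(split.test_cells)
    regions = evaluation.region_auroc(split, roc_fn)

    induced = induce_system(
        result.semantic_system,
        split.train.gene_ids,
        split.train.situation_ids,
        gene_annotations,
        situation_annotations,
    )
    train_acc = training_accuracy(induced, split.train)

    report: dict[str, Any] = {
        "strategy": result.strategy,
        "seed": split.seed,
        "n_biclusters": len(result.semantic_system),
        "train_shape": list(split.train.shape),
        "n_test_cells": len(split.test_cells),
        "region_sizes": split.region_sizes(),
        "training_accuracy": train_acc,
        "auroc": overall.auroc,
        "operating_points": [list(p) for p in overall.operating_points],
        "hull": [list(p) for p in overall.hull],
        "region_auroc": regions,
    }
    if result.rho is not None:
        report["rho"] = result.rho
    report.update(result.info)
    return report


def run_all(
    matrix: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    config: RunConfig,
) -> tuple[dict[str, Any], dict[str, Any]]:
    """Split, learn, evaluate; returns (bicluster report, evaluation report)."""
    split = evaluation.split_matrix(matrix, config.element_fraction, config.seed)
    result = run_strategy(split.train, gene_annotations, situation_annotations, config)
    eval_report = evaluate_split(split, result, gene_annotations, situation_annotations, config)
    induced = induce_system(
        result.semantic_system,
        split.train.gene_ids,
        split.train.situation_ids,
        gene_annotations,
        situation_annotations,
    )
    bc_report = io.bicluster_report(
        result.semantic_system,
        result.enrichment,
        [(sorted(bc.genes), sorted(bc.situations)) for bc in induced],
    )
    return bc_report, eval_report
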