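"""Rectangular train/test evaluation of semantic bicluster systems.

Because a training split must itself be a matrix (biclustering needs
rectangles), holding out a fraction ``f`` of matrix *elements* is realized
by retaining ``round(|G| * sqrt(f))`` genes and ``round(|S| * sqrt(f))``
situations.  The complement — every cell outside the retained submatrix —
forms the test set and decomposes into three regions: kG (known genes x
unseen situations), kL (unseen genes x known situations) and bd (unseen x
unseen), which probe generalization across situations, across genes, and
across both.  Soft systems are scored by a theta-grid of operating points
whose upper convex hull yields the AUROC; confidence-ranked models by a
standard threshold-sweep ROC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .core import (
    AnnotationRelation,
    BiclusterSystem,
    ExpressionMatrix,
    SemanticBiclusterSystem,
)
from .enrichment import term_enrichment_p, _candidate_terms
from .errors import DimensionError, ParameterError

__all__ = [
    "TestCell",
    "EvaluationSplit",
    "ROCResult",
    "split_matrix",
    "test_accuracy",
    "roc_grid",
    "roc_confidence",
    "region_auroc",
    "enriched_proportion",
    "DEFAULT_THETA_GRID",
]

REGIONS = ("kG", "kL", "bd")
#: match-threshold grid of the soft classifier
DEFAULT_THETA_GRID = (1.0, 5.0, 10.0, 50.0)


@dataclass(frozen=True)
class TestCell:
    gene: str
    situation: str
    label: int
    region: str  # kG | kL | bd


@dataclass
class EvaluationSplit:
    """A rectangular training submatrix plus the labelled complement."""

    train: ExpressionMatrix
    test_cells: list[TestCell]
    seed: int = 0

    def region_cells(self, region: str) -> list[TestCell]:
        if region not in REGIONS:
            raise ParameterError(f"unknown region {region!r}")
        return [c for c in self.test_cells if c.region == region]

    def region_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(REGIONS, 0)
        for c in self.test_cells:
            sizes[c.region] += 1
        return sizes


@dataclass
class ROCResult:
    """Operating points, their upper convex hull and the hull AUROC."""

    operating_points: list[tuple[float, float]]
    hull: list[tuple[float, float]]
    auroc: float
    parameters: list = field(default_factory=list)  # one entry per operating point

    @property
    def points(self) -> list[tuple[float, float]]:
        return self.hull


def split_matrix(
    matrix: ExpressionMatrix, element_fraction: float = 0.7, seed: int = 0
) -> EvaluationSplit:
    """Random rectangular split retaining ~``element_fraction`` of the cells.

    Retention is equal per dimension: ``round(n * sqrt(f))`` rows and
    columns, so the retained cell fraction is close to ``f`` while the
    training split stays a matrix.  All cells outside it become test cells
    tagged kG, kL or bd.
    """
    if not (0 < element_fraction <= 1):
        raise ParameterError("element_fraction must lie in (0;1]")
    ng, ns = matrix.shape
    keep_g = min(ng, round(ng * math.sqrt(element_fraction)))
    keep_s = min(ns, round(ns * math.sqrt(element_fraction)))
    if keep_g < 1 or keep_s < 1:
        raise ParameterError("element_fraction retains zero rows or columns")
    rng = np.random.default_rng(seed)
    g_keep_idx = np.sort(rng.choice(ng, size=keep_g, replace=False))
    s_keep_idx = np.sort(rng.choice(ns, size=keep_s, replace=False))
    g_keep = set(g_keep_idx.tolist())
    s_keep = set(s_keep_idx.tolist())

    train = matrix.submatrix(
        [matrix.gene_ids[i] for i in g_keep_idx],
        [matrix.situation_ids[j] for j in s_keep_idx],
    )
    cells: list[TestCell] = []
    vals = matrix.values
    for i, g in enumerate(matrix.gene_ids):
        for j, s in enumerate(matrix.situation_ids):
            gi, sj = i in g_keep, j in s_keep
            if gi and sj:
                continue
            region = "kG" if gi else ("kL" if sj else "bd")
            cells.append(TestCell(g, s, int(vals[i, j]), region))
    return EvaluationSplit(train, cells, seed)


def test_accuracy(
    classifier: Callable[[str, str], int], test_cells: Sequence[TestCell]
) -> float:
    """Fraction of test cells on which the classifier reproduces the label."""
    if not test_cells:
        raise DimensionError("test set is empty")
    hits = sum(1 for c in test_cells if classifier(c.gene, c.situation) == c.label)
    return hits / len(test_cells)


def _rates(pred: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    pos = labels == 1
    neg = ~pos
    tpr = float(pred[pos].sum()) / pos.sum()
    fpr = float(pred[neg].sum()) / neg.sum()
    return fpr, tpr


def _upper_hull(points: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Upper convex hull of ROC points, anchored at (0,0) and (1,1)."""
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    hull: list[tuple[float, float]] = []
    for p in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            # drop the middle point unless it turns clockwise (stays above)
            if (x2 - x1) * (p[1] - y1) - (y2 - y1) * (p[0] - x1) < 0:
                break
            hull.pop()
        hull.append(p)
    return hull


def _trapezoid_auc(points: Sequence[tuple[float, float]]) -> float:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min(initial=1) == labels.max(initial=0):
        raise ParameterError("ROC requires both classes in the test set")


def roc_grid(
    system: SemanticBiclusterSystem,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    test_cells: Sequence[TestCell],
    theta_grid_g: Sequence[float] = DEFAULT_THETA_GRID,
    theta_grid_s: Sequence[float] = DEFAULT_THETA_GRID,
) -> ROCResult:
    """ROC over the grid of (theta_G, theta_S) soft-classification thresholds.

    Each grid pair yields one binary classifier and hence one operating
    point (the default 4x4 grids give 16); the reported AUROC is the
    trapezoid area under their upper convex hull.
    """
    if not theta_grid_g or not theta_grid_s:
        raise ParameterError("theta grids must be non-empty")
    labels = np.array([c.label for c in test_cells])
    _check_two_classes(labels)

    genes = sorted({c.gene for c in test_cells})
    sits = sorted({c.situation for c in test_cells})
    g_pos = {g: i for i, g in enumerate(genes)}
    s_pos = {s: i for i, s in enumerate(sits)}
    # per bicluster, matched weight of every test gene / situation
    g_scores = np.array(
        [
            [sb.gene_terms.matched_weight(gene_annotations.terms_of(g)) for g in genes]
            for sb in system
        ]
    ).reshape(len(system), len(genes))
    s_scores = np.array(
        [
            [
                sb.situation_terms.matched_weight(situation_annotations.terms_of(s))
                for s in sits
            ]
            for sb in system
        ]
    ).reshape(len(system), len(sits))
    gi = np.array([g_pos[c.gene] for c in test_cells])
    sj = np.array([s_pos[c.situation] for c in test_cells])

    points: list[tuple[float, float]] = []
    params: list[tuple[float, float]] = []
    for tg in theta_grid_g:
        for ts in theta_grid_s:
            if len(system):
                ok = (g_scores >= tg)[:, gi] & (s_scores >= ts)[:, sj]
                pred = ok.any(axis=0).astype(int)
            else:
                pred = np.zeros(len(test_cells), dtype=int)
            points.append(_rates(pred, labels))
            params.append((float(tg), float(ts)))
    hull = _upper_hull(points)
    return ROCResult(points, hull, _trapezoid_auc(hull), params)


def roc_confidence(
    model,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    test_cells: Sequence[TestCell],
) -> ROCResult:
    """Standard ranked ROC over a model exposing per-pair confidences."""
    labels = np.array([c.label for c in test_cells])
    _check_two_classes(labels)
    scores = np.array(
        [
            model.confidence(
                gene_annotations.terms_of(c.gene),
                situation_annotations.terms_of(c.situation),
            )
            for c in test_cells
        ]
    )
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    auc = _trapezoid_auc(points)
    return ROCResult(points, points, auc, thresholds.tolist())


def region_auroc(
    split: EvaluationSplit,
    roc_fn: Callable[[Sequence[TestCell]], ROCResult],
) -> dict[str, float | None]:
    """Apply a ROC computation separately to the kG, kL and bd regions.

    A degenerate region (empty or single-class) is reported as None rather
    than raising.
    """
    out: dict[str, float | None] = {}
    for region in REGIONS:
        cells = split.region_cells(region)
        try:
            out[region] = roc_fn(cells).auroc if cells else None
        except ParameterError:
            out[region] = None
    return out


def enriched_proportion(
    system: BiclusterSystem,
    matrix: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    alpha: float = 0.05,
) -> float:
    """Fraction of biclusters carrying >= 1 enriched term in BOTH dimensions.

    Measures the biological homogeneity of a bicluster system: a bicluster
    counts only if some gene term and some situation term are both
    over-represented at level ``alpha``.
    """
    if len(system) == 0:
        raise ParameterError("enriched_proportion needs at least one bicluster")
    genes_bg = list(matrix.gene_ids)
    sits_bg = list(matrix.situation_ids)
    hits = 0
    for bc in system:
        g_ok = any(
            term_enrichment_p(bc.genes, genes_bg, t, gene_annotations) <= alpha
            for t in sorted(_candidate_terms(bc.genes, gene_annotations))
        )
        s_ok = g_ok and any(
            term_enrichment_p(bc.situations, sits_bg, t, situation_annotations) <= alpha
            for t in sorted(_candidate_terms(bc.situations, situation_annotations))
        )
        if g_ok and s_ok:
            hits += 1
    return hits / len(system)
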