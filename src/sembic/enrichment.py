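"""Bi-directional enrichment: from ordinary to soft semantic biclusters.

Given an ordinary bicluster system found purely from the expression matrix,
this module attaches meaning to each bicluster by testing every ontology
term for over-representation among the bicluster's genes (against all
matrix genes) and among its situations (against all matrix situations),
using the one-sided hypergeometric tail.  Significant terms are kept with
weight ``1 - p``, turning each bicluster into a soft semantic bicluster.
Significance thresholds can be fixed per dimension or calibrated by a
permutation test that bounds the false discovery rate of retained terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .core import (
    AnnotationRelation,
    Bicluster,
    BiclusterSystem,
    ExpressionMatrix,
    SemanticBicluster,
    SemanticBiclusterSystem,
    WeightedTermSet,
)
from .errors import ContainmentError, ParameterError, ValidationError

__all__ = [
    "Ontology",
    "EnrichmentResult",
    "TermScore",
    "annotation_closure",
    "term_enrichment_p",
    "annotate_bicluster",
    "permutation_alpha",
    "annotate_system",
    "PermutationConfig",
    "WEIGHT_EPSILON",
]

#: floor for term weights so they stay within (0; 1]
WEIGHT_EPSILON = 1e-6

EDGE_TYPES = ("is_a", "part_of", "develops_from")


class Ontology:
    """A DAG of terms linked child -> parent by is_a / part_of / develops_from edges.

    All three edge types are treated as transitive for annotation
    propagation, mirroring the ancestor semantics of GO-style hierarchies.
    """

    def __init__(
        self,
        terms: Iterable[str] | dict[str, str],
        edges: Iterable[tuple[str, str, str]] = (),
    ):
        if isinstance(terms, dict):
            self._names = dict(terms)
        else:
            self._names = {t: t for t in terms}
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self._names)
        for child, parent, etype in edges:
            if child not in self._names or parent not in self._names:
                raise ValidationError(f"edge endpoint not declared: {child!r} -> {parent!r}")
            if etype not in EDGE_TYPES:
                raise ValidationError(f"unknown edge type {etype!r}")
            self.graph.add_edge(child, parent, type=etype)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValidationError("ontology graph contains a cycle")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._names)

    def name(self, term: str) -> str:
        return self._names[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable by following edges towards the roots (term excluded)."""
        return frozenset(nx.descendants(self.graph, term))

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.graph if self.graph.out_degree(t) == 0)

    def leaves(self) -> frozenset[str]:
        return frozenset(t for t in self.graph if self.graph.in_degree(t) == 0)

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, term: str) -> bool:
        return term in self._names


def annotation_closure(relation: AnnotationRelation, onto: Ontology) -> AnnotationRelation:
    """Close each entity's term set under ancestor propagation.

    An entity annotated with a term is implicitly annotated with every
    ancestor of that term.  Idempotent.
    """
    missing = relation.all_terms() - onto.terms
    if missing:
        raise ValidationError(f"annotated terms absent from ontology: {sorted(missing)[:5]}")
    anc_cache: dict[str, frozenset[str]] = {}
    closed: dict[str, set[str]] = {}
    for entity, terms in relation.items():
        out: set[str] = set(terms)
        for t in terms:
            if t not in anc_cache:
                anc_cache[t] = onto.ancestors(t)
            out |= anc_cache[t]
        closed[entity] = out
    return AnnotationRelation(closed)


def term_enrichment_p(
    in_set: Iterable[str],
    background: Iterable[str],
    term: str,
    relation: AnnotationRelation,
) -> float:
    """One-sided hypergeometric over-representation p-value of ``term`` in ``in_set``.

    With N background entities of which K carry the term, and a draw of
    n = |in_set| entities of which k carry it, returns P(X >= k) under the
    hypergeometric null of annotation-blind sampling.
    """
    in_set = set(in_set)
    background = set(background)
    if not background:
        raise ContainmentError("background must be non-empty")
    if not in_set <= background:
        raise ContainmentError("in_set must be a subset of background")
    N = len(background)
    K = sum(1 for e in background if term in relation.terms_of(e))
    n = len(in_set)
    k = sum(1 for e in in_set if term in relation.terms_of(e))
    # survival function at k-1 gives P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


@dataclass(frozen=True)
class TermScore:
    term: str
    p_value: float
    weight: float


@dataclass
class EnrichmentResult:
    """Per-bicluster, per-dimension enriched terms plus the thresholds used."""

    alpha_genes: float
    alpha_situations: float
    gene_terms: list[list[TermScore]] = field(default_factory=list)
    situation_terms: list[list[TermScore]] = field(default_factory=list)
    kept_indices: list[int] = field(default_factory=list)


def _candidate_terms(entities: Iterable[str], relation: AnnotationRelation) -> set[str]:
    """Terms annotating at least one member; all others have p = 1 trivially."""
    out: set[str] = set()
    for e in entities:
        out |= relation.terms_of(e)
    return out


def _dimension_indicator(
    background: list[str], relation: AnnotationRelation
) -> tuple[list[str], np.ndarray]:
    """Entity-by-term boolean indicator over the terms used in the background."""
    terms = sorted({t for e in background for t in relation.terms_of(e)})
    t_idx = {t: i for i, t in enumerate(terms)}
    ind = np.zeros((len(background), len(terms)), dtype=bool)
    for i, e in enumerate(background):
        for t in relation.terms_of(e):
            ind[i, t_idx[t]] = True
    return terms, ind


def _p_values_from_indicator(member_mask: np.ndarray, ind: np.ndarray) -> np.ndarray:
    """Vector of one-sided hypergeometric tail p-values for all indicator terms."""
    N = len(member_mask)
    n = int(member_mask.sum())
    K = ind.sum(axis=0)
    k = ind[member_mask].sum(axis=0)
    return np.minimum(1.0, hypergeom.sf(k - 1, N, K, n))


def _enrich_dimension(
    members: frozenset[str],
    background: list[str],
    relation: AnnotationRelation,
    alpha: float,
    indicator: tuple[list[str], np.ndarray] | None = None,
) -> list[TermScore]:
    terms, ind = indicator if indicator is not None else _dimension_indicator(background, relation)
    mask = np.array([e in members for e in background])
    p_all = _p_values_from_indicator(mask, ind)
    k = ind[mask].sum(axis=0)
    scores = [
        TermScore(terms[j], float(p_all[j]), max(WEIGHT_EPSILON, 1.0 - float(p_all[j])))
        for j in np.flatnonzero((p_all <= alpha) & (k >= 1))
    ]
    scores.sort(key=lambda ts: (ts.p_value, ts.term))
    return scores


def annotate_bicluster(
    bc: Bicluster,
    matrix: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    alpha_genes: float = 0.05,
    alpha_situations: float = 0.1,
) -> SemanticBicluster | None:
    """Attach significantly enriched terms to both dimensions of one bicluster.

    Returns None for trivial biclusters (a single gene or situation), which
    cannot be meaningfully enriched.  Retained terms carry weight
    ``max(eps, 1 - p)``; the backgrounds are the full gene and situation
    lists of the host matrix.
    """
    if bc.is_trivial():
        return None
    g_scores = _enrich_dimension(bc.genes, list(matrix.gene_ids), gene_annotations, alpha_genes)
    s_scores = _enrich_dimension(
        bc.situations, list(matrix.situation_ids), situation_annotations, alpha_situations
    )
    return SemanticBicluster(
        WeightedTermSet((ts.term, ts.weight) for ts in g_scores),
        WeightedTermSet((ts.term, ts.weight) for ts in s_scores),
    )


def _system_p_values(
    member_masks: list[np.ndarray], ind: np.ndarray
) -> np.ndarray:
    """Flat vector of per-(bicluster, candidate term) p-values on one dimension.

    Candidates are the terms annotating at least one member of the
    respective bicluster.
    """
    out: list[np.ndarray] = []
    for mask in member_masks:
        p = _p_values_from_indicator(mask, ind)
        k = ind[mask].sum(axis=0)
        out.append(p[k >= 1])
    return np.concatenate(out) if out else np.empty(0)


def permutation_alpha(
    matrix: ExpressionMatrix,
    system: BiclusterSystem,
    relation: AnnotationRelation,
    dimension: Literal["gene", "situation"],
    n_perms: int = 100,
    target_fdr: float = 0.05,
    seed: int = 0,
) -> float:
    """Calibrate the significance threshold by permuting annotation labels.

    Entity identities on the tested dimension are shuffled (breaking any
    entity-to-annotation link while keeping bicluster index sets and the
    annotation multiset fixed) and all term p-values are recomputed per
    permutation.  The returned alpha is the largest observed real p-value
    for which the estimated FDR — mean permuted count of p <= alpha divided
    by the real count — stays at or below ``target_fdr``; 0 when no
    candidate qualifies (no term survives).
    """
    if len(system) == 0:
        raise ParameterError("cannot calibrate on an empty bicluster system")
    if n_perms < 1:
        raise ParameterError("n_perms must be >= 1")
    if not (0 < target_fdr < 1):
        raise ParameterError("target_fdr must lie in (0;1)")

    entities = list(matrix.gene_ids if dimension == "gene" else matrix.situation_ids)
    _, ind = _dimension_indicator(entities, relation)
    pos = {e: i for i, e in enumerate(entities)}
    masks = []
    for bc in system:
        if bc.is_trivial():
            continue
        members = bc.genes if dimension == "gene" else bc.situations
        mask = np.zeros(len(entities), dtype=bool)
        mask[[pos[e] for e in members]] = True
        masks.append(mask)
    real_p = _system_p_values(masks, ind)
    if real_p.size == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    perm_p = [
        _system_p_values(masks, ind[rng.permutation(len(entities))]) for _ in range(n_perms)
    ]

    best = 0.0
    for alpha in np.unique(real_p):
        real_count = int((real_p <= alpha).sum())
        perm_count = float(np.mean([(pp <= alpha).sum() for pp in perm_p]))
        if real_count > 0 and perm_count / real_count <= target_fdr:
            best = max(best, float(alpha))
    return best


@dataclass(frozen=True)
class PermutationConfig:
    """Settings of the permutation-based significance-threshold calibration."""

    n_perms: int = 100
    target_fdr: float = 0.05
    seed: int = 0


def annotate_system(
    system: BiclusterSystem,
    matrix: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    alpha_genes: float = 0.05,
    alpha_situations: float = 0.1,
    permutation: PermutationConfig | None = None,
) -> tuple[SemanticBiclusterSystem, EnrichmentResult]:
    """Bi-directional enrichment of a whole system.

    Every non-trivial bicluster is annotated on both dimensions; biclusters
    with no significant term on either side are dropped.  A bicluster
    significant on a single side is kept — its empty side is the vacuous
    conjunction and induces all entities of that dimension.  When a
    ``permutation`` configuration is given, the per-dimension significance
    thresholds are not taken from ``alpha_genes`` / ``alpha_situations``
    but calibrated by the permutation test so that the estimated FDR of
    retained terms stays below its target.
    """
    if permutation is not None and len(system):
        alpha_genes = permutation_alpha(
            matrix, system, gene_annotations, "gene",
            permutation.n_perms, permutation.target_fdr, permutation.seed,
        )
        alpha_situations = permutation_alpha(
            matrix, system, situation_annotations, "situation",
            permutation.n_perms, permutation.target_fdr, permutation.seed + 1,
        )
    result = EnrichmentResult(alpha_genes, alpha_situations)
    semantic = SemanticBiclusterSystem([])
    g_ind = _dimension_indicator(list(matrix.gene_ids), gene_annotations)
    s_ind = _dimension_indicator(list(matrix.situation_ids), situation_annotations)
    for idx, bc in enumerate(system):
        if bc.is_trivial():
            continue
        g_scores = _enrich_dimension(
            bc.genes, list(matrix.gene_ids), gene_annotations, alpha_genes, g_ind
        )
        s_scores = _enrich_dimension(
            bc.situations,
            list(matrix.situation_ids),
            situation_annotations,
            alpha_situations,
            s_ind,
        )
        if not g_scores and not s_scores:
            continue
        semantic.biclusters.append(
            SemanticBicluster(
                WeightedTermSet((ts.term, ts.weight) for ts in g_scores),
                WeightedTermSet((ts.term, ts.weight) for ts in s_scores),
            )
        )
        result.gene_terms.append(g_scores)
        result.situation_terms.append(s_scores)
        result.kept_indices.append(idx)
    return semantic, result
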