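"""Core domain model: binary expression matrices, ordinary and semantic biclusters.

The objects here implement the formal machinery of semantic biclustering.
An :class:`ExpressionMatrix` holds a binary gene-by-situation indicator
matrix.  An ordinary :class:`Bicluster` is an extensional object — a subset
of rows and a subset of columns.  A :class:`SemanticBicluster` is
intensional: it is a pair of (weighted) ontology-term conjunctions, one over
gene annotations and one over situation annotations, and therefore induces a
bicluster on *any* universe of annotated genes and situations, not only on
the matrix it was learned from.  That out-of-sample reach is what makes the
rectangular train/test evaluation protocol possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import DimensionError, ParameterError, UnknownIdentifierError

__all__ = [
    "ExpressionMatrix",
    "AnnotationRelation",
    "Bicluster",
    "BiclusterSystem",
    "WeightedTermSet",
    "SemanticBicluster",
    "SemanticBiclusterSystem",
    "extension",
    "training_accuracy",
    "regularized_score",
    "induce_bicluster",
    "induce_system",
    "semantic_extension",
    "soft_classify",
]


def _check_unique(ids: tuple[str, ...], what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ParameterError(f"duplicate {what} ids: {dup[:5]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Binary expression indicator matrix with named rows (genes) and columns (situations)."""

    gene_ids: tuple[str, ...]
    situation_ids: tuple[str, ...]
    values: np.ndarray  # uint8, shape (n_genes, n_situations), entries in {0, 1}

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "situation_ids", tuple(self.situation_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.situation_ids, "situation")
        vals = np.asarray(self.values, dtype=np.uint8)
        if vals.shape != (len(self.gene_ids), len(self.situation_ids)):
            raise DimensionError(
                f"values shape {vals.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.situation_ids)})"
            )
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ParameterError("matrix cells must be 0 or 1")
        object.__setattr__(self, "values", vals)

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @cached_property
    def situation_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.situation_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_ones(self) -> int:
        return int(self.values.sum())

    def submatrix(self, genes: Iterable[str], situations: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        situations = list(situations)
        gi = [self._gene_pos(g) for g in genes]
        sj = [self._situation_pos(s) for s in situations]
        return ExpressionMatrix(tuple(genes), tuple(situations), self.values[np.ix_(gi, sj)])

    def _gene_pos(self, g: str) -> int:
        try:
            return self.gene_index[g]
        except KeyError:
            raise UnknownIdentifierError(f"unknown gene id: {g!r}") from None

    def _situation_pos(self, s: str) -> int:
        try:
            return self.situation_index[s]
        except KeyError:
            raise UnknownIdentifierError(f"unknown situation id: {s!r}") from None

    def __getitem__(self, key: tuple[str, str]) -> int:
        g, s = key
        return int(self.values[self._gene_pos(g), self._situation_pos(s)])


class AnnotationRelation:
    """Many-to-many relation between entities (genes or situations) and ontology terms.

    Entities absent from the mapping are treated as annotated with the empty
    term set; lookups never raise.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {
            e: frozenset(ts) for e, ts in (mapping or {}).items()
        }

    def terms_of(self, entity: str) -> frozenset[str]:
        return self._map.get(entity, frozenset())

    def entities(self) -> frozenset[str]:
        return frozenset(self._map)

    def all_terms(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self._map.values():
            out |= ts
        return frozenset(out)

    def items(self) -> Iterator[tuple[str, frozenset[str]]]:
        return iter(self._map.items())

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AnnotationRelation) and self._map == other._map

    def __repr__(self) -> str:
        return f"AnnotationRelation({len(self._map)} entities, {len(self.all_terms())} terms)"


@dataclass(frozen=True)
class Bicluster:
    """An ordinary (extensional) bicluster: a row subset times a column subset."""

    genes: frozenset[str]
    situations: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "situations", frozenset(self.situations))

    @property
    def n_cells(self) -> int:
        return len(self.genes) * len(self.situations)

    def is_trivial(self) -> bool:
        """A bicluster with at most one gene or at most one situation."""
        return len(self.genes) <= 1 or len(self.situations) <= 1


@dataclass
class BiclusterSystem:
    """A collection of ordinary biclusters; its extension is the union of rectangles."""

    biclusters: list[Bicluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)


class WeightedTermSet:
    """A conjunction of weighted, possibly negated ontology terms.

    Each term appears at most once with a weight in (0; 1] and a sign.  A
    positive term is matched by an entity whose (closed) annotation contains
    the term; a negated term is matched when the term is absent.  Crisp term
    sets carry weight 1 on every term.  The empty set is the vacuous
    conjunction: it is satisfied by every entity and its matched weight is 0.
    """

    __slots__ = ("_entries",)

    def __init__(self, entries: Iterable[tuple[str, float] | tuple[str, float, bool]] = ()):
        store: dict[str, tuple[float, bool]] = {}
        for entry in entries:
            term, weight = entry[0], float(entry[1])
            positive = bool(entry[2]) if len(entry) > 2 else True
            if not (0.0 < weight <= 1.0):
                raise ParameterError(f"term weight must lie in (0;1], got {weight} for {term!r}")
            if term in store:
                raise ParameterError(f"duplicate term in weighted set: {term!r}")
            store[term] = (weight, positive)
        self._entries = store

    @classmethod
    def crisp(cls, terms: Iterable[str]) -> "WeightedTermSet":
        return cls((t, 1.0) for t in terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._entries)

    def items(self) -> Iterator[tuple[str, float, bool]]:
        for term, (w, pos) in self._entries.items():
            yield term, w, pos

    def is_crisp(self) -> bool:
        return all(w == 1.0 for w, _ in self._entries.values())

    def satisfied_by(self, annotation: frozenset[str]) -> bool:
        """Conjunctive (crisp) satisfaction: every positive term present, every negated absent."""
        return all(
            (term in annotation) == positive for term, (_, positive) in self._entries.items()
        )

    def matched_weight(self, annotation: frozenset[str]) -> float:
        """Sum of weights of literals whose presence/absence condition holds."""
        return sum(
            w
            for term, (w, positive) in self._entries.items()
            if (term in annotation) == positive
        )

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WeightedTermSet) and self._entries == other._entries

    def __repr__(self) -> str:
        lits = ", ".join(
            f"{'' if pos else '¬'}{t}:{w:.3g}" for t, (w, pos) in self._entries.items()
        )
        return f"WeightedTermSet({{{lits}}})"


@dataclass
class SemanticBicluster:
    """An intensional bicluster: weighted term conjunctions over both dimensions."""

    gene_terms: WeightedTermSet
    situation_terms: WeightedTermSet

    def is_crisp(self) -> bool:
        return self.gene_terms.is_crisp() and self.situation_terms.is_crisp()


@dataclass
class SemanticBiclusterSystem:
    """A collection of semantic biclusters, optionally using negated literals."""

    biclusters: list[SemanticBicluster] = field(default_factory=list)
    literal_mode: bool = False  # True when negated terms (tree language) may occur

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[SemanticBicluster]:
        return iter(self.biclusters)


# ---------------------------------------------------------------------------
# Operations on ordinary systems


def extension(
    system: BiclusterSystem, matrix: ExpressionMatrix
) -> set[tuple[str, str]]:
    """Union of the rectangles of all biclusters, as (gene_id, situation_id) pairs."""
    out: set[tuple[str, str]] = set()
    for bc in system:
        for g in bc.genes:
            matrix._gene_pos(g)
        for s in bc.situations:
            matrix._situation_pos(s)
        out.update((g, s) for g in bc.genes for s in bc.situations)
    return out


def _extension_mask(system: BiclusterSystem, matrix: ExpressionMatrix) -> np.ndarray:
    """Boolean indicator of the extension, aligned with ``matrix.values``."""
    mask = np.zeros(matrix.shape, dtype=bool)
    for bc in system:
        gi = [matrix._gene_pos(g) for g in bc.genes]
        sj = [matrix._situation_pos(s) for s in bc.situations]
        if gi and sj:
            mask[np.ix_(gi, sj)] = True
    return mask


def training_accuracy(system: BiclusterSystem, matrix: ExpressionMatrix) -> float:
    """In-sample accuracy of the system viewed as a cell classifier.

    The system predicts 1 inside its extension and 0 outside; the score is
    the fraction of matrix cells where prediction and value agree.
    """
    if matrix.values.size == 0:
        raise DimensionError("training accuracy is undefined on an empty matrix")
    mask = _extension_mask(system, matrix)
    agree = (matrix.values.astype(bool) == mask).sum()
    return float(agree) / matrix.values.size


def regularized_score(
    system: BiclusterSystem, matrix: ExpressionMatrix, lam: float = 0.0
) -> float:
    """Training accuracy plus a parsimony bonus ``lam / |B|``.

    The bonus rewards explaining the matrix with few biclusters and thereby
    counteracts the degenerate optimum of one single-cell bicluster per 1.
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    acc = training_accuracy(system, matrix)
    if lam == 0:
        return acc
    if len(system) == 0:
        raise ParameterError("regularizer lambda/|B| is undefined for an empty system")
    return acc + lam / len(system)


# ---------------------------------------------------------------------------
# Operations on semantic systems


def induce_bicluster(
    sb: SemanticBicluster,
    genes: Iterable[str],
    situations: Iterable[str],
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
) -> Bicluster:
    """Induce the ordinary bicluster of ``sb`` on a universe of genes and situations.

    A gene belongs iff it satisfies every literal of the gene-term
    conjunction; analogously for situations.  An empty conjunction is
    vacuously true and induces the whole universe on that side.
    """
    g_sel = frozenset(
        g for g in genes if sb.gene_terms.satisfied_by(gene_annotations.terms_of(g))
    )
    s_sel = frozenset(
        s
        for s in situations
        if sb.situation_terms.satisfied_by(situation_annotations.terms_of(s))
    )
    return Bicluster(g_sel, s_sel)


def induce_system(
    system: SemanticBiclusterSystem,
    genes: Iterable[str],
    situations: Iterable[str],
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
) -> BiclusterSystem:
    """Per-bicluster induction of an ordinary system on the given universe."""
    genes = list(genes)
    situations = list(situations)
    return BiclusterSystem(
        [
            induce_bicluster(sb, genes, situations, gene_annotations, situation_annotations)
            for sb in system
        ]
    )


def semantic_extension(
    system: SemanticBiclusterSystem,
    genes: Iterable[str],
    situations: Iterable[str],
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
) -> set[tuple[str, str]]:
    """Union of induced rectangles over an arbitrary universe.

    Restricted to the training universe this coincides with the ordinary
    extension of the induced system; unrestricted it classifies unseen genes
    and situations as well.
    """
    genes = list(genes)
    situations = list(situations)
    out: set[tuple[str, str]] = set()
    for sb in system:
        bc = induce_bicluster(sb, genes, situations, gene_annotations, situation_annotations)
        out.update((g, s) for g in bc.genes for s in bc.situations)
    return out


def soft_classify(
    system: SemanticBiclusterSystem,
    gene: str,
    situation: str,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    theta_g: float,
    theta_s: float,
) -> int:
    """Soft membership of a (gene, situation) pair in the system's extension.

    Returns 1 iff some bicluster supports the pair: the weights of its
    gene-term literals matched by the gene's annotation sum to at least
    ``theta_g`` and, simultaneously, the matched situation-term weights sum
    to at least ``theta_s``.  Monotone non-increasing in both thresholds.
    """
    g_ann = gene_annotations.terms_of(gene)
    s_ann = situation_annotations.terms_of(situation)
    for sb in system:
        if (
            sb.gene_terms.matched_weight(g_ann) >= theta_g
            and sb.situation_terms.matched_weight(s_ann) >= theta_s
        ):
            return 1
    return 0
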