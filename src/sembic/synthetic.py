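"""Seeded generator of annotated matrices with planted semantic biclusters.

The generator emulates the structure of GO/DLO/DAO-annotated expression
tables: two random rooted ontology DAGs (gene side and situation side),
entity-to-term annotation relations, and a binary matrix whose 1-cells are
the extension of a planted system of crisp semantic biclusters, optionally
corrupted by independent 0->1 and 1->0 flips.  Planted defining terms are
ontology leaves, so the ancestor closure introduces the correlated
redundant terms characteristic of real GO annotations.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnnotationRelation,
    ExpressionMatrix,
    SemanticBicluster,
    SemanticBiclusterSystem,
    WeightedTermSet,
    semantic_extension,
)
from .enrichment import EDGE_TYPES, Ontology
from .errors import ParameterError

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticInstance", "random_ontology", "plant"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of a synthetic instance.

    Defaults are sized to the imaginal-disc scale (~1,200 genes in 72
    situations) with a handful of planted biclusters, mild annotation
    spillover and low flip noise.
    """

    n_genes: int = 1200
    n_situations: int = 72
    gene_terms: int = 400
    situation_terms: int = 150
    dag_depth: int = 3
    n_planted: int = 4
    terms_per_side: int = 4
    fp_noise: float = 0.0
    fn_noise: float = 0.0
    background_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_situations < 1:
            raise ParameterError("matrix dimensions must be positive")
        if self.gene_terms < 1 or self.situation_terms < 1:
            raise ParameterError("vocabulary sizes must be positive")
        if self.n_planted < 1 or self.terms_per_side < 1:
            raise ParameterError("need at least one planted bicluster and term per side")
        if not (0 <= self.fp_noise < 0.5 and 0 <= self.fn_noise < 0.5):
            raise ParameterError("noise rates must lie in [0;0.5)")
        if not (0 <= self.background_density < 1):
            raise ParameterError("background_density must lie in [0;1)")


@dataclass
class GroundTruth:
    """The planted semantic system, its extension and the pre-noise labels."""

    system: SemanticBiclusterSystem
    extension: set[tuple[str, str]]
    clean_labels: np.ndarray  # uint8 (n_genes, n_situations)
    planted_gene_terms: list[frozenset[str]] = field(default_factory=list)
    planted_situation_terms: list[frozenset[str]] = field(default_factory=list)


@dataclass
class SyntheticInstance:
    matrix: ExpressionMatrix
    gene_annotations: AnnotationRelation
    situation_annotations: AnnotationRelation
    gene_ontology: Ontology
    situation_ontology: Ontology
    truth: GroundTruth


def random_ontology(
    n_terms: int,
    dag_depth: int = 3,
    seed: int | np.random.Generator = 0,
    prefix: str = "T",
) -> Ontology:
    """Random rooted DAG: each non-root term gets 1-2 parents from shallower levels.

    Acyclic by construction — edges always point from a deeper to a
    strictly shallower level, with a single root at level 0.
    """
    if n_terms < 1:
        raise ParameterError("n_terms must be >= 1")
    if dag_depth < 1:
        raise ParameterError("dag_depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    names = {t: f"{prefix.lower()} term {i}" for i, t in enumerate(ids)}
    levels = np.zeros(n_terms, dtype=int)
    if n_terms > 1:
        levels[1:] = 1 + np.arange(n_terms - 1) % dag_depth  # every level populated
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        shallower = np.flatnonzero(levels[:i] < levels[i])
        if not shallower.size:
            shallower = np.array([0])
        n_parents = int(rng.integers(1, 3)) if shallower.size > 1 else 1
        parents = rng.choice(shallower, size=min(n_parents, shallower.size), replace=False)
        for p in parents:
            etype = EDGE_TYPES[rng.choice(3, p=[0.6, 0.25, 0.15])]
            edges.append((ids[i], ids[int(p)], etype))
    return Ontology(names, edges)


def _leaves_deepest_first(onto: Ontology) -> list[str]:
    """Leaves ordered by decreasing longest-path depth to a root (ties by id)."""
    import networkx as nx

    depth = {t: 0 for t in onto.roots()}
    for t in reversed(list(nx.topological_sort(onto.graph))):  # parents before children
        if t not in depth:
            depth[t] = 1 + max(depth[p] for _, p in onto.graph.out_edges(t))
    return sorted(onto.leaves(), key=lambda t: (-depth[t], t))


def plant(config: GeneratorConfig | None = None) -> SyntheticInstance:
    """Generate a matrix whose signal is the extension of planted semantic biclusters.

    Each planted bicluster picks ``terms_per_side`` distinct leaf terms per
    ontology and a random block of member genes and situations; members are
    annotated with the defining terms, non-members receive each defining
    term independently at rate ``background_density`` (annotation
    spillover).  Every entity additionally carries a few random decoy
    terms.  Clean labels are 1 exactly on the extension induced by the
    annotations; flip noise is applied afterwards (1->0 at ``fn_noise``,
    0->1 at ``fp_noise``).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    gene_onto = random_ontology(config.gene_terms, config.dag_depth, rng, prefix="G")
    sit_onto = random_ontology(config.situation_terms, config.dag_depth, rng, prefix="S")

    gene_ids = tuple(f"gene{i:05d}" for i in range(config.n_genes))
    sit_ids = tuple(f"situation{i:03d}" for i in range(config.n_situations))

    g_leaves = _leaves_deepest_first(gene_onto)
    s_leaves = _leaves_deepest_first(sit_onto)
    need_g = config.n_planted * config.terms_per_side
    need_s = config.n_planted * config.terms_per_side
    if len(g_leaves) < need_g or len(s_leaves) < need_s:
        raise ParameterError(
            "not enough ontology leaves for the requested planting: "
            f"have {len(g_leaves)} gene / {len(s_leaves)} situation leaves, "
            f"need {need_g} / {need_s}"
        )
    # defining terms are the most specific (deepest) leaves: annotating to
    # deep terms is how curated annotations behave, and it guarantees each
    # defining conjunction drags a chain of ancestor terms along with it
    g_pick = rng.permutation(need_g)
    s_pick = rng.permutation(need_s)

    g_ann: dict[str, set[str]] = {g: set() for g in gene_ids}
    s_ann: dict[str, set[str]] = {s: set() for s in sit_ids}

    # planted member blocks are disjoint between biclusters (a shuffled
    # partition on each dimension); annotation spillover may still create
    # extra members, so the realized extension is induced from the
    # annotations, not from these index blocks
    block_genes = min(max(2, round(0.10 * config.n_genes)), config.n_genes // config.n_planted)
    block_sits = min(
        max(2, round(0.20 * config.n_situations)), config.n_situations // config.n_planted
    )
    if block_genes < 1 or block_sits < 1:
        raise ParameterError("too many planted biclusters for the matrix dimensions")
    gene_perm = rng.permutation(config.n_genes)
    sit_perm = rng.permutation(config.n_situations)

    system = SemanticBiclusterSystem([])
    planted_g_terms: list[frozenset[str]] = []
    planted_s_terms: list[frozenset[str]] = []
    for k in range(config.n_planted):
        gt = frozenset(
            g_leaves[i]
            for i in g_pick[k * config.terms_per_side : (k + 1) * config.terms_per_side]
        )
        st = frozenset(
            s_leaves[i]
            for i in s_pick[k * config.terms_per_side : (k + 1) * config.terms_per_side]
        )
        members_g = gene_perm[k * block_genes : (k + 1) * block_genes]
        members_s = sit_perm[k * block_sits : (k + 1) * block_sits]
        for i in members_g:
            g_ann[gene_ids[i]] |= gt
        for j in members_s:
            s_ann[sit_ids[j]] |= st
        if config.background_density > 0:
            for t in sorted(gt):
                spill = rng.random(config.n_genes) < config.background_density
                for i in np.flatnonzero(spill):
                    g_ann[gene_ids[i]].add(t)
            for t in sorted(st):
                spill = rng.random(config.n_situations) < config.background_density
                for j in np.flatnonzero(spill):
                    s_ann[sit_ids[j]].add(t)
        system.biclusters.append(
            SemanticBicluster(WeightedTermSet.crisp(gt), WeightedTermSet.crisp(st))
        )
        planted_g_terms.append(gt)
        planted_s_terms.append(st)

    # decoy terms: unused leaves scattered uniformly, two per entity on average
    used_g = {g_leaves[i] for i in g_pick}
    used_s = {s_leaves[i] for i in s_pick}
    decoys_g = sorted(set(g_leaves) - used_g)
    decoys_s = sorted(set(s_leaves) - used_s)
    for g in gene_ids:
        if decoys_g:
            k = int(rng.integers(1, 4))
            for i in rng.choice(len(decoys_g), size=min(k, len(decoys_g)), replace=False):
                g_ann[g].add(decoys_g[int(i)])
    # a situation carries a single primary location term (plus its ancestor
    # chain after closure), mirroring anatomical annotation practice
    for s in sit_ids:
        if decoys_s:
            s_ann[s].add(decoys_s[int(rng.integers(len(decoys_s)))])

    gene_rel = AnnotationRelation(g_ann)
    sit_rel = AnnotationRelation(s_ann)

    ext = semantic_extension(system, gene_ids, sit_ids, gene_rel, sit_rel)
    if not ext:
        raise ParameterError("planted term combinations induced an empty extension")
    clean = np.zeros((config.n_genes, config.n_situations), dtype=np.uint8)
    g_idx = {g: i for i, g in enumerate(gene_ids)}
    s_idx = {s: j for j, s in enumerate(sit_ids)}
    for g, s in ext:
        clean[g_idx[g], s_idx[s]] = 1

    noisy = clean.copy()
    if config.fn_noise > 0:
        flips = (rng.random(noisy.shape) < config.fn_noise) & (clean == 1)
        noisy[flips] = 0
    if config.fp_noise > 0:
        flips = (rng.random(noisy.shape) < config.fp_noise) & (clean == 0)
        noisy[flips] = 1

    matrix = ExpressionMatrix(gene_ids, sit_ids, noisy)
    truth = GroundTruth(system, ext, clean, planted_g_terms, planted_s_terms)
    return SyntheticInstance(matrix, gene_rel, sit_rel, gene_onto, sit_onto, truth)
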