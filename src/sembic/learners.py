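"""Reduction of semantic biclustering to propositional concept learning.

The expression matrix is unrolled into one instance per cell: the features
are binary indicators of the gene's and the situation's ontology terms, and
the class is the cell's expression value.  A separate-and-conquer rule
learner (RIPPER family) or a gain-ratio decision tree (C4.5 family) is then
trained to predict expression.  Because every conjunctive rule over such
features selects a set of genes times a set of situations, each rule — and
each root-to-positive-leaf path of a tree — is exactly a (crisp) semantic
bicluster; tree paths may additionally carry negated terms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    AnnotationRelation,
    ExpressionMatrix,
    SemanticBicluster,
    SemanticBiclusterSystem,
    WeightedTermSet,
)
from .errors import MappingError, ParameterError

__all__ = [
    "UnrolledDataset",
    "Rule",
    "RuleList",
    "DecisionTree",
    "TreeNode",
    "LearnConfig",
    "unroll",
    "select_features",
    "learn_rules",
    "learn_tree",
    "tree_to_rules",
    "rules_to_semantic_biclusters",
    "predict_confidence",
    "laplace",
]

GENE_SIDE = "gene"
SITUATION_SIDE = "situation"


def laplace(p: int, n: int) -> float:
    """Laplace-corrected positive-class confidence (p+1)/(p+n+2)."""
    return (p + 1) / (p + n + 2)


@dataclass
class UnrolledDataset:
    """Instance-per-cell view of an annotated expression matrix.

    Row ``i`` corresponds, in row-major order, to the cell
    (gene ``i // n_situations``, situation ``i % n_situations``).  Gene and
    situation indicator blocks are stored per entity and broadcast on
    demand, so the full |G|*|S| x (|gamma|+|sigma|) design matrix is only
    materialized when a learner asks for it.
    """

    gene_ids: tuple[str, ...]
    situation_ids: tuple[str, ...]
    gene_vocab: tuple[str, ...]
    situation_vocab: tuple[str, ...]
    gene_features: np.ndarray  # uint8 (n_genes, |gamma|)
    situation_features: np.ndarray  # uint8 (n_situations, |sigma|)
    labels: np.ndarray  # uint8 (n_genes * n_situations,)

    def __post_init__(self) -> None:
        ng, ns = len(self.gene_ids), len(self.situation_ids)
        if self.gene_features.shape != (ng, len(self.gene_vocab)):
            raise ParameterError("gene feature block shape mismatch")
        if self.situation_features.shape != (ns, len(self.situation_vocab)):
            raise ParameterError("situation feature block shape mismatch")
        if self.labels.shape != (ng * ns,):
            raise ParameterError("label vector must have one entry per matrix cell")

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.gene_vocab) + len(self.situation_vocab)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.gene_vocab + self.situation_vocab

    def feature_side(self, j: int) -> str:
        return GENE_SIDE if j < len(self.gene_vocab) else SITUATION_SIDE

    def back_reference(self, row: int) -> tuple[str, str]:
        ns = len(self.situation_ids)
        return self.gene_ids[row // ns], self.situation_ids[row % ns]

    def feature_matrix(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Materialize the boolean design matrix for the given row indices."""
        ns = len(self.situation_ids)
        idx = np.arange(self.n_rows) if rows is None else np.asarray(rows)
        g = idx // ns
        s = idx % ns
        return np.hstack(
            [self.gene_features[g].astype(bool), self.situation_features[s].astype(bool)]
        )

    def to_matrix(self) -> ExpressionMatrix:
        """Regroup rows by their back-references into the original matrix."""
        ng, ns = len(self.gene_ids), len(self.situation_ids)
        return ExpressionMatrix(
            self.gene_ids, self.situation_ids, self.labels.reshape(ng, ns)
        )


def unroll(
    matrix: ExpressionMatrix,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
    gene_vocab: Sequence[str],
    situation_vocab: Sequence[str],
) -> UnrolledDataset:
    """Unroll a matrix into |G|*|S| instances of term indicators plus class."""
    gene_vocab = tuple(gene_vocab)
    situation_vocab = tuple(situation_vocab)
    g_feat = np.zeros((len(matrix.gene_ids), len(gene_vocab)), dtype=np.uint8)
    for i, g in enumerate(matrix.gene_ids):
        ann = gene_annotations.terms_of(g)
        for j, t in enumerate(gene_vocab):
            if t in ann:
                g_feat[i, j] = 1
    s_feat = np.zeros((len(matrix.situation_ids), len(situation_vocab)), dtype=np.uint8)
    for i, s in enumerate(matrix.situation_ids):
        ann = situation_annotations.terms_of(s)
        for j, t in enumerate(situation_vocab):
            if t in ann:
                s_feat[i, j] = 1
    return UnrolledDataset(
        matrix.gene_ids,
        matrix.situation_ids,
        gene_vocab,
        situation_vocab,
        g_feat,
        s_feat,
        matrix.values.reshape(-1).copy(),
    )


def select_features(data: UnrolledDataset, min_fraction: float = 0.001) -> UnrolledDataset:
    """Drop features positive in fewer than ceil(min_fraction * n_rows) instances.

    Rare terms cannot generalize over a reasonable number of cells and only
    slow the learners down.  The class column and back-references are always
    preserved; ``min_fraction = 0`` is the identity.
    """
    if not (0 <= min_fraction < 1):
        raise ParameterError("min_fraction must lie in [0;1)")
    threshold = math.ceil(min_fraction * data.n_rows)
    ns, ng = len(data.situation_ids), len(data.gene_ids)
    # each gene-term positive appears once per situation, and vice versa
    g_counts = data.gene_features.sum(axis=0).astype(np.int64) * ns
    s_counts = data.situation_features.sum(axis=0).astype(np.int64) * ng
    g_keep = g_counts >= threshold
    s_keep = s_counts >= threshold
    if not g_keep.any() and not s_keep.any() and data.n_features > 0:
        warnings.warn("feature selection removed every feature", stacklevel=2)
    return UnrolledDataset(
        data.gene_ids,
        data.situation_ids,
        tuple(t for t, k in zip(data.gene_vocab, g_keep) if k),
        tuple(t for t, k in zip(data.situation_vocab, s_keep) if k),
        data.gene_features[:, g_keep],
        data.situation_features[:, s_keep],
        data.labels,
    )


# ---------------------------------------------------------------------------
# Rules


@dataclass(frozen=True)
class Rule:
    """A conjunctive rule over signed gene and situation terms predicting expression.

    Literals are (term, positive) pairs; ``p`` and ``n`` are the positive
    and negative training instances the rule covers.
    """

    gene_literals: frozenset[tuple[str, bool]]
    situation_literals: frozenset[tuple[str, bool]]
    p: int = 0
    n: int = 0

    @property
    def confidence(self) -> float:
        return laplace(self.p, self.n)

    def has_negation(self) -> bool:
        return any(not pos for _, pos in self.gene_literals | self.situation_literals)

    def matches(self, gene_terms: frozenset[str], situation_terms: frozenset[str]) -> bool:
        return all((t in gene_terms) == pos for t, pos in self.gene_literals) and all(
            (t in situation_terms) == pos for t, pos in self.situation_literals
        )

    @staticmethod
    def from_terms(
        literals: Iterable[tuple[str, bool]],
        gene_vocab: Iterable[str],
        situation_vocab: Iterable[str],
        p: int = 0,
        n: int = 0,
    ) -> "Rule":
        gv, sv = set(gene_vocab), set(situation_vocab)
        g_lits, s_lits = set(), set()
        for term, pos in literals:
            in_g, in_s = term in gv, term in sv
            if in_g == in_s:
                raise MappingError(
                    f"term {term!r} belongs to "
                    + ("both vocabularies" if in_g else "neither vocabulary")
                )
            (g_lits if in_g else s_lits).add((term, pos))
        return Rule(frozenset(g_lits), frozenset(s_lits), p, n)


@dataclass
class RuleList:
    """An ordered rule list with first-match confidence semantics.

    A pair matching no rule receives confidence 0 (the default
    no-expression prediction).
    """

    rules: list[Rule] = field(default_factory=list)
    gene_vocab: tuple[str, ...] = ()
    situation_vocab: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def confidence(self, gene_terms: frozenset[str], situation_terms: frozenset[str]) -> float:
        for rule in self.rules:
            if rule.matches(gene_terms, situation_terms):
                return rule.confidence
        return 0.0


@dataclass(frozen=True)
class LearnConfig:
    """Shared knobs of the rule and tree learners.

    ``split_criterion`` selects the tree's attribute test: plain
    information gain (default) or gain ratio with the average-gain guard.
    On term-indicator features, where the ancestor closure yields many
    rare, correlated attributes, the ratio's preference for low-entropy
    splits fragments the tree badly; plain gain keeps it compact.
    """

    seed: int = 0
    min_leaf: int = 2  # minimal instance count at a tree leaf
    tree_holdout: float = 0.2  # fraction held out for reduced-error pruning
    max_rules: int = 200
    max_literals: int = 20
    split_criterion: str = "gain"  # "gain" | "gain_ratio"


def _stratified_mask(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask selecting ~fraction of rows from each class."""
    mask = np.zeros(len(y), dtype=bool)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        take = int(round(fraction * len(idx)))
        mask[rng.permutation(idx)[:take]] = True
    return mask


def _foil_best_literal(
    X: np.ndarray, y: np.ndarray, covered: np.ndarray, used: set[int]
) -> tuple[int, float]:
    """Feature index of the positive literal with maximal FOIL gain, or (-1, 0)."""
    p0 = int((covered & y).sum())
    n0 = int((covered & ~y).sum())
    if p0 == 0:
        return -1, 0.0
    base = math.log2(p0 / (p0 + n0))
    cov_X = X[covered]
    cov_y = y[covered]
    p1 = (cov_X & cov_y[:, None]).sum(axis=0).astype(float)
    n1 = (cov_X & ~cov_y[:, None]).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = p1 * (np.log2(p1 / (p1 + n1)) - base)
    gain[p1 == 0] = -np.inf
    for j in used:
        gain[j] = -np.inf
    best = int(np.argmax(gain))  # ties -> lowest feature index
    return (best, float(gain[best])) if np.isfinite(gain[best]) and gain[best] > 0 else (-1, 0.0)


def _rule_cover(X: np.ndarray, features: Sequence[int]) -> np.ndarray:
    cov = np.ones(len(X), dtype=bool)
    for j in features:
        cov &= X[:, j]
    return cov


def learn_rules(data: UnrolledDataset, config: LearnConfig | None = None) -> RuleList:
    """Separate-and-conquer induction of a positive-expression rule list.

    The data is split 2:1 into grow and prune partitions (stratified,
    seeded).  Each rule is grown by adding the presence literal with the
    best FOIL gain until it covers no grow negatives, then pruned by
    deleting trailing literals to maximize (p-n)/(p+n) on the prune
    partition.  Rule addition stops when grow positives are exhausted or
    the latest rule errs on more than half of its prune coverage; covered
    positives are removed between rules.  Coverage counts on the full data
    give each rule its Laplace confidence.
    """
    config = config or LearnConfig()
    rng = np.random.default_rng(config.seed)
    y = data.labels.astype(bool)
    if not y.any() or data.n_features == 0:
        return RuleList([], data.gene_vocab, data.situation_vocab)
    X = data.feature_matrix()

    grow_mask = _stratified_mask(y, 2 / 3, rng)
    prune_mask = ~grow_mask
    active = np.ones(len(y), dtype=bool)  # rows not yet claimed by an accepted rule
    rules: list[Rule] = []
    names = data.feature_names

    while len(rules) < config.max_rules and (active & grow_mask & y).any():
        grow = active & grow_mask
        # --- grow phase
        feats: list[int] = []
        covered = grow.copy()
        while (covered & ~y).any() and len(feats) < config.max_literals:
            j, gain = _foil_best_literal(X, y, covered, set(feats))
            if j < 0:
                break
            feats.append(j)
            covered &= X[:, j]
        if not feats or not (covered & y).any():
            break
        # --- prune phase: keep the prefix maximizing (p - n) / (p + n)
        prune = active & prune_mask
        best_len, best_v = len(feats), -np.inf
        for k in range(len(feats), 0, -1):
            cov = prune & _rule_cover(X, feats[:k])
            p = int((cov & y).sum())
            n = int((cov & ~y).sum())
            v = (p - n) / (p + n) if (p + n) else 0.0
            if v > best_v:  # ties keep the longer, more specific prefix
                best_len, best_v = k, v
        feats = feats[:best_len]
        cov_prune = prune & _rule_cover(X, feats)
        p_pr = int((cov_prune & y).sum())
        n_pr = int((cov_prune & ~y).sum())
        if (p_pr + n_pr) > 0 and n_pr / (p_pr + n_pr) > 0.5:
            break  # prune-split error above 50%: stop adding rules
        cov_all = _rule_cover(X, feats)
        rule = Rule.from_terms(
            [(names[j], True) for j in feats],
            data.gene_vocab,
            data.situation_vocab,
            p=int((cov_all & y).sum()),
            n=int((cov_all & ~y).sum()),
        )
        rules.append(rule)
        active &= ~(cov_all & y)  # remove covered positives
    return RuleList(rules, data.gene_vocab, data.situation_vocab)


# ---------------------------------------------------------------------------
# Decision tree


@dataclass
class TreeNode:
    """Binary node testing the presence of one term, or a leaf with counts."""

    feature: int | None = None  # None for leaves
    left: "TreeNode | None" = None  # feature absent
    right: "TreeNode | None" = None  # feature present
    p: int = 0
    n: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prediction(self) -> int:
        return 1 if self.p > self.n else 0  # ties default to no expression

    @property
    def confidence(self) -> float:
        return laplace(self.p, self.n)


@dataclass
class DecisionTree:
    """A binary decision tree over term-presence features."""

    root: TreeNode
    gene_vocab: tuple[str, ...]
    situation_vocab: tuple[str, ...]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.gene_vocab + self.situation_vocab

    def _descend(self, gene_terms: frozenset[str], situation_terms: frozenset[str]) -> TreeNode:
        names = self.feature_names
        node = self.root
        while not node.is_leaf:
            term = names[node.feature]
            present = term in gene_terms if node.feature < len(self.gene_vocab) else (
                term in situation_terms
            )
            node = node.right if present else node.left
        return node

    def confidence(self, gene_terms: frozenset[str], situation_terms: frozenset[str]) -> float:
        return self._descend(gene_terms, situation_terms).confidence

    def predict(self, gene_terms: frozenset[str], situation_terms: frozenset[str]) -> int:
        return self._descend(gene_terms, situation_terms).prediction

    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)


def _entropy(p: int, n: int) -> float:
    tot = p + n
    if tot == 0 or p == 0 or n == 0:
        return 0.0
    fp, fn_ = p / tot, n / tot
    return -fp * math.log2(fp) - fn_ * math.log2(fn_)


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    used: set[int],
    criterion: str = "gain",
) -> int:
    """Feature with the best split score on the given rows, or -1.

    ``criterion="gain"`` scores by information gain; ``"gain_ratio"`` by
    gain ratio restricted to features with at least average positive gain
    (without the guard, rare features with near-zero split info dominate).
    Ties break on the lowest feature index.
    """
    if X.shape[1] == 0:
        return -1
    sub_X = X[rows]
    sub_y = y[rows]
    p = int(sub_y.sum())
    n = len(sub_y) - p
    base = _entropy(p, n)
    if base == 0.0:
        return -1
    total = len(sub_y)
    p_right = (sub_X & sub_y[:, None]).sum(axis=0).astype(float)
    t_right = sub_X.sum(axis=0).astype(float)
    n_right = t_right - p_right
    t_left = total - t_right
    p_left = p - p_right
    n_left = t_left - p_left

    def ent(pp: np.ndarray, nn: np.ndarray) -> np.ndarray:
        tot = pp + nn
        with np.errstate(divide="ignore", invalid="ignore"):
            fp = np.where(tot > 0, pp / np.maximum(tot, 1), 0.0)
            e = np.where(
                (fp > 0) & (fp < 1),
                -fp * np.log2(np.maximum(fp, 1e-12))
                - (1 - fp) * np.log2(np.maximum(1 - fp, 1e-12)),
                0.0,
            )
        return e

    cond = (t_left * ent(p_left, n_left) + t_right * ent(p_right, n_right)) / total
    gain = base - cond
    gain[(t_left == 0) | (t_right == 0)] = -np.inf  # degenerate splits
    for j in used:
        gain[j] = -np.inf

    if criterion == "gain":
        score = gain
    elif criterion == "gain_ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            fl = t_left / total
            split_info = np.where(
                (fl > 0) & (fl < 1),
                -fl * np.log2(np.maximum(fl, 1e-12))
                - (1 - fl) * np.log2(np.maximum(1 - fl, 1e-12)),
                0.0,
            )
            score = np.where(split_info > 0, gain / split_info, -np.inf)
        usable = np.isfinite(score) & (gain > 1e-12)
        if not usable.any():
            return -1
        mean_gain = gain[usable].mean()
        score = np.where(usable & (gain >= mean_gain - 1e-12), score, -np.inf)
    else:
        raise ParameterError(f"unknown split criterion {criterion!r}")

    best = int(np.argmax(score))
    return best if np.isfinite(score[best]) and gain[best] > 1e-12 else -1


def learn_tree(data: UnrolledDataset, config: LearnConfig | None = None) -> DecisionTree:
    """Top-down induction of a binary decision tree.

    Growth stops on class purity, on fewer than ``min_leaf`` instances, or
    when no split has positive information gain.  The grown tree is then
    simplified by reduced-error pruning against an internal stratified
    holdout (default 20%, seeded): a subtree is collapsed to a leaf
    whenever the collapse does not increase holdout error.
    """
    config = config or LearnConfig()
    if data.n_rows == 0:
        raise ParameterError("cannot learn a tree from an empty dataset")
    rng = np.random.default_rng(config.seed)
    y = data.labels.astype(bool)
    X = data.feature_matrix()
    hold_mask = _stratified_mask(y, config.tree_holdout, rng)
    train_rows = np.flatnonzero(~hold_mask)
    if not train_rows.size:
        train_rows = np.arange(len(y))

    def build(rows: np.ndarray, used: set[int]) -> TreeNode:
        p = int(y[rows].sum())
        n = len(rows) - p
        node = TreeNode(p=p, n=n)
        if p == 0 or n == 0 or len(rows) < max(2, config.min_leaf):
            return node
        j = _best_split(X, y, rows, used, config.split_criterion)
        if j < 0:
            return node
        right_rows = rows[X[rows, j]]
        left_rows = rows[~X[rows, j]]
        if len(right_rows) == 0 or len(left_rows) == 0:
            return node
        node.feature = j
        node.left = build(left_rows, used | {j})
        node.right = build(right_rows, used | {j})
        return node

    root = build(train_rows, set())

    # reduced-error pruning on the holdout
    hold_rows = np.flatnonzero(hold_mask)

    def holdout_errors(node: TreeNode, rows: np.ndarray) -> int:
        if not rows.size:
            return 0
        if node.is_leaf:
            return int((y[rows] != bool(node.prediction)).sum())
        return holdout_errors(node.left, rows[~X[rows, node.feature]]) + holdout_errors(
            node.right, rows[X[rows, node.feature]]
        )

    def prune(node: TreeNode, rows: np.ndarray) -> None:
        if node.is_leaf:
            return
        prune(node.left, rows[~X[rows, node.feature]])
        prune(node.right, rows[X[rows, node.feature]])
        leaf_err = int((y[rows] != bool(node.prediction)).sum()) if rows.size else 0
        if leaf_err <= holdout_errors(node, rows):
            node.feature, node.left, node.right = None, None, None

    if hold_rows.size:  # an empty holdout carries no pruning evidence
        prune(root, hold_rows)
    return DecisionTree(root, data.gene_vocab, data.situation_vocab)


def tree_to_rules(tree: DecisionTree) -> list[Rule]:
    """One rule per positive leaf; literals signed by the branch taken."""
    names = tree.feature_names
    n_gene = len(tree.gene_vocab)
    rules: list[Rule] = []

    def walk(node: TreeNode, path: list[tuple[int, bool]]) -> None:
        if node.is_leaf:
            if node.prediction == 1:
                g_lits = frozenset(
                    (names[j], pos) for j, pos in path if j < n_gene
                )
                s_lits = frozenset(
                    (names[j], pos) for j, pos in path if j >= n_gene
                )
                rules.append(Rule(g_lits, s_lits, node.p, node.n))
            return
        walk(node.left, path + [(node.feature, False)])
        walk(node.right, path + [(node.feature, True)])

    walk(tree.root, [])
    return rules


def rules_to_semantic_biclusters(rules: Iterable[Rule] | RuleList) -> SemanticBiclusterSystem:
    """Convert rules to crisp semantic biclusters (weight 1, signs preserved)."""
    rule_seq = list(rules.rules if isinstance(rules, RuleList) else rules)
    system = SemanticBiclusterSystem([], literal_mode=any(r.has_negation() for r in rule_seq))
    for rule in rule_seq:
        system.biclusters.append(
            SemanticBicluster(
                WeightedTermSet((t, 1.0, pos) for t, pos in sorted(rule.gene_literals)),
                WeightedTermSet((t, 1.0, pos) for t, pos in sorted(rule.situation_literals)),
            )
        )
    return system


def predict_confidence(
    model: RuleList | DecisionTree,
    gene: str,
    situation: str,
    gene_annotations: AnnotationRelation,
    situation_annotations: AnnotationRelation,
) -> float:
    """Positive-expression confidence of a model for an arbitrary (gene, situation) pair."""
    g_terms = gene_annotations.terms_of(gene)
    s_terms = situation_annotations.terms_of(situation)
    return model.confidence(g_terms, s_terms)
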