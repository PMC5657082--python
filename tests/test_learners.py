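"""Unrolling, rule induction, tree learning and bicluster conversion."""

import numpy as np
import pytest

from sembic.core import AnnotationRelation, ExpressionMatrix, extension, induce_system
from sembic.errors import MappingError, ParameterError
from sembic.learners import (
    LearnConfig,
    Rule,
    RuleList,
    learn_rules,
    learn_tree,
    predict_confidence,
    rules_to_semantic_biclusters,
    select_features,
    tree_to_rules,
    unroll,
)


def build_pattern_instance(n_genes=20, n_sits=8, seed=0):
    """Cells are 1 exactly where the gene has tA and the situation has sB."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"g{i}" for i in range(n_genes))
    sits = tuple(f"s{j}" for j in range(n_sits))
    g_has = rng.random(n_genes) < 0.4
    s_has = rng.random(n_sits) < 0.5
    g_rel = AnnotationRelation(
        {g: ({"tA"} if g_has[i] else set()) | ({"tC"} if rng.random() < 0.3 else set())
         for i, g in enumerate(genes)}
    )
    s_rel = AnnotationRelation(
        {s: ({"sB"} if s_has[j] else set()) | ({"sD"} if rng.random() < 0.3 else set())
         for j, s in enumerate(sits)}
    )
    values = np.outer(g_has, s_has).astype(np.uint8)
    return ExpressionMatrix(genes, sits, values), g_rel, s_rel


@pytest.fixture
def pattern():
    return build_pattern_instance()


class TestUnroll:
    def test_minimal_dimensions(self):
        m = ExpressionMatrix(("g",), ("s",), np.array([[1]], dtype=np.uint8))
        data = unroll(m, AnnotationRelation({"g": {"t"}}), AnnotationRelation({"s": {"u"}}),
                      ["t"], ["u"])
        assert data.n_rows == 1
        assert data.n_features == 2  # plus the class column

    def test_dimension_formula(self):
        m = ExpressionMatrix(("g1", "g2"), ("s1", "s2"), np.zeros((2, 2), dtype=np.uint8))
        data = unroll(m, AnnotationRelation(), AnnotationRelation(), ["t1", "t2"], ["u1"])
        assert data.n_rows == 4
        assert data.n_features == 3

    def test_row_major_back_references_and_labels(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        ns = len(m.situation_ids)
        for r in (0, 5, data.n_rows - 1):
            g, s = data.back_reference(r)
            assert (g, s) == (m.gene_ids[r // ns], m.situation_ids[r % ns])
            assert data.labels[r] == m[g, s]

    def test_roundtrip_reconstructs_matrix(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA"], ["sB"])
        back = data.to_matrix()
        assert back.gene_ids == m.gene_ids
        assert back.situation_ids == m.situation_ids
        assert np.array_equal(back.values, m.values)

    def test_feature_values_reflect_annotations(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        X = data.feature_matrix()
        for r in range(0, data.n_rows, 7):
            g, s = data.back_reference(r)
            assert X[r, 0] == ("tA" in g_rel.terms_of(g))
            assert X[r, 3] == ("sD" in s_rel.terms_of(s))


class TestSelectFeatures:
    def test_absent_feature_dropped(self):
        m = ExpressionMatrix(("g1", "g2"), ("s1",), np.zeros((2, 1), dtype=np.uint8))
        data = unroll(m, AnnotationRelation({"g1": {"t1"}}), AnnotationRelation(),
                      ["t1", "t_unused"], [])
        out = select_features(data, 0.001)
        assert out.gene_vocab == ("t1",)

    def test_threshold_is_ceiling(self):
        # 1000 rows; a feature present in exactly 1 row meets ceil(0.001 * 1000) = 1
        genes = tuple(f"g{i}" for i in range(100))
        m = ExpressionMatrix(genes, tuple(f"s{j}" for j in range(10)),
                             np.zeros((100, 10), dtype=np.uint8))
        g_rel = AnnotationRelation({"g0": {"rare"}})
        data = unroll(m, g_rel, AnnotationRelation(), ["rare"], [])
        # "rare" appears in 10 rows (one gene x 10 situations) >= 1
        assert select_features(data, 0.001).gene_vocab == ("rare",)
        # demands ceil(0.011*1000) = 11 > 10 -> dropped
        assert select_features(data, 0.011).gene_vocab == ()

    def test_zero_fraction_is_identity(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        out = select_features(data, 0.0)
        assert out.feature_names == data.feature_names


class TestLearnRules:
    def test_all_negative_data_gives_empty_list(self):
        m = ExpressionMatrix(("g1", "g2"), ("s1", "s2"), np.zeros((2, 2), dtype=np.uint8))
        data = unroll(m, AnnotationRelation({"g1": {"t"}}), AnnotationRelation(), ["t"], [])
        assert len(learn_rules(data)) == 0

    def test_single_planted_pattern_learned_exactly(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        rules = learn_rules(data, LearnConfig(seed=0))
        assert len(rules) >= 1
        # the rule list reproduces every training label
        for i, g in enumerate(m.gene_ids):
            for j, s in enumerate(m.situation_ids):
                conf = rules.confidence(g_rel.terms_of(g), s_rel.terms_of(s))
                assert (conf > 0.5) == bool(m.values[i, j])

    def test_two_disjoint_patterns_jointly_exact(self):
        rng = np.random.default_rng(1)
        genes = tuple(f"g{i}" for i in range(30))
        sits = tuple(f"s{j}" for j in range(10))
        ga = rng.random(30) < 0.3
        gb = ~ga & (rng.random(30) < 0.3)
        sa = rng.random(10) < 0.4
        sb = ~sa & (rng.random(10) < 0.5)
        g_rel = AnnotationRelation(
            {g: ({"tA"} if ga[i] else set()) | ({"tB"} if gb[i] else set())
             for i, g in enumerate(genes)}
        )
        s_rel = AnnotationRelation(
            {s: ({"uA"} if sa[j] else set()) | ({"uB"} if sb[j] else set())
             for j, s in enumerate(sits)}
        )
        values = (np.outer(ga, sa) | np.outer(gb, sb)).astype(np.uint8)
        m = ExpressionMatrix(genes, sits, values)
        data = unroll(m, g_rel, s_rel, ["tA", "tB"], ["uA", "uB"])
        rules = learn_rules(data, LearnConfig(seed=0))
        system = rules_to_semantic_biclusters(rules)
        induced = induce_system(system, genes, sits, g_rel, s_rel)
        from sembic.core import training_accuracy

        assert training_accuracy(induced, m) == 1.0

    def test_noiseless_generator_training_accuracy_is_one(self, small_instance):
        inst, g_rel, s_rel = small_instance
        data = unroll(inst.matrix, g_rel, s_rel,
                      sorted(g_rel.all_terms()), sorted(s_rel.all_terms()))
        rules = learn_rules(select_features(data), LearnConfig(seed=0))
        system = rules_to_semantic_biclusters(rules)
        induced = induce_system(
            system, inst.matrix.gene_ids, inst.matrix.situation_ids, g_rel, s_rel
        )
        from sembic.core import training_accuracy

        assert training_accuracy(induced, inst.matrix) == 1.0


class TestLearnTree:
    def test_pure_data_gives_single_leaf(self):
        m = ExpressionMatrix(("g1", "g2"), ("s1",), np.ones((2, 1), dtype=np.uint8))
        data = unroll(m, AnnotationRelation({"g1": {"t"}}), AnnotationRelation(), ["t"], [])
        tree = learn_tree(data, LearnConfig(seed=0))
        assert tree.root.is_leaf and tree.root.prediction == 1

    def test_feature_free_data_gives_majority_leaf(self):
        m = ExpressionMatrix(("g1", "g2", "g3"), ("s1",),
                             np.array([[1], [0], [0]], dtype=np.uint8))
        tree = learn_tree(unroll(m, AnnotationRelation(), AnnotationRelation(), [], []))
        assert tree.root.is_leaf and tree.root.prediction == 0

    def test_planted_conjunction_reproduced_on_all_cells(self, pattern):
        m, g_rel, s_rel = pattern
        data = unroll(m, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        tree = learn_tree(data, LearnConfig(seed=3))
        for i, g in enumerate(m.gene_ids):
            for j, s in enumerate(m.situation_ids):
                pred = tree.predict(g_rel.terms_of(g), s_rel.terms_of(s))
                assert pred == m.values[i, j]

    def test_empty_dataset_rejected(self):
        m = ExpressionMatrix((), ("s1",), np.zeros((0, 1), dtype=np.uint8))
        data = unroll(m, AnnotationRelation(), AnnotationRelation(), [], [])
        with pytest.raises(ParameterError):
            learn_tree(data)


class TestTreeToRules:
    def test_depth_one_positive_branch(self):
        m = ExpressionMatrix(tuple(f"g{i}" for i in range(8)), ("s1", "s2"),
                             np.array([[1, 1]] * 4 + [[0, 0]] * 4, dtype=np.uint8))
        g_rel = AnnotationRelation({f"g{i}": {"tA"} for i in range(4)})
        data = unroll(m, g_rel, AnnotationRelation(), ["tA"], [])
        rules = tree_to_rules(learn_tree(data, LearnConfig(seed=0)))
        assert rules == [Rule(frozenset({("tA", True)}), frozenset(), 8, 0)] or all(
            ("tA", True) in r.gene_literals for r in rules
        )

    def test_negated_literals_from_left_branches(self, pattern):
        m, g_rel, s_rel = pattern
        # invert the pattern so the concept needs absence of tA
        inv = ExpressionMatrix(m.gene_ids, m.situation_ids, (1 - m.values).astype(np.uint8))
        data = unroll(inv, g_rel, s_rel, ["tA", "tC"], ["sB", "sD"])
        rules = tree_to_rules(learn_tree(data, LearnConfig(seed=0)))
        assert any(r.has_negation() for r in rules)

    def test_all_negative_tree_has_no_rules(self):
        m = ExpressionMatrix(("g1", "g2"), ("s1",), np.zeros((2, 1), dtype=np.uint8))
        data = unroll(m, AnnotationRelation({"g1": {"t"}}), AnnotationRelation(), ["t"], [])
        assert tree_to_rules(learn_tree(data)) == []


class TestRuleConversion:
    def test_rule_maps_to_crisp_rectangle(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        rule = Rule(frozenset({("tA", True)}), frozenset({("uX", True)}), 4, 0)
        system = rules_to_semantic_biclusters([rule])
        induced = induce_system(system, ["g1", "g2", "g3"], ["s1", "s2", "s3"], g_rel, s_rel)
        assert induced.biclusters[0].genes == {"g1", "g2"}
        assert induced.biclusters[0].situations == {"s1", "s2"}

    def test_gene_only_rule_induces_all_situations(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        system = rules_to_semantic_biclusters([Rule(frozenset({("tA", True)}), frozenset())])
        induced = induce_system(system, ["g1", "g3"], ["s1", "s2", "s3"], g_rel, s_rel)
        assert induced.biclusters[0].situations == {"s1", "s2", "s3"}

    def test_negated_rule_rectangle(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        rule = Rule(frozenset({("tA", False)}), frozenset({("uX", True)}))
        system = rules_to_semantic_biclusters([rule])
        assert system.literal_mode
        induced = induce_system(system, ["g1", "g2", "g3"], ["s1", "s2", "s3"], g_rel, s_rel)
        assert induced.biclusters[0].genes == {"g3"}
        assert induced.biclusters[0].situations == {"s1", "s2"}

    def test_unknown_vocabulary_term_rejected(self):
        with pytest.raises(MappingError):
            Rule.from_terms([("zz", True)], ["tA"], ["uX"])
        with pytest.raises(MappingError):
            Rule.from_terms([("both", True)], ["both"], ["both"])


def test_rectangle_property_on_random_rules():
    """Every rule's covered cell set is the product of its induced sides."""
    rng = np.random.default_rng(12)
    gene_vocab = [f"t{i}" for i in range(8)]
    sit_vocab = [f"u{i}" for i in range(8)]
    genes = [f"g{i}" for i in range(12)]
    sits = [f"s{j}" for j in range(9)]
    for _ in range(1000):
        g_rel = AnnotationRelation(
            {g: set(rng.choice(gene_vocab, rng.integers(0, 5), replace=False)) for g in genes}
        )
        s_rel = AnnotationRelation(
            {s: set(rng.choice(sit_vocab, rng.integers(0, 5), replace=False)) for s in sits}
        )
        lits = [(t, bool(rng.integers(2))) for t in rng.choice(gene_vocab, rng.integers(0, 3), replace=False)]
        lits += [(u, bool(rng.integers(2))) for u in rng.choice(sit_vocab, rng.integers(0, 3), replace=False)]
        rule = Rule.from_terms(lits, gene_vocab, sit_vocab)
        covered = {
            (g, s)
            for g in genes
            for s in sits
            if rule.matches(g_rel.terms_of(g), s_rel.terms_of(s))
        }
        g_side = {g for g in genes if all((t in g_rel.terms_of(g)) == pos for t, pos in rule.gene_literals)}
        s_side = {s for s in sits if all((t in s_rel.terms_of(s)) == pos for t, pos in rule.situation_literals)}
        assert covered == {(g, s) for g in g_side for s in s_side}


class TestPredictConfidence:
    def test_no_matching_rule_defaults_to_zero(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        model = RuleList([Rule(frozenset({("tB", True)}), frozenset({("uY", True)}), 3, 0)])
        assert predict_confidence(model, "g1", "s1", g_rel, s_rel) == 0.0

    def test_laplace_confidence_of_matching_rule(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        model = RuleList([Rule(frozenset({("tA", True)}), frozenset(), 9, 0)])
        assert predict_confidence(model, "g1", "s1", g_rel, s_rel) == pytest.approx(10 / 11)

    def test_first_match_wins(self, tiny_annotations):
        g_rel, s_rel = tiny_annotations
        model = RuleList(
            [
                Rule(frozenset({("tA", True)}), frozenset(), 1, 1),
                Rule(frozenset({("tB", True)}), frozenset(), 9, 0),
            ]
        )
        # g2 matches both; the first rule's confidence applies
        assert predict_confidence(model, "g2", "s1", g_rel, s_rel) == pytest.approx(2 / 4)

    def test_pure_leaf_laplace(self):
        m = ExpressionMatrix(tuple(f"g{i}" for i in range(5)), ("s1",),
                             np.array([[1]] * 4 + [[0]], dtype=np.uint8))
        g_rel = AnnotationRelation({f"g{i}": {"t"} for i in range(4)})
        data = unroll(m, g_rel, AnnotationRelation(), ["t"], [])
        tree = learn_tree(data, LearnConfig(seed=0, tree_holdout=0.0))
        # pure positive leaf with p=4, n=0 -> Laplace 5/6
        assert predict_confidence(tree, "g0", "s1", g_rel, AnnotationRelation()) == pytest.approx(5 / 6)
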