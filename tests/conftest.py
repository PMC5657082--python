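import numpy as np
import pytest

from sembic.core import AnnotationRelation, ExpressionMatrix
from sembic.enrichment import annotation_closure
from sembic.synthetic import GeneratorConfig, plant


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3x3 matrix with a 2x2 block of 1s and one isolated 1."""
    return ExpressionMatrix(
        ("g1", "g2", "g3"),
        ("s1", "s2", "s3"),
        np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.uint8),
    )


@pytest.fixture
def tiny_annotations() -> tuple[AnnotationRelation, AnnotationRelation]:
    genes = AnnotationRelation(
        {"g1": {"tA"}, "g2": {"tA", "tB"}, "g3": {"tB"}}
    )
    situations = AnnotationRelation({"s1": {"uX"}, "s2": {"uX", "uY"}, "s3": {"uY"}})
    return genes, situations


def _closed(inst):
    g_rel = annotation_closure(inst.gene_annotations, inst.gene_ontology)
    s_rel = annotation_closure(inst.situation_annotations, inst.situation_ontology)
    return inst, g_rel, s_rel


@pytest.fixture(scope="session")
def clean_instance():
    """Default-scale planted instance with every corruption channel off."""
    return _closed(
        plant(GeneratorConfig(fp_noise=0.0, fn_noise=0.0, background_density=0.0, seed=0))
    )


@pytest.fixture(scope="session")
def small_instance():
    """Small planted instance for fast end-to-end tests."""
    cfg = GeneratorConfig(
        n_genes=150,
        n_situations=24,
        gene_terms=120,
        situation_terms=60,
        n_planted=2,
        background_density=0.0,
        seed=0,
    )
    return _closed(plant(cfg))
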