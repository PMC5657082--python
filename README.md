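# sembic — semantic biclustering of binary expression matrices

`sembic` finds *semantic biclusters* in binary gene-expression matrices:
rectangular patterns (a subset of genes times a subset of situations) whose
members can be jointly described by ontology terms on **both** dimensions —
e.g. "glucose-metabolism genes in late developmental stages". Intended
users are computational biologists working with binarized expression
compendia (in-situ hybridization tables, presence/absence calls) that come
with gene annotations (GO/KEGG-like) and sample annotations (anatomy or
developmental-stage ontologies).

## Model

Let `A = (a_gs)` be a binary matrix over genes `G` and situations `S`, with
annotation relations `R_γ ⊆ G×γ` and `R_σ ⊆ S×σ` into two ontology
vocabularies. An ordinary bicluster is a pair `(G', S')`; a system `B` of
biclusters predicts 1 on its extension `ext(B) = ∪_k G_k × S_k` and its
quality is the training accuracy `|{(g,s): a_gs = b(g,s)}| / (|G||S|)`,
optionally regularized by `+ λ/|B|`.

A **semantic bicluster** `(T^γ, T^σ)` is defined intensionally by term
conjunctions: it induces the gene set `{g : ∀t ∈ T^γ, (g,t) ∈ R_γ}` and the
analogous situation set, so it classifies *any* annotated pair — including
genes and situations never seen during training. Its *soft* variant
carries per-term weights `w ∈ (0;1]` and supports a pair `(g,s)` when the
matched gene-term weights sum to at least `θ_G` and the matched
situation-term weights to at least `θ_S`.

Two strategies produce semantic systems:

1. **Bi-directional enrichment** — a noise-tolerant greedy search extracts
   biclusters minimizing `description + ρ·(false positives + false
   negatives)`; each bicluster is then annotated with the ontology terms
   over-represented among its genes and its situations (one-sided
   hypergeometric test, weight `1 − p`), with significance thresholds
   calibrated by a permutation test bounding the false discovery rate.
2. **Rule / tree learning** — the matrix is unrolled into one instance per
   cell (term-indicator features, expression class), rare features are
   dropped, and a separate-and-conquer rule learner (RIPPER family) or a
   binary decision tree (C4.5 family) is trained; every rule and every
   root-to-positive-leaf path is itself a crisp semantic bicluster (tree
   paths may carry negated terms).

Evaluation splits the matrix rectangularly — `round(|G|·√f)` genes ×
`round(|S|·√f)` situations train, the complement tests — and partitions
test cells into kG (known genes × unseen situations), kL (unseen genes ×
known situations) and bd (unseen × unseen). Soft systems are scored by the
upper-convex-hull AUROC over a `θ` grid (default `{1,5,10,50}²`, 16
operating points); rule/tree models by a standard confidence-sweep ROC.

## Worked example

```python
from sembic.synthetic import GeneratorConfig, plant
from sembic.enrichment import annotation_closure
from sembic.pipeline import RunConfig, run_all

# 1200 genes x 72 situations, 4 planted semantic biclusters,
# 5% dropout and 1% spurious expression
inst = plant(GeneratorConfig(fn_noise=0.05, fp_noise=0.01, seed=0))
g_rel = annotation_closure(inst.gene_annotations, inst.gene_ontology)
s_rel = annotation_closure(inst.situation_annotations, inst.situation_ontology)

bc_report, eval_report = run_all(
    inst.matrix, g_rel, s_rel, RunConfig(strategy="enrich", seed=0)
)
print(eval_report["n_biclusters"], eval_report["rho"], eval_report["auroc"])
```

prints (amongst the full JSON-ready reports):

```
biclusters found:   4
selected rho:       1.0
train shape:        [1004, 60]
training accuracy:  0.950
hull AUROC:         0.950
region AUROC:       kG=0.960, kL=0.943, bd=0.937
```

The four planted biclusters are recovered; the held-out hull AUROC of
0.95 sits at the optimum allowed by the injected label noise, and the
region scores show the system generalizing to unseen situations (kG),
unseen genes (kL) and both at once (bd). Each recovered bicluster carries
its enriched terms with weights `1 − p` (here 12 gene terms on the first,
top weight 1.000).

The same pipeline runs from the shell:

```bash
sembic simulate --out-dir data --seed 0
sembic run-all --matrix data/matrix.tsv \
    --gene-annotations data/gene_annotations.tsv \
    --situation-annotations data/situation_annotations.tsv \
    --gene-ontology data/gene_ontology.obo \
    --situation-ontology data/situation_ontology.obo \
    --strategy enrich --out-dir out --seed 0
```

writing `out/biclusters.json` and `out/evaluation.json`.

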