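# Methods

This note documents the models and procedures implemented in `sembic`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish.

## Formal model

The package treats a binary expression matrix as a sample of cells
`(g, s, a_gs)` rather than a sample of columns: rectangularity makes cells
mutually dependent, which is why evaluation uses a rectangular train
submatrix and scores the (non-rectangular) complement cell by cell. A
bicluster system is viewed throughout as a binary classifier — 1 inside
its extension, 0 outside — so training accuracy, held-out accuracy and
ROC analysis all apply uniformly to ordinary, semantic and soft semantic
systems.

Semantic biclusters are conjunctions of ontology terms per dimension. Two
conventions matter in edge cases:

- an **empty conjunction is vacuously true** and induces every entity on
  its side, so biclusters described by one dimension only remain usable;
- **negated terms** (produced by decision-tree paths) are signed literals:
  a negated literal is satisfied when the term is absent from the entity's
  closed annotation, and its weight counts toward the soft matched sum
  exactly when that absence holds. Crisp biclusters are weight-1 term
  sets, so a single soft classifier serves both strategies.

## Greedy bicluster search

The searcher minimizes an explicit cost
`Σ_k (|G_k| + |S_k|) + ρ·(covered 0s + uncovered 1s)`. Each round grows
one candidate in two phases:

1. **Exact core.** Seed at the column with the most uncovered 1s
   (ties → lowest index); rows are the seed column's uncovered 1s; columns
   are then added one at a time, each time keeping only rows with a 1 in
   every selected column and accepting the column that most improves
   `ρ·new_true_positives − (|R|+|C|)`. The core therefore contains no
   0-cells.
2. **Noise-tolerant extension.** Whole rows/columns are appended while
   each strictly decreases the total cost (`ρ·(gain − loss) > 1`).

A candidate is accepted only if it strictly lowers the system cost, which
makes the cost sequence strictly decreasing and guarantees termination.
Everything is deterministic; index order breaks all ties. The extension
step uses a *strict* inequality deliberately: cost-neutral moves absorb
noise rows and merge adjacent patterns, destroying exact recovery of
clean planted blocks while buying nothing in cost.

`ρ` is the accepted-noise level. `select_rho` runs the search per
candidate and compares the resulting systems on a common reference scale
(total cost at ρ = 1), returning the smallest candidate on ties.

## Bi-directional enrichment

Annotations are first closed under ancestor propagation; `is_a`,
`part_of` and `develops_from` edges are all treated as transitive. Each
non-trivial bicluster (>1 gene and >1 situation) is tested on both
dimensions with the one-sided hypergeometric tail against the matrix's
own entity lists as background (not the global ontology universe —
enrichment should mean "unusual within this assay"). Terms at `p ≤ α`
are kept with weight `w = max(10⁻⁶, 1 − p)`. The `1 − p` map keeps
weights in `(0;1]` as the soft classifier requires and makes the default
`θ` grid `{1, 5, 10, 50}` meaningful as approximate matched-term counts.

The significance threshold can be fixed per dimension (`0.05` genes /
`0.1` situations by default, reflecting the asymmetry between rich gene
vocabularies and small situation ontologies) or, as the pipeline does by
default, calibrated by permutation: entity labels on the tested dimension
are shuffled `n_perms = 100` times, all per-bicluster term p-values are
recomputed on identical index sets, and the returned α is the largest
observed real p-value whose estimated FDR — mean permuted count of
`p ≤ α` over the real count — stays below the target (default 0.05).
Chance enrichments produced by testing hundreds of candidate terms per
bicluster are suppressed this way without any explicit multiple-testing
correction. Biclusters with no significant term on either side are
dropped; a single enriched side is kept (the other side is vacuous).

## Rule and tree learning

The unrolled dataset stores per-entity indicator blocks and materializes
the `|G|·|S| × (|γ|+|σ|)` design matrix lazily; row-major order defines
the cell back-references. Feature selection drops every term positive in
fewer than `ceil(min_fraction · rows)` instances (default 1‰) — rare
terms cannot generalize and only slow the learners.

The rule learner is a simplified RIPPER: stratified 2:1 grow/prune split;
rules grow by the positive-presence literal with maximal FOIL gain until
no grow negatives are covered; pruning deletes trailing literals to
maximize `(p−n)/(p+n)` on the prune split (ties keep the more specific
prefix); rule addition stops when grow positives are exhausted or the
latest rule errs on more than half of its prune coverage; covered
positives are removed between rules. No MDL global-optimization passes
are performed. Confidences are Laplace `(p+1)/(p+n+2)` on the full
training data, with first-match semantics and default 0 (no expression).

The tree learner grows a binary tree and prunes it by reduced error
against an internal stratified 20% holdout. The default split criterion
is **plain information gain**, not gain ratio. On term-indicator features
after ancestor closure, the candidate set contains many rare, mutually
correlated attributes; gain ratio's denominator rewards exactly those
(near-zero split info), roots the tree on near-zero-gain splits and
fragments it into hundreds of leaves whose long negated-literal paths
misroute unseen entities. Plain gain produces compact trees that read as
one subtree per planted pattern. Gain ratio (with the average-gain
guard) remains available via `LearnConfig(split_criterion="gain_ratio")`.

Both learners output crisp semantic biclusters: each rule, and each path
to a positive leaf, maps to weight-1 signed term sets. The rectangle
property — the covered cell set of any conjunctive rule factors into
(induced genes) × (induced situations) — is a structural consequence of
the propositional language and is enforced by tests on randomized
fixtures.

## Evaluation protocol

Holding out a fraction `1 − f` of matrix *elements* while keeping the
training split rectangular is realized as equal per-dimension retention:
`round(|G|·√f)` genes and `round(|S|·√f)` situations. At `f = 0.7` this
maps 6,510×100 to 5,447×84 and 1,207×72 to 1,010×60, i.e. 457,548 and
60,600 unrolled training instances respectively. Test cells partition
into kG/kL/bd by whether the gene and/or situation was retained;
degenerate (single-class) regions are reported as absent rather than
raising.

Soft systems are evaluated at every `(θ_G, θ_S)` grid pair (default 4×4
= 16 binary classifiers); the reported AUROC is the trapezoid area under
the upper convex hull of the operating points anchored at (0,0) and
(1,1). Confidence-ranked models use a standard threshold-sweep ROC
(scikit-learn's curve, trapezoid area, ties grouped at one threshold).
A single seeded split per run; repeated splits are a loop at the caller's
level, since cross-validation has no direct analogue in the
two-dimensional setting.

## Synthetic benchmark

The generator emulates a GO/anatomy-annotated binarized expression
table at imaginal-disc scale: 1,200 genes × 72 situations, a 400-term
gene ontology and a 150-term situation ontology (random rooted DAGs,
depth 3, 1–2 parents per term), and 4 planted biclusters, each defined
by 4 leaf terms per side. Defining terms are the *deepest* leaves —
curated annotations attach to specific terms — so each conjunction drags
a chain of correlated ancestors through the closure, deliberately
reproducing GO redundancy. Member blocks are disjoint between biclusters
(a shuffled partition per dimension), the standard planted-benchmark
convention that makes exact recovery well-defined. Genes additionally
carry 1–3 random decoy leaves, situations exactly one (a sample has one
primary location annotation). Corruption channels: per-term annotation
spillover (`background_density`, default 2%), and expression flips
(`fp_noise`, `fn_noise`, default 0). Clean labels are the extension
*induced by the annotations*, so spillover entities that acquire a full
conjunction are genuine members. Everything derives from one seed.

The noisy study condition used in tests is dropout-dominated
(`fn = 5%`, `fp = 1%`). This is both the realistic profile for binarized
expression and a mathematical necessity: with symmetric 5% flips on an
~8%-dense matrix, 38% of positive labels are pure noise and the
Bayes-optimal AUROC is ≈ 0.81, so no method could demonstrate
generalization above 0.9 there.

What passing tests show: the pipeline recovers planted rectangular
structure exactly in the absence of corruption, attaches the correct
terms, generalizes across unseen genes and situations, and degrades
gracefully under dropout noise. What they do not show: performance on
real data, where annotation coverage is incomplete and biased, expression
patterns are not exact unions of rectangles, and ontology topology is far
more skewed than a random DAG.

## Numerical choices and degenerate inputs

- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, N, K, n)`,
  clipped to `[0,1]`; exactness is tested against explicit combinatorial
  sums for every configuration up to N = 12.
- Weight floor `ε = 10⁻⁶`: `w = max(ε, 1 − p)` keeps weights inside
  `(0;1]` even for terms retained at `p` close to 1 under a permissive
  threshold, where `1 − p` alone would leave the open interval.
- Convex hull by monotone chain over deduplicated points; AUROC by
  trapezoid (`numpy.trapezoid`).
- Ties everywhere break by index or lexicographic order; all stochastic
  steps (splits, grow/prune partitions, permutations, the generator) use
  `numpy.random.default_rng` seeded from configuration.
- Empty matrices, empty systems with a nonzero regularizer, empty
  candidate lists, single-class ROC inputs and trivial biclusters raise
  typed errors (`DimensionError`, `ParameterError`, ...) or are skipped
  where the protocol says so (trivial biclusters, degenerate regions).

## Known limitations

- The greedy searcher is a heuristic; on adversarial matrices its cost
  can exceed the optimum (bounded in tests at 1.5× on exhaustively
  enumerable instances). Overlapping planted patterns on both dimensions
  can merge into locally optimal rectangles.
- The enrichment step tests terms independently; correlated ancestors are
  all reported (the permutation threshold controls false discoveries, not
  redundancy). No information-content weighting.
- The rule learner omits RIPPER's global MDL optimization; the tree uses
  reduced-error rather than pessimistic pruning. Behavioral equivalence
  with WEKA's JRip/J48 is not claimed.
- Weights map from p-values as `1 − p`; alternatives (e.g. `−log p`
  scaled) would change the meaning of the θ grid and are not explored.
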