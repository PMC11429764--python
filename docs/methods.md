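# Methods

## Logical models and rule language

A model is an ordered list of nodes, each a gene (or protein, identified by
its gene symbol) with a Boolean update rule over named regulators. Rules use
the connectives `!` (NOT), `&` (AND), `|` (OR) with precedence `!` > `&` >
`|`, parentheses, and the constants `0`/`1`. The grammar matches common
BoolNet/GINsim conventions; symbols are case-sensitive tokens over
`[A-Za-z0-9_.-]+` so legacy names like `Pu.1` or `Gata-1` parse unchanged.
Constants are permitted as whole rules so a clamped (mutated) node is itself
a well-formed model — perturbation is rule replacement, not a special
simulation mode.

Regulators referenced by some rule but lacking a rule of their own are
materialized as *input nodes* with identity rules (`X = X`), flagged
`is_input`. This keeps the state space well defined (every trajectory is
over a fixed node set) while recording that the source model made no claim
about the node's regulation. Input nodes never participate in rule merging.

## Identifier standardization

Node alignment across models uses standardized HGNC symbols as join keys.
Standardization is driven by an offline TSV table (`raw_name`,
`hgnc_symbol`, `hgnc_id`); substitution over node names and rule variables
is simultaneous (computed from the original names in one pass), so mapping
chains cannot cascade and the operation is idempotent. Two distinct nodes of
one model mapping to the same symbol is surfaced as an error rather than
silently merged — that situation genuinely requires curation. Mouse-style
capitalization (`Gata1` vs `GATA1`) and fusion-protein names are handled by
whatever rows the table author provides; no ortholog inference is attempted.

## Merge semantics

For a symbol with rules in two or more models ("overlapping"), the merged
rule is:

- **OR**: the disjunction of the source rules — pointwise maximum.
- **AND**: the conjunction — pointwise minimum.
- **IW (Inhibitor Wins)**: `AND(NOT i for i in I) AND OR(source rules)`,
  where `I` is the union over source models of regulators with inhibitory
  influence on that symbol's rule. This conjunction-guard construction is
  pointwise equal to the piecewise reading "0 if any member of `I` is
  active, else the OR combination", which the test suite asserts by
  exhaustive truth table. The inhibitor literals are *not* stripped from the
  OR body; under the guard the two constructions coincide, and keeping
  bodies intact preserves provenance of the source logic.

Influence signs are computed from the function, not from annotations: a
regulator is an inhibitor if flipping it 0→1 lowers the output in some
context over the other regulators and never raises it (exhaustive over all
`2^(k-1)` contexts, capped at k = 16 regulators). Non-monotone (DUAL)
regulators — which do occur in random and in curated rules — count as
inhibitory for IW by default, the conservative choice for a semantics whose
point is inhibitory dominance; `dual_as_inhibitor=False` excludes them, and
`sign_overrides` lets curated edge signs take precedence. A symbol that is
only an external input in one model contributes no rule (absence of a rule
is not a claim of constancy); exclusive symbols are copied verbatim.

OR and AND merging are associative and commutative up to rule equivalence,
so merging n models is order-independent; IW is defined directly over the
full model list. Per-node method overrides allow mixed strategies.

## Dynamics

States are bit tuples in model node order, encoded as integers with node i
at bit i. Two update schemes:

- **Synchronous**: all nodes update at once; the state graph is a
  deterministic functional graph whose cycles are the attractors. Exhaustive
  analysis iterates the successor table (built as vectorized truth tables)
  from every state with path coloring, giving exact basin fractions that
  partition the state space.
- **Asynchronous** (general, one node per step): attractors are the
  terminal strongly connected components of the nondeterministic transition
  graph, computed with networkx. The reported "basin" is the fraction of
  states from which the attractor is reachable; under nondeterminism these
  overlap and need not sum to 1.

Fixed points (`f(x) = x`, scheme-independent) are found by branch-and-prune:
pick an undetermined node, try both values, propagate — any rule that
simplifies to a constant under the partial assignment forces its node's
value, contradictions prune the branch. This is exact (validated against
enumeration) and handles up to 40 nodes by default versus 22 for exhaustive
attractor analysis; beyond the attractor cap a seeded sampling mode
(synchronous only, opt-in) estimates attractors and basins from random
trajectories and marks every result approximate. The caps are explicit
errors, not silent fallbacks.

Mutations are clamps: gain-of-function replaces the rule with `1`,
loss-of-function with `0`; the original rule is archived in the node's
annotations. Clamped nodes provably hold their value in every attractor
state.

Attractors are labelled model-initial + 1-based rank (e.g. `M1`), ordered
by descending basin then smallest state encoding, so outputs are stable
across runs.

## Evaluation statistics

- **Pattern matrix**: one row per attractor over the union gene set. Fixed
  points contribute their state; cyclic attractors contribute the per-gene
  majority across their states, with exact 50/50 ties recorded as 0 and
  flagged separately (the collapse rule for cycles is a choice — the flag
  keeps it auditable). Genes absent from an attractor's source model are
  missing values.
- **Hamming clustering**: pairwise distance = differing cells / comparable
  cells, where a cell is comparable only if non-missing in both rows; a
  pair with no comparable cells is an error. Average-linkage agglomerative
  clustering (scipy); cut by cluster count or distance threshold.
- **Activation frequency**: fraction of attractor states in which a gene is
  ON. `UNIFORM_STATES` (default) pools all states of all attractors
  equally; `BASIN` weights each attractor's per-gene mean by its basin
  fraction (renormalized). The two agree when basins are equal and
  attractors have equal state counts. Both are exposed because neither is
  canonical; outputs record which was used.
- **Expression correlation**: Pearson (default) or Spearman between modeled
  activation frequency and an observed per-gene frequency table, over the
  gene intersection (≥ 3 genes required, excluded genes reported). Constant
  vectors raise a degenerate-variance error rather than returning NaN.
- **Network score**: clamp a mutation profile, recompute attractors, and
  take the weighted sum of phenotype-node activation frequencies (signed
  weights from a YAML config). This generalizes published hallmark-score
  constructions; the weights are user-supplied, not fitted.
- **Cohort correlation**: patients grouped by identical mutation profile;
  per-group score vs mean clinical value, Pearson across groups, with an
  optional patient-count-weighted variant (whether published analyses
  weight by group size in the statistic or only in plotting is ambiguous,
  so both modes exist and outputs say which ran).

## Synthetic data generator

The generator stands in for model search and for microarray/cohort data at
test time. Defaults: 10 nodes per model, in-degree 1–3, negation
probability 0.3, pair overlap 3, noise σ = 0.05, 30 patients — small enough
for exhaustive dynamics, large enough that the three merge semantics and
the recovery statistics behave nontrivially. Rule trees are depth ≤ 3 so
influence classification stays exhaustive and cheap. Shared symbols in a
generated pair get *independent* rules in each model, the hard case for
merging. Expression tables are true activation frequencies plus truncated
Gaussian noise; cohorts carry 1–3 random clamps per patient with clinical
values affine in the ground-truth network score (offset 20, scale 60 —
blast-percentage-like units) plus noise. The first three patients always
receive canonical distinct profiles (phenotype node clamped 1, clamped 0,
one random clamp) so every cohort satisfies the ≥ 3-distinct-profiles
precondition with non-degenerate scores by construction, not by luck.

What the generator does *not* emulate: scale-free GRN topology, correlated
measurement noise, linked mutations, or multi-valued regulation. Passing
recovery tests therefore show the statistics are implemented correctly and
the pipeline is self-consistent — not that real expression data will
correlate at the same strength.

## Numerical and sizing choices

Truth tables are computed as vectorized boolean arrays (variable j = bit j
of the row index), capping equivalence checks at 20 variables and sign
classification at 16. Test ensembles use models of 2–12 nodes where
checks are exhaustive: merge semantics are verified on 200 random pairs,
the fixed-point solver on 100 models against enumeration, attractor
analysis on 50 models against an independent Tarjan SCC oracle, and file
round trips on 100 models — sizes at which every assertion is a complete
truth-table or state-space comparison rather than a sample.

## Known limitations

- No BDD/SAT backends: all analysis is explicit-state, so the exhaustive
  caps are hard limits rather than performance knobs.
- Only Boolean (maxLevel 1) SBML-qual models; multi-valued logic is
  rejected, not coerced.
- The asynchronous scheme is the general one-node-per-step semantics;
  models published under other schemes (priority classes, random order)
  must be analyzed under their own scheme to reproduce their published
  attractors.
- Probabilistic rule merging and weighting are out of scope; the three
  semantics are deterministic by design.
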