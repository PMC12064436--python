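# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic cohorts do and do not emulate, and
the known limitations.

## Synthetic cohorts

The generator draws a tiered DAG: tier 0 is exogenous and holds the age
(continuous) and sex (binary) analogues; the 3-level outcome ("none",
"diagnosed late", "diagnosed early" — the categorical coding is all the
pipeline consumes, so no explicit time-to-event model is used) sits alone in
the last tier; the remaining variables occupy the middle tiers. Edges are
sampled forwards along a fixed tier-consistent order with probability
calibrated to a requested expected degree (default 2.0); no edges enter
tier 0. Latent confounders are parentless with exactly two observed,
non-exogenous children, which keeps the latent projection well defined and
gives the discovery stage genuine bidirected structure to find. When a
configuration asks for a minimum number of outcome parents (the pipeline
default is 2 — a cohort outcome with no measured risk factors is not an
interesting study), parents are added uniformly at random after edge sampling.

Mechanisms: continuous nodes are linear in their parents' signals plus
Gaussian noise (SD 1); categorical nodes are multinomial-logistic with
centred per-level coefficient patterns of norm `|w|·√L`. Edge weights are
uniform on ±[0.4, 0.9]: detectable at a few thousand samples without being
near-deterministic. Categorical parents contribute through centred linear
level scores. The outcome's intercepts (1.0, 0.0, −0.5) give a moderately
imbalanced class split (roughly 55/25/20) — imbalanced enough to be
cohort-like while keeping power for the categorical tests; a 1.5%-prevalence
outcome would need two orders of magnitude more samples than these desk-scale
studies use.

Missingness is MCAR (independent Bernoulli per cell) or MAR with the
missingness probability scaled by quartile of a fully observed driver
(multipliers 0.4/0.8/1.2/1.6 around the requested mean rate). Variable
labels are assembled from the gold category's lexicon words plus neutral
filler tokens; roughly one middle variable in five is a decoy carrying no
category.

What the generator does *not* emulate: realistic marginal distributions of
any particular cohort, field-ID structure, longitudinal follow-up, informative
(MNAR) missingness, or selection into the cohort. Passing tests therefore
demonstrate correctness and calibration of the machinery under the stated
model class, not performance on any specific real dataset.

All randomness flows from one integer seed through `numpy.random.SeedSequence`
streams with fixed per-operation keys, so every stage is independently
reproducible and imputation chains are bit-reproducible per (seed, chain)
regardless of execution order.

## Embedding selection

Labels are lowercased, punctuation-stripped and stopword-filtered (the
stopword list is shipped and versioned in the package; it is a small curated
function-word list — content-bearing adverbs like "ever" are kept). Word-level
backends embed a phrase as the arithmetic mean of in-vocabulary token vectors;
out-of-vocabulary tokens are skipped, and a phrase with no in-vocabulary
tokens is reported "unscorable", never silently dropped. The per-variable
score under a backend is the maximum cosine similarity over target phrases;
the best phrase maximizes the mean score across backends. Selection rules:
threshold per backend combined by any/all/mean (default: any backend ≥ 0.6),
or top-k per phrase. Selection is monotone in the threshold by construction.

The shipped fixture backends are deterministic hash-seeded tables: tokens of
a lexicon category sit at `anchor + 0.35·noise` (renormalised) around a
category anchor, so same-category tokens cluster; all other vocabulary is
pure hash noise. On labels generated from the same lexicon the gold/decoy
score distributions separate cleanly (≈0.72+ vs ≈0.45−), and 0.6 is the
calibrated default threshold. Real word2vec vectors in the standard text
format can be loaded with `load_word2vec_text`; no pre-trained model is
downloaded or required.

Coverage accuracy is |covered ∩ evaluable| / |evaluable|, where a category is
covered iff at least one selected variable carries it and evaluable excludes
categories removed from QC.

## Imputation

Missing-rate QC removes variables whose missing fraction strictly exceeds the
threshold (default 0.75). Continuous variables are standardized to observed
mean 0 / SD 1 *before* imputation (the order is recorded in the manifest and
can be flipped by configuration). MICE visits variables in
decreasing-missingness order, initializes missing cells by marginal draws,
and runs 5 iterations by default (common chained-equations practice). The
default conditional model is a random forest — 10 trees, bootstrap
resampling, mtry = √p, a 5-observation terminal-leaf floor, and a per-tree
subsample cap of 800 rows. The leaf floor guarantees a donor pool in every
terminal node: an imputation is the observed value of a random donor sharing
the terminal node of a randomly chosen tree, i.e. predictive-mean-matching-
like draws that preserve marginal shapes and heteroscedasticity. The
subsample cap bounds tree depth and fit cost on cohort-sized inputs without
touching the donor mechanism (donor pools are formed by routing *all*
training rows through the fitted trees). A parametric alternative (linear
regression with residual-SD noise draws; multinomial-logistic sampling) is
available and much faster at large m·p. The outcome is used as a predictor
but never imputed; outcome-incomplete rows are expected to be excluded
upstream by design.

## Mixed graphical model

The pairwise model uses unit-variance Gaussian conditionals for (standardized)
continuous nodes and multinomial-logistic conditionals for categorical nodes,
with shared symmetric interactions: a scalar per continuous pair, a vector
over levels per continuous–categorical pair, a level×level block per
categorical pair. The fit minimizes the joint negative log-pseudolikelihood
(1/n scaled) plus a group-lasso penalty per edge block, by monotone proximal
gradient descent with backtracking (sufficient-decrease line search on the
smooth part; step grows 1.25× after accepted steps). Convergence is declared
at relative objective change below 1e−5; the objective trace is exposed and
non-increasing. Categorical variables are one-hot coded without a reference
level; the group penalty resolves the softmax shift invariance (the
minimum-norm representative of each block is centred), serving as the
identification constraint.

A scalar penalty λ expands to the triple (λ, ⅔λ, 4⁄9λ) for
continuous–continuous, continuous–categorical and categorical–categorical
blocks: indicator columns have roughly half the standard deviation of a
standardized continuous column, so a shared scalar systematically
over-penalizes blocks with categorical sides (factor ⅔ per categorical side);
an explicit triple overrides this. The default λ = 0.15 was calibrated on
linear-Gaussian chains at n = 2000. Regularization can also be selected by
pseudolikelihood BIC (degrees of freedom = intercepts + sizes of nonzero
blocks) or by stability selection (StARS-style: smallest λ whose sparse-side
monotonized edge instability 2·p̂·(1−p̂) stays ≤ 0.05 over subsample refits).

The skeleton (block norm > 1e−8) is *advisory* for FCI: it restricts the
initial adjacency set, and FCI's own tests may delete but never add edges.

## Conditional-independence testing

The test of a ⫫ b | S is a nested-model comparison chosen by the target's
type, symmetrized by testing both directions and keeping the larger p-value
(conservative). Continuous targets use the exact F-test between nested linear
models, computed from the precomputed Gram matrix of the full design so the
per-query cost is independent of n. Categorical targets use Rao's score
(Lagrange-multiplier) test against the null multinomial fit — asymptotically
equivalent to the likelihood-ratio test but requiring only the null model,
which is shared and cached across the many queries that condition on the same
set; the likelihood-ratio variant remains available (`cat_test="lr"`).
Multinomial fits use damped Newton iterations with a 1e−6 ridge that keeps
quasi-separable fits finite. Queries whose residual degrees of freedom are
exhausted are flagged untestable and treated as "dependent" (edge kept) —
conservative for discovery. Batches are corrected by Benjamini–Hochberg;
independence is declared when the adjusted p exceeds α (default 0.05).

## FCI-MAX

Adjacency search starts from the MGM skeleton (or the complete graph) and
sweeps conditioning-set sizes 0..`max_cond_size` (default 3 at p ≈ 30–100;
None = unlimited for oracle runs); at each size the full batch of tests is
FDR-corrected before any edge is removed, and every separating set is
recorded with its p-value. A Possible-D-SEP sweep (after preliminary MAX
colliders) then re-tests surviving edges against subsets of the
Possible-D-SEP sets, which is required for adjacency correctness under latent
confounding; on large problems the pool per node can be capped to the
`pdsep_pool_cap` graph-nearest members (the pipeline default is 6) as a
tractability bound in the spirit of path-length caps in other FCI
implementations — oracle verification runs uncapped.

Orientation starts from all circles. Background knowledge is applied first:
for a forbidden cause x of y (explicit pair, "forbid-all-from" sink such as
the outcome, or a tier violation), the arrowhead is placed *at x* on the x–y
edge — in MAG semantics an arrowhead at an endpoint asserts that endpoint is
not an ancestor of the other. Unshielded triples a–c–b are then oriented as
colliders iff c is absent from the *maximum-p-value* separating set of (a, b),
searching the current adjacency neighborhoods in addition to recorded sets
(ties broken to the smallest, lexicographically first set). Zhang's rules
R1–R4 (including the discriminating-path rule, which consults the same
max-p sepsets) and R8–R10 run to a fixed point. R5–R7 are omitted: the
pipeline assumes no selection bias. A rule contradicting a knowledge-forced
mark raises a conflict error naming the edge and rule; contradictions between
data-driven rules keep the first definite mark (deterministic, since nodes,
triples and candidate sets are always processed in lexicographic order —
there is no randomness anywhere in FCI).

## Pooling

An edge instance is an unordered pair plus its oriented mark pair; each of
the m PAGs votes for its instances with equal weight, and the threshold-t
view keeps instances with agreement ≥ t (defaults 0.3 / 0.5 / 1.0). Agreement
is mark-level by default — the same pair with different mark pairs counts as
distinct, conflicting variants, reported side by side — with an
adjacency-only mode for sensitivity analysis. Threshold views are nested by
construction. The outcome subnetwork keeps edges on paths of ≤ `max_steps`
(default 2) edges ending at the outcome whose marks are compatible with
influence toward it: arrowhead into each successor, tail or circle at the
predecessor side; a bidirected edge (pure confounding) is not influence and
is excluded. Recovery reports compare a threshold view against the true MAG
*projected onto the analyzed variables* (variables dropped by selection are
treated as unmeasured): adjacency precision (1.0 for an empty view, by
convention), adjacency recall, and the fraction of claimed arrowheads
consistent with true non-ancestry.

## Pipeline defaults and problem sizes

The orchestrator validates its nested-dict config strictly (unknown keys are
errors) and derives all stage seeds from the single top-level seed; the
manifest records the config, its hash and package versions, making re-runs
bit-identical. Defaults: QC threshold 0.75, m = 50 imputations, 5 MICE
iterations, random-forest imputation, λ = 0.15, α = 0.05, max conditioning
size 3, pooling tiers 30/50/100%. The bundled analyses and the acceptance
script run scaled-down designs chosen to exercise every stage at desk scale —
20–30 observed variables, 2–3 latents, n = 2000–3000, m = 5–10, 5–10
replicate seeds — with m = 50 reserved for the configuration default, as the
per-imputation analyses are embarrassingly parallel in real use.

## Known limitations

- Selection-bias structures (undirected PAG edges, rules R5–R7) are out of
  scope; the synthetic cohorts contain none.
- The score/LR tests are asymptotic for categorical targets; at very small n
  or near-empty cells their calibration degrades (the F-test branch is exact).
- Mark-level pooling can fragment votes across orientation variants of the
  same pair: a pair can clear a threshold in adjacency mode yet miss it in
  mark mode. Both modes are exposed.
- `pdsep_pool_cap` trades a small amount of adjacency correctness under dense
  latent confounding for tractability; set it to None to recover full FCI
  behaviour.
- The MGM pseudolikelihood is non-convex in general mixed models; the edge
  count along a λ path is monotone in practice but rare non-monotone steps
  are possible and are tolerated, not silenced, in the tests.
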