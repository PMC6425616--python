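# Methods

## Model

We reconcile a gene forest 𝒢 (a set of rooted binary gene trees with globally
unique leaf labels) with a rooted binary species tree S, related by a total
map s(·) from gene leaves to species leaves; s need not be injective or
surjective.  A mapping α assigns every gene node a species node subject to
ancestor-consistency (a node's image dominates every descendant's image) and
leaf anchoring (α(l) = s(l)).  Events are derived, not free parameters: an
internal node is a speciation exactly when its image is the LCA of its
children's images and those images are incomparable; otherwise it is a
duplication.  Deriving events this way is never worse than declaring a
duplication where a speciation is allowed (the speciation label saves two
losses and cannot increase any duplication height), so it loses no optima and
makes a reconciliation a pure node-to-species map.

Losses follow the standard distance accounting: an internal node u
contributes dist(α(u), α(u₁)) + dist(α(u), α(u₂)), minus 2 if u is a
speciation.  The LCA-mapping μ (every node as low as possible) is the
pointwise-minimal valid mapping and minimises the loss count; repeated
*shift-downs* — remapping a node k levels towards its children's LCA, which
removes at least k losses — turn any valid mapping into μ.

Segmental counting charges duplications per layer, not per node: for each
species node s, the duplications co-mapped to s form a sub-poset of the gene
forest under ancestry, and the number of simultaneous events needed to
explain them is that poset's height (= minimum antichain partition, by
Mirsky's theorem; the implementation uses the longest-chain formulation, the
exhaustive-partition formulation lives in the validation oracle, and a test
holds them equal).  Heights are counted in nodes: one isolated duplication at
s gives h(s) = 1.  The objective is cost_SD(α) = δ·Σ_s h_α(s) + λ·l(α).

A convention inherited with the model and kept internally: the iterated
parent map satisfies par⁰(x) = par(x) (one step, not the identity) and
par(root) = root.  `RootedTree.par_k` implements exactly this and no
identity-at-zero helper is exposed; the candidate bound below is stated
directly in ancestor counts to avoid the off-by-one trap.

## Solving

**λ ≥ δ.**  μ is optimal (unique for λ > δ): lowering any lifted node saves
at least one loss and costs at most one duplication layer.  The solver
returns μ without searching; for λ = δ other optima of equal cost may exist.

**δ > λ.**  The problem is NP-hard even at λ = 0, so we run an exact
branch-and-bound over *partial mappings* (undetermined nodes carry ⊥;
determinedness is downward-closed).  For a minimal undetermined node v (both
children determined) write base(v) = LCA(α(v₁), α(v₂)).  Three facts, each
valid for arbitrary partial mappings, drive the search:

1. *Candidate bound.*  An optimal completion maps v within the ⌈δ/λ⌉
   ancestors of base(v), inclusive of base(v) itself (⌈δ/λ⌉+1 candidates
   before clamping at the root): mapping higher loses more in losses than one
   duplication layer can be worth.
2. *Required duplications.*  v is a duplication in every completion iff one
   of its children's images dominates μ(v).
3. *Easy nodes.*  If v is not a required duplication, or if placing v at
   base(v) leaves every per-species height unchanged (a free slot in an
   existing layer), then every optimal completion maps v to base(v); such
   nodes are fixed without branching, to a fixpoint, processed in increasing
   depth of base(v) for determinism.

The search starts from the state produced by fixing all non-required
duplications bottom-up (all speciations, zero duplications), then repeatedly
branches a *lowest* minimal undetermined node (no other node's base strictly
below its own; ties broken by maximum base depth, then smallest canonical
name) over its candidate path, bottom-up.  Branches are cut when the
duplication-height sum exceeds the budget d, or when the admissible bound
δ·d̂(partial) + λ·(l(partial) + Σ_w pending(w)) reaches the incumbent, where
pending(w) is w's loss contribution at base(w) — a lower bound since lifting
only adds losses.  Both d̂ and l are monotone along a branch, so the bound is
admissible; caches (per-species duplication lists and heights, loss count,
the minimal-undetermined set, and per-node base/required/pending info) are
maintained incrementally with trail-based undo, and tests compare them
against from-scratch recomputation.

**A published co-mapping rule we do not use.**  A stronger rule in the
literature forces, when a lowest minimal undetermined node is mapped to s,
every minimal undetermined node w with base(w) ≤ s to s as well.  Random
cross-validation against exhaustive enumeration during development produced a
counterexample: with several lowest nodes whose bases are pairwise
incomparable, an optimal completion can map v to the root while w optimally
stays strictly below s (the rule's case analysis covers only images
comparable to base(v)).  Applying the rule there loses the optimum.  We
therefore rely on the easy-node fixpoint alone; the counterexample is frozen
as a regression test.  Consequences: branching steps raise the height sum by
exactly 1 when branching at base(v), but by 0 when a higher placement reuses
an existing layer, so the search-tree depth is bounded by the number of
internal gene nodes rather than by d alone; exactness is unaffected (the
height-budget prune remains valid), but the strict worst-case bound
⌈δ/λ⌉^d no longer holds.  The `auto` driver runs a single bounded search
with budget d̂(μ) and the cost of μ as incumbent — complete because the
optimum never needs a higher height sum than μ's (μ minimises losses).

**λ = 0.**  The search needs λ > 0, so a zero loss cost is replaced by
ε = δ / (2·|V(𝒢)|·|V(S)| + 1): even the maximal possible number of losses
then costs less than one duplication, making the search minimise d̂ first and
loss count second (the reported lexicographic tie-break).  Final costs are
re-expressed with the true λ = 0; losses are reported but not charged.

## Synthetic data

The generator evolves each family top-down inside the species tree.  A
lineage entering a branch duplicates there with probability `dup_rate`
(default 0.1), at most once per lineage per branch — both copies then
continue to the branch's endpoint without further duplication on that branch.
At each speciation a lineage is lost on a child branch with probability
`loss_rate` (default 0.05).  Unary nodes left by pruning are suppressed; the
recorded ground-truth mapping stays valid, and its loss count is computed
with the model's distance formulas (not the raw pruning count, which the
suppression can hide events from) so that the tally is exactly what the
solver scores.  Families that go fully extinct are resampled up to 100 times.
Defaults are 8 species and 10 families — enough scattered events to exercise
scoring and search without swamping planted signal.

One duplication per lineage per branch means two same-species duplications of
one family always sit in disjoint copies, hence are incomparable: every
ground-truth per-species duplication forest is an antichain, and the true
d̂ equals the number of species nodes carrying at least one duplication.
This makes planted ground truths exact by construction.  The price is that
the generator never produces within-branch duplication *chains* (tandem
re-duplication of a fresh copy); chains still arise in the model and solver
(nested duplications across branches, and any user-supplied data), just not
in generated ground truths.

*Episodes* force a chosen set of families to duplicate on a chosen species
node, emulating a segmental or whole-genome duplication; with background
rates at zero, E planted episodes give ground-truth d̂ = E exactly.  The
episode-recovery study uses δ = 10, λ = 1 (the largest ratio in the solver's
cross-validation grid): expensive enough that the optimum keeps co-mapped
layers, cheap enough in losses that merging distinct episode layers into a
common ancestor never pays on these instances, so the planted count is
recovered exactly.

What passing synthetic tests does *not* show: real gene families violate the
generator's assumptions (no rate heterogeneity across branches or families,
no horizontal transfer or incomplete lineage sorting, no sequence-level
uncertainty in the input trees).  Results on real data inherit the usual
caveats of parsimony reconciliation, including sensitivity to the chosen
δ/λ, which the model cannot estimate from data.

## Problem sizes and runtime envelope

Test and validation scales were chosen to keep exhaustive oracles exact and
runs fast: oracle cross-validation uses ≥ 300 instances with ≤ 7 internal
gene nodes and ≤ 6 species leaves across cost ratios 0.5–10; episode
recovery uses 50 replicates at 8 species × 10 families, loss-free.  The exact
search handles such desk-scale instances (and moderate instances at ratios
≤ 3) in milliseconds to seconds.  Dense background duplications combined
with large δ/λ open a wide merge-exploration space (the NP-hard core of the
problem: many near-symmetric co-optimal lift combinations); on such inputs
the search can take minutes or more.  The `--max-expansions` safety valve
returns the best mapping found, flagged non-optimal, with a distinct exit
code.

## Degenerate inputs and conventions

Single-leaf gene trees are valid (they contribute nothing); an empty forest
is an error.  Non-binary trees are rejected at parse time with the offending
node named.  Branch lengths are parsed and ignored (the model is
topology-only); species-tree internal labels are kept as display names.
Reported node identifiers are canonical leaf-set names (sorted leaf labels
joined by `|`), so outputs are stable across runs and node orderings.  Leaf
maps come from a two-column TSV, or from the `SPECIES__geneid` label
convention when no file is given.  In `score`, nodes absent from the mapping
file default to their LCA-mapping image, so remapping files only name the
nodes they move.

## Known limitations

* No horizontal transfer, incomplete lineage sorting, or segmental losses;
  no resolution of non-binary input trees.
* One deterministic optimum is returned; co-optima are not enumerated.
* δ and λ are user inputs; the package neither estimates them nor searches
  the cost space beyond the explicit `sweep` subcommand.
* The worst-case fixed-parameter guarantee tied to the dropped co-mapping
  rule is not claimed; see the solver section.
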