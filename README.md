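# segrec — reconciling many gene trees with segmental duplications and losses

`segrec` reconciles a *set* of rooted binary gene trees with a rooted binary
species tree at once, treating co-occurring duplications as shared
**segmental** events.  It is aimed at phylogenomics analyses that ask whether
duplications observed across many gene families trace back to a few large
duplication events — up to and including whole-genome duplications — rather
than to many independent single-gene ones.

## The model

A reconciliation α maps every gene-tree node to a species-tree node.  Leaves
are anchored by the gene-to-species assignment s(·); an internal node u with
children u₁, u₂ is a **speciation** (𝕊) when α(u) = LCA(α(u₁), α(u₂)) and the
children's images are incomparable, and a **duplication** (𝔻) otherwise
(speciations are chosen whenever allowed, so events are determined by the
node-to-species map).  Losses are counted per branch:
l(u) = dist(α(u), α(u₁)) + dist(α(u), α(u₂)), minus 2 for a speciation.

Classically each duplication node costs δ.  Under segmental counting,
duplications from different families mapped to the same species node s can be
explained by one macro-event per *layer*: the minimum number of simultaneous
events at s is the height h_α(s) of the forest induced by the duplications
co-mapped to s (equivalently, the minimum number of antichains partitioning
them).  Writing d̂(α) = Σ_s h_α(s), the objective is

    cost_SD(α) = δ · d̂(α) + λ · l(α),

with δ the segmental-duplication cost and λ the loss cost.

Two regimes follow:

* **λ ≥ δ** — the classic LCA-mapping μ (each internal node as low as
  possible) is optimal, and uniquely so when λ > δ.  This is a polynomial
  fast path.
* **δ > λ** — minimising cost_SD is NP-hard.  `segrec` runs an exact
  branch-and-bound over partial mappings: branching is restricted to a
  candidate path of ⌈δ/λ⌉ ancestors above each node's lowest placement,
  forced ("easy") nodes are fixed without branching, and branches are cut by
  an admissible bound and an optional duplication-height budget.  λ = 0 is
  handled by an epsilon substitution that makes the search minimise d̂ first
  and losses second.

## Worked example

The bundled two-family example (also in `segrec.examples`) uses the species
tree `((A,B)E,(C,D)G)F` and two gene trees with six duplication nodes.
Score the LCA-mapping (δ = 1, λ = 0 prints pure segmental counts):

```bash
segrec score --species-tree species.nwk --gene-trees genes.nwk \
             --dup-cost 1 --loss-cost 0
```

```
species	dup_height
F	2
E	1
A	1
B	1
C	1
#total_d_hat	6
#dup_nodes	6
#losses	7
#cost_sd	6
```

Six duplication nodes, six segmental layers (a two-deep chain at the root F
and singletons at A, B, C, E): the LCA-mapping gains nothing from segmental
counting here.  Now make duplications expensive and solve:

```bash
segrec reconcile --species-tree species.nwk --gene-trees genes.nwk \
                 --dup-cost 3 --loss-cost 1
```

```
species	dup_height
F	2
E	1
C	1
#total_d_hat	4
#dup_nodes	6
#losses	9
#cost_sd	21
```

The optimum lifts the A- and B-duplications into existing layers: still six
duplication nodes (`#dup_nodes`), but only four segmental events
(`#total_d_hat`), at the price of two extra losses — cost 3·4 + 1·9 = 21
versus 3·6 + 1·7 = 25 for the LCA-mapping.  A hand-made alternative that
instead lifts three duplications to the root (shipped as
`segrec.examples.ALTERNATIVE_ASSIGNMENT`, scored with `--mapping`) reaches
d̂ = 4 as a three-layer stack at F plus the singleton at A.

Other subcommands: `simulate` (seeded instances with planted episodes and
known ground truth), `oracle` (exhaustive optimum on tiny inputs), and
`sweep` (a duplication-cost sweep over a user-supplied gene-family dataset,
e.g. the classic 16-eukaryote compilation).

## Layout

| Module | Contents |
| --- | --- |
| `segrec.trees` | rooted binary trees/forests, Newick I/O, LCA/ancestry machinery |
| `segrec.model` | mappings, event classification, losses, duplication-forest heights, cost_SD |
| `segrec.solver` | LCA fast path and the exact branch-and-bound for δ > λ |
| `segrec.oracle` | brute-force enumeration and antichain partitioning (validation only) |
| `segrec.synth` | seeded instance generator with planted segmental episodes |
| `segrec.cli` | `segrec` command-line entry point |

See `docs/methods.md` for the model details, algorithmic design choices and
known limitations.
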