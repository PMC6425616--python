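"""Seeded generator of reconciliation instances with known ground truth.

Gene families evolve top-down inside a species tree: a lineage entering a
species-tree branch may duplicate there (one Bernoulli draw per lineage per
branch; both copies then continue to the branch's endpoint), and each lineage
may be lost on a child branch at each speciation.  Unary nodes produced by
pruning are suppressed, which can hide losses from the raw pruning count; the
recorded ground truth therefore scores losses with the reconciliation
distance formulas on the recorded mapping, which is exactly what the solver
scores.

Because a lineage duplicates at most once per branch, two duplications of the
same family mapped to the same species are always incomparable (they sit in
disjoint copies), so every per-species duplication forest of the ground truth
is an antichain and the true duplication-height sum is simply the number of
species nodes carrying at least one duplication.  Planted *episodes* force a
set of families to duplicate together on a chosen species node, emulating a
segmental/whole-genome duplication shared across families.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .model import CostParams, LeafMap, Mapping, count_losses, dup_heights
from .trees import Forest, Node, RootedTree, parse_forest, parse_tree, write_forest, write_newick


class FamilyExtinctError(RuntimeError):
    """All lineages of a family were lost, repeatedly, beyond the retry cap."""


@dataclass
class SimParams:
    """Study conditions for the generator.

    Defaults describe a moderate regime: 8 extant species, 10 gene families,
    a 10% chance for a lineage to duplicate on any given branch and a 5%
    chance to be lost on a child branch — enough events to exercise the
    scoring and the solver without swamping the signal of planted episodes.
    """

    n_species: int = 8
    n_families: int = 10
    dup_rate: float = 0.1
    loss_rate: float = 0.05
    episodes: list[tuple[str, list[int]]] = field(default_factory=list)
    seed: int = 0
    retry_cap: int = 100

    def __post_init__(self):
        if not (0.0 <= self.dup_rate <= 1.0 and 0.0 <= self.loss_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """The generating scenario: the true mapping, and its scores."""

    mapping: Mapping
    d_hat: int
    losses: int
    heights: dict[Node, int]

    def cost(self, costs: CostParams) -> float:
        return costs.dup_cost * self.d_hat + costs.loss_cost * self.losses


def random_species_tree(n_leaves: int, seed: int) -> RootedTree:
    """Random binary topology by sequential random coalescence of the leaf
    set (Yule-like); leaves are labeled S1..Sn."""
    if n_leaves < 2:
        raise ValueError("need at least 2 species")
    rng = random.Random(seed)
    pool: list[Node] = [Node(label=f"S{i + 1}") for i in range(n_leaves)]
    while len(pool) > 1:
        i, j = rng.sample(range(len(pool)), 2)
        a, b = pool[i], pool[j]
        parent = Node()
        parent.children = [a, b]
        a.parent = parent
        b.parent = parent
        pool = [n for k, n in enumerate(pool) if k not in (i, j)]
        pool.append(parent)
    return RootedTree(pool[0])


def evolve_family(
    species: RootedTree,
    params: SimParams,
    family_id: int,
    seed: int,
    forced: Optional[set[Node]] = None,
) -> tuple[RootedTree, dict[str, str], dict[Node, Node]]:
    """Simulate one gene family inside the species tree.

    Returns the gene tree, its leaf-label -> species-label fragment, and the
    recorded true node -> species mapping.  ``forced`` species nodes always
    receive a duplication (planted episode); otherwise duplication on a branch
    is Bernoulli(dup_rate), at most once per lineage per branch.  Lineages are
    lost on child branches with probability loss_rate; a family in which every
    lineage dies is resampled up to the retry cap.
    """
    forced = forced or set()
    rng = random.Random(seed)
    truth: dict[Node, Node] = {}
    leafmap: dict[str, str] = {}
    counter = [0]

    def enter(s: Node, may_dup: bool) -> Optional[Node]:
        # lineage on the branch ending at species node s
        if may_dup and (s in forced or rng.random() < params.dup_rate):
            left = enter(s, False)
            right = enter(s, False)
            if left is None:
                return right
            if right is None:
                return left
            node = Node()
            node.children = [left, right]
            left.parent = node
            right.parent = node
            truth[node] = s
            return node
        return at_node(s)

    def at_node(s: Node) -> Optional[Node]:
        if s.is_leaf:
            counter[0] += 1
            label = f"{s.label}__F{family_id}g{counter[0]}"
            leaf = Node(label=label)
            truth[leaf] = s
            leafmap[label] = s.label
            return leaf
        kids = []
        for child in s.children:
            if rng.random() < params.loss_rate:
                continue  # lineage lost on the branch to this child
            sub = enter(child, True)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # unary speciation suppressed
        node = Node()
        node.children = kids
        for k in kids:
            k.parent = node
        truth[node] = s
        return node

    for attempt in range(params.retry_cap):
        truth.clear()
        leafmap.clear()
        counter[0] = 0
        root = enter(species.root, True)
        if root is not None:
            tree = RootedTree(root)
            kept = {n for n in tree.nodes}
            return tree, leafmap, {n: truth[n] for n in kept}
    raise FamilyExtinctError(
        f"family {family_id} went extinct {params.retry_cap} times in a row"
    )


def generate_instance(
    species: RootedTree,
    params: SimParams,
) -> tuple[Forest, LeafMap, GroundTruth]:
    """Generate a full instance: all families (with any planted episodes),
    the combined leaf map, and the ground-truth mapping with its tally.

    The generator's own duplication-height tally counts, per species node,
    one unit when at least one duplication maps there (see module docstring);
    an invariant test checks it against the model's chain-based recount.
    """
    episode_targets: dict[int, set[Node]] = {}
    for name, fams in params.episodes:
        target = species.node_by_name(name)
        for f in fams:
            if not 0 <= f < params.n_families:
                raise ValueError(f"episode references unknown family {f}")
            episode_targets.setdefault(f, set()).add(target)

    trees = []
    leafmap: dict[str, str] = {}
    truth_map: dict[Node, Node] = {}
    master = random.Random(params.seed)
    for fam in range(params.n_families):
        fam_seed = master.randrange(2**31)
        tree, lm, tm = evolve_family(
            species, params, fam, fam_seed, forced=episode_targets.get(fam)
        )
        trees.append(tree)
        leafmap.update(lm)
        truth_map.update(tm)

    forest = Forest(trees)
    lmap = LeafMap(leafmap)
    mapping = Mapping(forest, species, lmap,
                      image={v: truth_map[v] for v in forest.nodes})

    # generator-side tally: species carrying >= 1 duplication each count 1
    dup_species = {
        mapping.image[v]
        for v in mapping.determined_internal()
        if mapping.event(v) == "D"
    }
    tally_dhat = len(dup_species)
    heights = dup_heights(mapping)
    truth = GroundTruth(
        mapping=mapping,
        d_hat=tally_dhat,
        losses=count_losses(mapping),
        heights=heights,
    )
    return forest, lmap, truth


def plant_episodes(
    species: RootedTree,
    params: SimParams,
) -> tuple[Forest, LeafMap, GroundTruth]:
    """Alias of :func:`generate_instance` emphasising the planted-episode use
    case; episodes are carried in ``params.episodes``."""
    return generate_instance(species, params)


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------


def write_fixture(species: RootedTree, forest: Forest, leafmap: LeafMap,
                  truth: Optional[GroundTruth], params: SimParams,
                  out_dir: str | Path) -> None:
    """Emit species Newick, gene multi-Newick, leaf-map TSV, ground-truth
    mapping TSV and a JSON manifest; reading them back reproduces the
    instance exactly (same seed regenerates byte-identical files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "species.nwk").write_text(write_newick(species) + "\n")
    (out / "genes.nwk").write_text(write_forest(forest))
    (out / "leafmap.tsv").write_text(leafmap.to_tsv())
    if truth is not None:
        (out / "truth.tsv").write_text(truth.mapping.to_tsv())
    manifest = {
        "seed": params.seed,
        "n_species": params.n_species,
        "n_families": params.n_families,
        "dup_rate": params.dup_rate,
        "loss_rate": params.loss_rate,
        "episodes": [[name, list(fams)] for name, fams in params.episodes],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_fixture(in_dir: str | Path) -> tuple[RootedTree, Forest, LeafMap, SimParams]:
    inp = Path(in_dir)
    species = parse_tree((inp / "species.nwk").read_text())
    forest = parse_forest((inp / "genes.nwk").read_text())
    leafmap = LeafMap.from_tsv((inp / "leafmap.tsv").read_text())
    man = json.loads((inp / "manifest.json").read_text())
    params = SimParams(
        n_species=man["n_species"],
        n_families=man["n_families"],
        dup_rate=man["dup_rate"],
        loss_rate=man["loss_rate"],
        episodes=[(name, list(fams)) for name, fams in man["episodes"]],
        seed=man["seed"],
    )
    return species, forest, leafmap, params
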