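"""Shared fixtures: small random reconciliation instances with ground truth."""

from __future__ import annotations

import random

import pytest

from segrec.model import CostParams, LeafMap, lca_mapping
from segrec.synth import SimParams, generate_instance, random_species_tree
from segrec.trees import parse_forest, parse_tree


def make_instance(seed: int, max_species: int = 4, max_families: int = 3,
                  dup_rate: float = 0.25, loss_rate: float = 0.15):
    """One random small instance (species tree, gene forest, leaf map)."""
    rng = random.Random(seed)
    species = random_species_tree(rng.randint(2, max_species), seed)
    params = SimParams(
        n_species=len(species.leaves),
        n_families=rng.randint(1, max_families),
        dup_rate=dup_rate,
        loss_rate=loss_rate,
        seed=seed,
    )
    forest, leafmap, truth = generate_instance(species, params)
    return species, forest, leafmap, truth


def small_instances(n: int, base_seed: int = 0, max_internal: int = 7,
                    max_species: int = 4, **kw):
    """Yield n random instances whose gene forests have at most
    ``max_internal`` internal nodes (suitable for exhaustive oracles)."""
    out = []
    seed = base_seed
    while len(out) < n:
        species, forest, leafmap, truth = make_instance(
            seed, max_species=max_species, **kw
        )
        seed += 1
        internal = sum(1 for v in forest.nodes if not v.is_leaf)
        if internal <= max_internal:
            out.append((species, forest, leafmap, truth))
    return out


@pytest.fixture
def congruent_instance():
    """Gene tree topologically identical to the species tree, bijective map."""
    species = parse_tree("(((A,B),C),(D,E));")
    forest = parse_forest("(((A__g1,B__g1),C__g1),(D__g1,E__g1));")
    leafmap = LeafMap.from_label_convention(forest)
    return species, forest, leafmap


@pytest.fixture
def caterpillar_instance():
    """Caterpillar species tree with named internal nodes, used for
    loss-accounting tests that lift a duplication a known number of levels."""
    species = parse_tree("(((((A,B)S,C)X,D)T,E)Y,F)R;")
    forest = parse_forest("(((A__g1,B__g1),A__g2),F__g1);")
    leafmap = LeafMap.from_label_convention(forest)
    return species, forest, leafmap
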