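"""Event classification, loss counting, duplication-forest heights, scoring."""

import random

import pytest

from segrec.examples import (
    ALTERNATIVE_ASSIGNMENT,
    alternative_mapping,
    segmental_example,
)
from segrec.model import (
    CostParams,
    DUPLICATION,
    InvalidMappingError,
    LeafMap,
    SPECIATION,
    classify_event,
    cost_sd,
    count_losses,
    dup_heights,
    lca_mapping,
    mapping_from_assignment,
    validate_mapping,
)
from segrec.oracle import min_antichain_partition
from segrec.synth import SimParams, generate_instance, random_species_tree

from conftest import small_instances


def random_lifted_mapping(mu, rng, n_lifts=3):
    """A random valid mapping obtained from the LCA-mapping by lifting some
    internal nodes towards the root (preserves ancestor-consistency because
    only images of ancestors grow)."""
    m = mu.copy()
    internal = [v for v in m.forest.nodes if not v.is_leaf]
    S = m.species
    for _ in range(n_lifts):
        if not internal:
            break
        v = rng.choice(internal)
        # lifting v requires every ancestor's image to dominate; lift the
        # whole ancestor chain to keep validity
        target = S.par(m.image[v])
        m.image[v] = target
        node = v.parent
        while node is not None:
            if not S.is_ancestor_or_equal(m.image[node], target):
                m.image[node] = target
            node = node.parent
    assert validate_mapping(m) is None
    return m


class TestCostParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            CostParams(0.0, 1.0)
        with pytest.raises(ValueError):
            CostParams(1.0, -1.0)
        CostParams(1.0, 0.0)  # zero loss cost is fine


class TestLeafMap:
    def test_tsv_roundtrip(self):
        lm = LeafMap({"g1": "A", "g2": "B"})
        assert LeafMap.from_tsv(lm.to_tsv()).by_label == lm.by_label

    def test_label_convention_failure(self):
        from segrec.trees import parse_forest
        forest = parse_forest("(x,y);")
        with pytest.raises(ValueError, match="convention"):
            LeafMap.from_label_convention(forest)

    def test_validation_errors(self, congruent_instance):
        species, forest, _ = congruent_instance
        with pytest.raises(InvalidMappingError, match="no species assignment"):
            LeafMap({"A__g1": "A"}).validate(forest, species)
        bad = {l.label: "Z" for l in forest.leaves}
        with pytest.raises(InvalidMappingError, match="unknown species"):
            LeafMap(bad).validate(forest, species)


class TestLcaMapping:
    def test_congruent_tree_is_all_speciations(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        mu = lca_mapping(forest, species, leafmap)
        summary = cost_sd(mu, CostParams(1.0, 1.0))
        assert summary.d_hat == 0 and summary.losses == 0
        assert summary.cost_sd == 0
        for v in forest.nodes:
            if not v.is_leaf:
                assert mu.event(v) == SPECIATION
                # each gene node sits on its species counterpart
                gene_species = {l.label.split("__")[0] for l in v.leaves()}
                sp_leaves = {l.label for l in mu.image[v].leaves()}
                assert gene_species == sp_leaves

    def test_mu_is_pointwise_minimal(self):
        rng = random.Random(5)
        for species, forest, leafmap, _ in small_instances(20, base_seed=50):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(5):
                alpha = random_lifted_mapping(mu, rng)
                for v in forest.nodes:
                    assert species.is_ancestor_or_equal(alpha.image[v], mu.image[v])

    def test_matches_naive_recursion(self):
        for species, forest, leafmap, _ in small_instances(30, base_seed=99):
            mu = lca_mapping(forest, species, leafmap)
            for tree in forest.trees:
                def naive(node):
                    if node.is_leaf:
                        return species.node_by_name(leafmap.species_of(node.label))
                    return species.lca(naive(node.children[0]), naive(node.children[1]))
                for v in tree.nodes:
                    assert mu.image[v] is naive(v)


class TestEvents:
    def test_speciation_and_duplication_basics(self):
        from segrec.trees import parse_forest, parse_tree
        species = parse_tree("((A,B)E,C)R;")
        forest = parse_forest("((A__1,B__1),(A__2,A__3));")
        mu = lca_mapping(forest, species, LeafMap.from_label_convention(forest))
        t = forest.trees[0]
        spec_node = t.root.children[0]   # children map to A and B -> S at E
        dup_node = t.root.children[1]    # children map to A and A -> D at A
        assert classify_event(mu, spec_node) == SPECIATION
        assert classify_event(mu, dup_node) == DUPLICATION
        # root: children map to E and A (comparable) -> duplication
        assert classify_event(mu, t.root) == DUPLICATION

    def test_lifted_nodes_are_duplications(self):
        """A node mapped strictly above its LCA image is always a duplication,
        and so is any node with a descendant mapped at or above its LCA image."""
        rng = random.Random(17)
        checked = 0
        for species, forest, leafmap, _ in small_instances(40, base_seed=11):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(5):
                alpha = random_lifted_mapping(mu, rng)
                for v in forest.nodes:
                    if v.is_leaf:
                        continue
                    if alpha.image[v] is not mu.image[v]:
                        assert alpha.event(v) == DUPLICATION
                        checked += 1
        assert checked >= 100

    def test_descendant_domination_forces_duplication(self):
        """If a proper descendant's image dominates v's LCA image, v is a
        duplication."""
        rng = random.Random(23)
        checked = 0
        for species, forest, leafmap, _ in small_instances(40, base_seed=31):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(5):
                alpha = random_lifted_mapping(mu, rng)
                for tree in forest.trees:
                    for v in tree.nodes:
                        if v.is_leaf:
                            continue
                        stack = list(v.children)
                        dominated = False
                        while stack:
                            w = stack.pop()
                            if species.is_ancestor_or_equal(
                                alpha.image[w], mu.image[v]
                            ):
                                dominated = True
                            stack.extend(w.children)
                        if dominated:
                            assert alpha.event(v) == DUPLICATION
                            checked += 1
        assert checked >= 100


class TestLosses:
    def test_congruent_is_lossless(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        assert count_losses(lca_mapping(forest, species, leafmap)) == 0

    def test_lifting_two_levels_adds_exactly_two_losses(self, caterpillar_instance):
        """Lifting a duplication two species levels adds 4 losses below it and
        removes 2 above: remapping it back down saves exactly 2."""
        species, forest, leafmap = caterpillar_instance
        mu = lca_mapping(forest, species, leafmap)
        dup = forest.trees[0].root.children[0]
        assert mu.event(dup) == DUPLICATION and mu.image[dup].name == "S"
        lifted = mapping_from_assignment(
            forest, species, leafmap, {dup.canonical_name: "T"}
        )
        assert lifted.event(dup) == DUPLICATION
        assert count_losses(lifted) - count_losses(mu) == 2

    def test_matches_per_branch_path_enumeration(self):
        """Loss count equals, per determined internal node, the number of
        species-branch traversals its children's images imply (minus two for a
        speciation)."""
        rng = random.Random(3)
        for species, forest, leafmap, _ in small_instances(25, base_seed=77):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(4):
                alpha = random_lifted_mapping(mu, rng)
                expected = 0
                for v in alpha.forest.nodes:
                    if v.is_leaf:
                        continue
                    for c in v.children:
                        # walk up from the child's image to v's image
                        node = alpha.image[c]
                        while node is not alpha.image[v]:
                            expected += 1
                            node = node.parent
                    if alpha.event(v) == SPECIATION:
                        expected -= 2
                assert count_losses(alpha) == expected

    def test_invalid_mapping_rejected(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        mu = lca_mapping(forest, species, leafmap)
        v = forest.trees[0].root.children[0]
        bad = mu.copy()
        bad.image[v] = species.node_by_name("D")  # incomparable to children
        with pytest.raises(InvalidMappingError):
            count_losses(bad)


class TestDupHeights:
    def test_no_duplications_all_zero(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        h = dup_heights(lca_mapping(forest, species, leafmap))
        assert all(v == 0 for v in h.values())

    def test_heights_equal_min_antichain_partition(self):
        rng = random.Random(13)
        cross_checked = 0
        for species, forest, leafmap, _ in small_instances(
            30, base_seed=7, dup_rate=0.35, loss_rate=0.1
        ):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(4):
                alpha = random_lifted_mapping(mu, rng)
                h = dup_heights(alpha)
                by_species = {}
                for v in alpha.duplication_nodes():
                    by_species.setdefault(alpha.image[v], []).append(v)
                for s, dups in by_species.items():
                    if len(dups) <= 6:
                        assert h[s] == min_antichain_partition(dups)
                        cross_checked += 1
        assert cross_checked >= 30

    def test_chain_of_duplications_counts_full_length(self):
        from segrec.trees import parse_forest, parse_tree
        species = parse_tree("(A,B);")
        forest = parse_forest("(((A__1,A__2),A__3),A__4);")
        mu = lca_mapping(forest, species, LeafMap.from_label_convention(forest))
        h = dup_heights(mu)
        assert h[species.node_by_name("A")] == 3


class TestCostSd:
    def test_summary_consistency(self):
        rng = random.Random(29)
        costs = CostParams(2.0, 1.0)
        for species, forest, leafmap, _ in small_instances(25, base_seed=123):
            mu = lca_mapping(forest, species, leafmap)
            for _ in range(4):
                alpha = random_lifted_mapping(mu, rng)
                s = cost_sd(alpha, costs)
                assert s.d_hat <= s.d_plain
                assert s.d_hat == sum(s.h_per_species.values())
                assert s.cost_sd == pytest.approx(2.0 * s.d_hat + s.losses)
                # segmental counting never exceeds the classic DL cost
                assert s.cost_sd <= 2.0 * s.d_plain + s.losses


class TestValidateMapping:
    def test_mu_is_valid(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        assert validate_mapping(lca_mapping(forest, species, leafmap)) is None

    def test_child_above_parent_named(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        mu = lca_mapping(forest, species, leafmap)
        child = forest.trees[0].root.children[0].children[0]
        bad = mu.copy()
        bad.image[child] = species.root  # above its parent's image
        report = validate_mapping(bad)
        assert report is not None and child.canonical_name in report

    def test_partial_mapping_property(self, congruent_instance):
        species, forest, leafmap = congruent_instance
        mu = lca_mapping(forest, species, leafmap)
        child = forest.trees[0].root.children[0]
        bad = mu.copy()
        bad.image[child] = None  # determined parent above an undetermined node
        report = validate_mapping(bad)
        assert report is not None and "partial-mapping" in report


class TestWorkedExample:
    def test_lca_mapping_heights(self):
        species, forest, leafmap = segmental_example()
        mu = lca_mapping(forest, species, leafmap)
        summary = cost_sd(mu, CostParams(1.0, 0.0))
        assert summary.heights_by_name() == {"A": 1, "B": 1, "C": 1, "E": 1, "F": 2}
        assert summary.d_hat == 6
        assert summary.cost_sd == 6

    def test_alternative_mapping_merges_layers(self):
        alt = alternative_mapping()
        summary = cost_sd(alt, CostParams(1.0, 0.0))
        assert summary.heights_by_name() == {"A": 1, "F": 3}
        assert summary.d_hat == 4
        # the merge is paid in losses
        species, forest, leafmap = segmental_example()
        mu = lca_mapping(forest, species, leafmap)
        assert count_losses(alt) > count_losses(mu)

    def test_alternative_turns_family_roots_into_duplications(self):
        alt = alternative_mapping()
        for t in alt.forest.trees:
            assert alt.event(t.root) == DUPLICATION
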