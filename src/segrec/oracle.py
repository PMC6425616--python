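"""Exhaustive reference implementations, for validation only.

Everything here is deliberately naive: valid mappings are enumerated outright
(each internal gene node ranges over the ancestors-or-self of its children's
LCA image), and per-species segmental counts are obtained by exhaustive
antichain partitioning.  These serve as independent ground truth for the
polynomial LCA path and the branch-and-bound solver on small instances; they
are never meant for realistic sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from .model import CostParams, LeafMap, Mapping, ReconSummary, cost_sd, lca_mapping
from .trees import Forest, Node, RootedTree


class EnumBudgetExceeded(RuntimeError):
    """The predicted enumeration space exceeds the allowed cap."""


@dataclass(frozen=True)
class EnumBudget:
    max_internal_gene_nodes: int = 10
    max_species_nodes: int = 25
    max_mappings: int = 2_000_000


def _predicted_space(mu: Mapping) -> int:
    """Upper bound on the number of valid mappings: product over internal gene
    nodes of the number of ancestors-or-self of mu(v)."""
    S = mu.species
    total = 1
    for v in mu.forest.nodes:
        if v.is_leaf:
            continue
        total *= S.dist(S.root, mu.image[v]) + 1
    return total


def enumerate_valid_mappings(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    budget: EnumBudget = EnumBudget(),
) -> Iterator[Mapping]:
    """Yield every valid complete mapping exactly once.

    Valid means ancestor-consistent with anchored leaves; each internal node's
    image then ranges over the ancestors-or-self of the LCA of its children's
    images, which is enumerated depth-first in post-order.
    """
    internal = [v for v in forest.postorder() if not v.is_leaf]
    if len(internal) > budget.max_internal_gene_nodes:
        raise EnumBudgetExceeded(
            f"{len(internal)} internal gene nodes exceeds the cap of "
            f"{budget.max_internal_gene_nodes}"
        )
    if len(species) > budget.max_species_nodes:
        raise EnumBudgetExceeded("species tree too large for enumeration")
    mu = lca_mapping(forest, species, leafmap)
    if _predicted_space(mu) > budget.max_mappings:
        raise EnumBudgetExceeded("predicted search space exceeds the cap")

    m = mu.copy()

    def rec(i: int) -> Iterator[Mapping]:
        if i == len(internal):
            yield m.copy()
            return
        v = internal[i]
        lo = species.lca_set([m.image[c] for c in v.children])
        s: Optional[Node] = lo
        while True:
            m.image[v] = s
            yield from rec(i + 1)
            if s.parent is None:
                break
            s = s.parent

    yield from rec(0)


def brute_force_optimum(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    costs: CostParams,
    budget: EnumBudget = EnumBudget(),
) -> tuple[ReconSummary, Mapping]:
    """Minimum-cost reconciliation by exhaustive enumeration.

    Ties are broken by enumeration order (first minimum found), which is
    deterministic: post-order over gene nodes, bottom-up over species.
    """
    best: Optional[tuple[ReconSummary, Mapping]] = None
    for m in enumerate_valid_mappings(forest, species, leafmap, budget):
        summary = cost_sd(m, costs)
        if best is None or summary.cost_sd < best[0].cost_sd:
            best = (summary, m)
    assert best is not None  # at least mu is always enumerated
    return best


def brute_force_min_dhat(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    budget: EnumBudget = EnumBudget(),
) -> tuple[int, int]:
    """Pure segmental objective (loss cost zero): returns the minimum d_hat
    over all valid mappings, and the minimum loss count among mappings
    attaining that d_hat (the lexicographic secondary criterion)."""
    best_d: Optional[int] = None
    best_l: Optional[int] = None
    unit = CostParams(1.0, 0.0)
    for m in enumerate_valid_mappings(forest, species, leafmap, budget):
        summary = cost_sd(m, unit)
        if best_d is None or summary.d_hat < best_d or (
            summary.d_hat == best_d and summary.losses < best_l
        ):
            best_d, best_l = summary.d_hat, summary.losses
    return best_d, best_l


def min_antichain_partition(nodes: list[Node]) -> int:
    """Exact minimum number of antichains partitioning a set of gene nodes
    (ancestry poset), by exhaustive part assignment.  Limited to 8 elements."""
    if len(nodes) > 8:
        raise ValueError("exhaustive antichain partitioning limited to 8 elements")
    if not nodes:
        return 0

    def comparable(a: Node, b: Node) -> bool:
        if a.tree is not b.tree:
            return False
        t = a.tree
        return t.is_ancestor_or_equal(a, b) or t.is_ancestor_or_equal(b, a)

    best = len(nodes)
    parts: list[list[Node]] = []

    def rec(i: int) -> None:
        nonlocal best
        if len(parts) >= best:
            return
        if i == len(nodes):
            best = min(best, len(parts))
            return
        v = nodes[i]
        for part in parts:
            if all(not comparable(v, u) for u in part):
                part.append(v)
                rec(i + 1)
                part.pop()
        parts.append([v])
        rec(i + 1)
        parts.pop()

    rec(0)
    return best
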