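"""Exact solver for minimum-cost reconciliation under segmental duplications.

Two regimes:

* ``loss_cost >= dup_cost``: the LCA-mapping is optimal (and uniquely so when
  the inequality is strict), so the solver returns it directly.

* ``dup_cost > loss_cost``: the problem is NP-hard, and the solver runs an
  exact branch-and-bound search whose branching degree is bounded by the cost
  ratio r = dup_cost/loss_cost and whose useful depth is bounded by the
  duplication-height budget d (plus height-free placements).  Partial
  mappings are grown bottom-up; undetermined nodes carry ``None``.  The search
  relies on three structural facts about optimal completions of a partial
  mapping ``a``:

  - *candidate bound*: an optimal completion maps a minimal undetermined node
    v no higher than the ceil(r)-th ancestor of mu_a(v), the LCA of its
    children's images (shifting a duplication further down always saves more
    in losses than it can cost in height);
  - *required duplications*: v is a duplication in every completion iff one of
    its children's images already dominates mu(v), the global LCA-mapping
    image of v;
  - *easy nodes*: if v is not a required duplication, or if mapping v to
    mu_a(v) leaves every per-species duplication height unchanged, then every
    optimal completion maps v to mu_a(v) — such nodes are fixed without
    branching;
  The first three facts hold for *arbitrary* partial mappings, and they are
  all the pruning this solver uses: branch on a lowest minimal undetermined
  node over its candidate path, then fix easy nodes to a fixpoint.  A
  stronger published co-mapping rule — when a lowest minimal undetermined
  node maps to s, force every minimal undetermined node w with mu_a(w) <= s
  to s as well — is deliberately NOT applied: its case analysis breaks down
  when several lowest nodes have pairwise-incomparable candidate bases (an
  optimal completion may then keep w strictly below s), and applying it can
  lose the optimum.  See tests for a minimal instance witnessing this.

  Without the forcing rule, a branching step raises the duplication-height
  sum by exactly one when the chosen species is the candidate base mu_a(v),
  and by zero or one when it is a proper ancestor (the new duplication may
  slot into an existing layer); the search is exact either way, with branches
  cut as soon as the height budget is exceeded or the admissible bound
  dup_cost * dhat + loss_cost * losses reaches the best cost found.

A zero loss cost is handled by substitution: losses are charged an epsilon
small enough that even the maximum possible number of losses costs less than
one duplication, which makes the search minimize the duplication-height sum
first and losses second; reported costs are then re-expressed with the true
zero loss cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .model import (
    DUPLICATION,
    CostParams,
    LeafMap,
    Mapping,
    ReconSummary,
    _poset_height,
    cost_sd,
    lca_mapping,
)
from .trees import Forest, Node, RootedTree


class InfeasibleBudgetError(RuntimeError):
    """No reconciliation exists within the requested duplication budget."""


class ExpansionLimitExceeded(RuntimeError):
    """Search stopped early; carries the best (possibly non-optimal) result."""

    def __init__(self, result: Optional["SolveResult"]):
        super().__init__("node-expansion limit exceeded")
        self.result = result


@dataclass
class SolveConfig:
    """Solver knobs: costs, duplication-height budget (int or 'auto'), and an
    optional node-expansion safety valve.  The core is deterministic; the seed
    field is reserved for tie-shuffling experiments and unused."""

    costs: CostParams
    budget: int | str = "auto"
    max_expansions: Optional[int] = None
    seed: Optional[int] = None


@dataclass
class SolveResult:
    summary: ReconSummary
    mapping: Mapping
    optimal: bool = True
    expansions: int = 0
    budget_used: int = 0


class PartialState:
    """A partial mapping plus incrementally maintained scores.

    Caches: per-species duplication node lists and heights, their sum
    ``dhat``, and the loss count of the determined part.  Determining a node
    never changes the event or loss contribution of already-determined nodes
    (events depend only on a node's own and its children's images), so single
    assignments update the caches exactly.
    """

    __slots__ = ("mapping", "mu", "dups", "heights", "dhat", "losses", "bots",
                 "info")

    def __init__(self, mapping: Mapping, mu: Mapping,
                 dups=None, heights=None, dhat=0, losses=0, bots=None,
                 info=None):
        self.mapping = mapping
        self.mu = mu  # global LCA-mapping, shared between states
        self.dups: dict[Node, list[Node]] = dups if dups is not None else {}
        self.heights: dict[Node, int] = heights if heights is not None else {}
        self.dhat = dhat
        self.losses = losses
        # minimal undetermined nodes, maintained incrementally
        if bots is None:
            bots = set(mapping.minimal_bot_nodes())
        self.bots: set[Node] = bots
        # per-node (base, required-duplication, min-pending-loss) cache;
        # valid while the node's children images are unchanged — invalidated
        # whenever a child is (un)assigned
        self.info: dict[Node, tuple[Node, bool, int]] = info if info is not None else {}

    def copy(self) -> "PartialState":
        return PartialState(
            self.mapping.copy(), self.mu,
            {s: list(d) for s, d in self.dups.items()},
            dict(self.heights), self.dhat, self.losses, set(self.bots),
            dict(self.info),
        )

    def node_info(self, v: Node) -> tuple[Node, bool, int]:
        """(mu_a(v), required-duplication?, minimum pending loss) for a node
        whose children are determined."""
        cached = self.info.get(v)
        if cached is not None:
            return cached
        m = self.mapping
        S = m.species
        a1, a2 = (m.image[c] for c in v.children)
        base = S.lca(a1, a2)
        muv = self.mu.image[v]
        required = (S.is_ancestor_or_equal(a1, muv)
                    or S.is_ancestor_or_equal(a2, muv))
        minpend = S.dist(base, a1) + S.dist(base, a2)
        if not S.comparable(a1, a2):
            minpend -= 2  # a speciation at the base is possible
        cached = (base, required, minpend)
        self.info[v] = cached
        return cached

    def is_complete(self) -> bool:
        # determinedness is downward-closed, so no minimal undetermined node
        # means no undetermined node at all
        return not self.bots

    def mu_alpha(self, v: Node) -> Node:
        """LCA of the children's images: the lowest species v can map to."""
        return self.node_info(v)[0]

    def assign(self, v: Node, s: Node) -> tuple:
        """Determine v at s, updating duplication heights, losses, and the
        minimal-undetermined set.  Returns an undo record for :meth:`undo`."""
        m = self.mapping
        assert m.image[v] is None and all(m.image[c] is not None for c in v.children)
        m.image[v] = s
        S = m.species
        d = 0
        for c in v.children:
            d += S.dist(s, m.image[c])
        is_dup = m.event(v) == DUPLICATION
        old_h = 0
        if is_dup:
            lst = self.dups.setdefault(s, [])
            lst.append(v)
            old_h = self.heights.get(s, 0)
            new_h = _poset_height(lst)
            self.heights[s] = new_h
            self.dhat += new_h - old_h
        else:
            d -= 2
        self.losses += d
        self.bots.discard(v)
        p = v.parent
        parent_added = False
        if p is not None:
            self.info.pop(p, None)  # p's children images changed
            if m.image[p] is None and all(
                m.image[c] is not None for c in p.children
            ):
                self.bots.add(p)
                parent_added = True
        return (v, s, is_dup, old_h, d, parent_added)

    def undo(self, record: tuple) -> None:
        """Revert one :meth:`assign`."""
        v, s, is_dup, old_h, d, parent_added = record
        if v.parent is not None:
            self.info.pop(v.parent, None)
        if parent_added:
            self.bots.discard(v.parent)
        self.bots.add(v)
        self.losses -= d
        if is_dup:
            lst = self.dups[s]
            assert lst[-1] is v
            lst.pop()
            self.dhat -= self.heights[s] - old_h
            self.heights[s] = old_h
        self.mapping.image[v] = None

    def assignment_delta(self, v: Node, s: Node) -> tuple[int, int]:
        """(height-sum increase, loss contribution) of determining v at s,
        without mutating the state."""
        m = self.mapping
        S = m.species
        a1, a2 = (m.image[c] for c in v.children)
        d = S.dist(s, a1) + S.dist(s, a2)
        if not S.comparable(a1, a2) and s is S.lca(a1, a2):
            return 0, d - 2  # speciation
        existing = self.dups.get(s, [])
        grow = _poset_height(existing + [v]) - self.heights.get(s, 0)
        return grow, d

    def min_pending_loss(self, v: Node) -> int:
        """Admissible lower bound on the loss contribution of the minimal
        undetermined node v in any completion: its contribution at the lowest
        allowed placement mu_a(v) (lifting a node only adds losses)."""
        return self.node_info(v)[2]


# ---------------------------------------------------------------------------
# Predicates and state transitions
# ---------------------------------------------------------------------------


def is_required_duplication(state: PartialState, v: Node) -> bool:
    """v (a minimal undetermined node) is a duplication in *every* completion
    iff a child's image already dominates mu(v), the global LCA image of v."""
    return state.node_info(v)[1]


def is_easy(state: PartialState, v: Node) -> bool:
    """v can be fixed to mu_a(v) without branching: either it is not a
    required duplication (it is then a speciation at mu_a(v) = mu(v) in every
    optimal completion), or placing it as a duplication at mu_a(v) leaves the
    duplication-height sum unchanged (a free slot in an existing layer)."""
    if not is_required_duplication(state, v):
        return True
    t = state.mu_alpha(v)
    existing = state.dups.get(t, [])
    return _poset_height(existing + [v]) == state.heights.get(t, 0)


def initial_cleanup(forest: Forest, species: RootedTree, leafmap: LeafMap,
                    mu: Optional[Mapping] = None) -> PartialState:
    """Starting state: all internal nodes undetermined, then every minimal
    undetermined node that is not a required duplication is fixed to mu_a(v)
    (a speciation), to a fixpoint.  The result is clean: no duplications exist
    at all, and every remaining minimal undetermined node is a required
    duplication."""
    if mu is None:
        mu = lca_mapping(forest, species, leafmap)
    state = PartialState(Mapping(forest, species, leafmap), mu)
    changed = True
    while changed:
        changed = False
        for v in list(state.bots):
            if not is_required_duplication(state, v):
                state.assign(v, state.mu_alpha(v))
                changed = True
    return state


def lowest_minimal_bot_node(state: PartialState) -> Node:
    """A minimal undetermined node v such that no other one has its candidate
    base mu_a strictly below mu_a(v).  Ties (incomparable bases) are broken by
    maximum species depth, then smallest canonical name, for determinism."""
    bots = list(state.bots)
    if not bots:
        raise ValueError("state is complete")
    S = state.mapping.species
    bases = {v: state.mu_alpha(v) for v in bots}
    lowest = [
        v for v in bots
        if not any(
            w is not v
            and bases[w] is not bases[v]
            and S.is_ancestor_or_equal(bases[v], bases[w])
            for w in bots
        )
    ]
    return min(lowest, key=lambda v: (-bases[v].depth, v.canonical_name))


def candidate_species(state: PartialState, v: Node, costs: CostParams) -> list[Node]:
    """Bottom-up path from mu_a(v) through its ceil(ratio) ancestors,
    inclusive on both ends, deduplicated at the root."""
    if costs.loss_cost <= 0:
        raise ValueError("candidate bound needs a positive loss cost")
    k = math.ceil(costs.dup_cost / costs.loss_cost)
    S = state.mapping.species
    out = [state.mu_alpha(v)]
    for _ in range(k):
        nxt = S.par(out[-1])
        if nxt is out[-1]:
            break
        out.append(nxt)
    return out


def _expand_inplace(state: PartialState, v: Node, s: Node,
                    assume_no_easy: bool = False) -> list[tuple]:
    """Assign v to s and fix easy nodes to a fixpoint, in place; returns the
    undo trail (pass to :func:`_undo_all` to revert).

    With ``assume_no_easy`` the entry state is trusted to contain no easy
    minimal undetermined node (true for every state the search recurses on),
    so after each assignment only the nodes whose easiness could have changed
    are re-examined: the newly minimal parent, and — when a duplication was
    added at some species — the nodes whose candidate base is that species.
    """
    trail = []

    def changed_by(record) -> set[Node]:
        _, sp, was_dup, _, _, parent_added = record
        out = set()
        if parent_added:
            out.add(record[0].parent)
        if was_dup:
            for w in state.bots:
                if state.mu_alpha(w) is sp:
                    out.add(w)
        return out

    if assume_no_easy:
        pool: set[Node] = set()
    else:
        pool = set(state.bots)
    rec0 = state.assign(v, s)
    trail.append(rec0)
    pool |= changed_by(rec0)
    easy = {w for w in pool if w in state.bots and is_easy(state, w)}
    while easy:
        w = min(easy, key=lambda u: (state.mu_alpha(u).depth, u.canonical_name))
        record = state.assign(w, state.mu_alpha(w))
        trail.append(record)
        easy.discard(w)
        for u in changed_by(record):
            if u in state.bots and is_easy(state, u):
                easy.add(u)
            else:
                easy.discard(u)
    return trail


def _undo_all(state: PartialState, trail: list[tuple]) -> None:
    for record in reversed(trail):
        state.undo(record)


def apply_and_cleanup(state: PartialState, v: Node, s: Node) -> PartialState:
    """Map the minimal undetermined node v to s, then fix easy nodes to a
    fixpoint (processed in increasing depth of their candidate base, for
    determinism).  Easy-node fixing is forced in every optimal completion, so
    this transition is exact.

    The duplication-height sum grows by exactly 1 when ``s`` is v's candidate
    base mu_a(v) and v was not easy, and by 0 or 1 otherwise (a duplication
    placed higher up may occupy a free slot in an existing layer)."""
    was_easy = is_easy(state, v)
    base = state.mu_alpha(v)
    new = state.copy()
    _expand_inplace(new, v, s, assume_no_easy=False)
    grew = new.dhat - state.dhat
    if s is base and not was_easy:
        assert grew == 1, "branching at the candidate base must add one layer"
    else:
        assert grew in (0, 1), "one assignment adds at most one layer"
    return new


# ---------------------------------------------------------------------------
# Search drivers
# ---------------------------------------------------------------------------


def zero_lambda_substitute(costs: CostParams, forest: Forest,
                           species: RootedTree) -> CostParams:
    """Replace a zero loss cost by an epsilon so small that even the maximum
    possible number of losses is cheaper than a single duplication:
    loss_cost' = dup_cost / (2 |V(G)| |V(S)| + 1)."""
    eps = costs.dup_cost / (2 * len(forest) * len(species) + 1)
    return CostParams(costs.dup_cost, eps)


def solve_bounded(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    costs: CostParams,
    d: int,
    *,
    incumbent: float = math.inf,
    mu: Optional[Mapping] = None,
    max_expansions: Optional[int] = None,
    _expansions: Optional[list[int]] = None,
) -> Optional[tuple[ReconSummary, Mapping]]:
    """Minimum-cost completion with duplication-height sum at most d, or None
    when none exists (or none beats the ``incumbent`` cost, when given).

    Requires dup_cost > loss_cost > 0.  Branches are pruned as soon as the
    height budget is exceeded or the admissible bound
    dup_cost * dhat + loss_cost * losses (both monotone along a branch)
    reaches the best cost seen so far.
    """
    if not (costs.dup_cost > costs.loss_cost > 0):
        raise ValueError("bounded search requires dup_cost > loss_cost > 0")
    if d < 0:
        raise ValueError("budget must be non-negative")
    expansions = _expansions if _expansions is not None else [0]

    best_cost = incumbent
    best_map: Optional[Mapping] = None

    root_state = initial_cleanup(forest, species, leafmap, mu=mu)

    def rec(state: PartialState) -> None:
        nonlocal best_cost, best_map
        if state.dhat > d:
            return
        if state.is_complete():
            cost = costs.dup_cost * state.dhat + costs.loss_cost * state.losses
            if cost < best_cost:
                best_cost = cost
                best_map = state.mapping.copy()
            return
        pending = sum(state.min_pending_loss(w) for w in state.bots)
        bound = (costs.dup_cost * state.dhat
                 + costs.loss_cost * (state.losses + pending))
        if bound >= best_cost:
            return
        if max_expansions is not None and expansions[0] >= max_expansions:
            raise ExpansionLimitExceeded(None)
        expansions[0] += 1
        v = lowest_minimal_bot_node(state)
        pending_v = state.min_pending_loss(v)
        for s in candidate_species(state, v, costs):
            # cheap pre-pruning: the easy-node fixpoint after assigning v
            # never raises the height sum further, so the child's dhat and a
            # loss lower bound are known before building the child state
            grow, loss_v = state.assignment_delta(v, s)
            if state.dhat + grow > d:
                continue
            child_bound = (costs.dup_cost * (state.dhat + grow)
                           + costs.loss_cost
                           * (state.losses + loss_v + pending - pending_v))
            if child_bound >= best_cost:
                continue
            trail = _expand_inplace(state, v, s, assume_no_easy=True)
            rec(state)
            _undo_all(state, trail)

    rec(root_state)
    if best_map is None:
        return None
    return cost_sd(best_map, costs), best_map


def solve(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    costs: CostParams,
    budget: int | str = "auto",
    max_expansions: Optional[int] = None,
) -> SolveResult:
    """Minimum-cost reconciliation under the segmental objective.

    For loss_cost >= dup_cost the LCA-mapping is returned directly.
    Otherwise one bounded search is run with the LCA-mapping's height sum as
    budget and its cost as incumbent (unless an explicit integer ``budget``
    is given), which is complete because the optimum never exceeds the
    LCA-mapping's height sum.
    """
    leafmap.validate(forest, species)
    mu = lca_mapping(forest, species, leafmap)
    if costs.dup_cost <= costs.loss_cost:
        summary = cost_sd(mu, costs)
        if isinstance(budget, int) and summary.d_hat > budget:
            raise InfeasibleBudgetError(
                f"LCA-mapping optimum has height sum {summary.d_hat} > budget {budget}"
            )
        return SolveResult(summary, mu, optimal=True, expansions=0,
                           budget_used=summary.d_hat)

    eff = costs if costs.loss_cost > 0 else zero_lambda_substitute(
        costs, forest, species
    )

    mu_summary_eff = cost_sd(mu, eff)
    best_cost = mu_summary_eff.cost_sd
    best_map = mu
    expansions = [0]
    optimal = True

    if isinstance(budget, int):
        try:
            res = solve_bounded(
                forest, species, leafmap, eff, budget,
                mu=mu, max_expansions=max_expansions, _expansions=expansions,
            )
        except ExpansionLimitExceeded:
            res = None
            optimal = False
        if res is not None:
            best_map = res[1]
        elif mu_summary_eff.d_hat > budget and optimal:
            raise InfeasibleBudgetError(
                f"no reconciliation with duplication-height sum <= {budget}"
            )
        budget_used = budget
    else:
        # The optimum never needs a duplication-height sum above the
        # LCA-mapping's: the LCA-mapping minimises losses (repeated
        # shift-downs turn any mapping into it without adding losses), so a
        # higher height sum can only cost more.  One bound-pruned search with
        # that budget and the LCA-mapping cost as incumbent is therefore
        # complete, and avoids re-paying the search at every smaller budget.
        budget_used = mu_summary_eff.d_hat
        try:
            res = solve_bounded(
                forest, species, leafmap, eff, mu_summary_eff.d_hat,
                incumbent=best_cost, mu=mu,
                max_expansions=max_expansions, _expansions=expansions,
            )
            if res is not None and res[0].cost_sd < best_cost:
                best_cost = res[0].cost_sd
                best_map = res[1]
        except ExpansionLimitExceeded:
            optimal = False

    summary = cost_sd(best_map, costs)  # true costs (loss cost may be 0)
    return SolveResult(summary, best_map, optimal=optimal,
                       expansions=expansions[0], budget_used=budget_used)
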