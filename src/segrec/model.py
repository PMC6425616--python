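"""Duplication–loss reconciliation with segmental duplication counting.

A reconciliation maps every node of a gene forest G into a species tree S.
Leaves are anchored by the gene→species assignment; an internal node u with
children u1, u2 is a *speciation* (S) when its image is the LCA of its
children's images and those images are incomparable, and a *duplication* (D)
otherwise (speciations are preferred whenever allowed — this makes the event
labels a function of the node-to-species map alone).  Losses are charged per
branch: a speciation pays dist(a(u),a(u1)) + dist(a(u),a(u2)) - 2, a
duplication the same without the -2.

The segmental objective charges co-mapped duplications once per "layer":
for each species s, the duplications mapped to s form a sub-poset of the gene
forest, and the minimum number of simultaneous (segmental) events needed to
explain them is the height of that poset — equivalently the minimum number of
antichains partitioning it.  d_hat = sum over species of these heights, and

    cost_SD = dup_cost * d_hat + loss_cost * losses.

Mappings may be *partial*: undetermined nodes carry None, and determinedness
is downward-closed (every ancestor of an undetermined node is undetermined).
Losses and heights of a partial mapping are computed over the determined part.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .trees import Forest, Node, RootedTree

SPECIATION = "S"
DUPLICATION = "D"
CONTEMPORARY = "C"


class InvalidMappingError(ValueError):
    """A mapping violating ancestor-consistency or leaf anchoring."""


@dataclass(frozen=True)
class CostParams:
    """Event costs: ``dup_cost`` (delta) per segmental duplication,
    ``loss_cost`` (lambda) per loss."""

    dup_cost: float
    loss_cost: float

    def __post_init__(self):
        if self.dup_cost <= 0:
            raise ValueError("duplication cost must be positive")
        if self.loss_cost < 0:
            raise ValueError("loss cost must be non-negative")


class LeafMap:
    """Total assignment of gene-forest leaves to species-tree leaves.

    Stored label-to-label; need not be injective (several genes of one family
    in one species) nor surjective (species without sampled genes).
    """

    def __init__(self, mapping: dict[str, str]):
        self.by_label = dict(mapping)

    @classmethod
    def from_tsv(cls, text: str) -> "LeafMap":
        """Two-column whitespace/TSV format: ``gene_leaf  species_leaf``."""
        mapping: dict[str, str] = {}
        for i, ln in enumerate(text.splitlines(), start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"leaf map line {i}: expected 2 columns, got {len(parts)}")
            gene, sp = parts
            if gene in mapping and mapping[gene] != sp:
                raise ValueError(f"leaf map line {i}: conflicting entries for {gene!r}")
            mapping[gene] = sp
        if not mapping:
            raise ValueError("empty leaf map")
        return cls(mapping)

    @classmethod
    def from_label_convention(cls, forest: Forest, sep: str = "__") -> "LeafMap":
        """Fallback convention: gene leaves labeled ``SPECIES__geneid``."""
        mapping = {}
        for leaf in forest.leaves:
            if sep not in leaf.label:
                raise ValueError(
                    f"gene leaf {leaf.label!r} does not follow the "
                    f"SPECIES{sep}geneid convention and no leaf-map file was given"
                )
            mapping[leaf.label] = leaf.label.split(sep, 1)[0]
        return cls(mapping)

    def to_tsv(self) -> str:
        return "".join(f"{g}\t{s}\n" for g, s in sorted(self.by_label.items()))

    def species_of(self, gene_label: str) -> str:
        return self.by_label[gene_label]

    def validate(self, forest: Forest, species: RootedTree) -> None:
        sp_leaves = {l.label for l in species.leaves}
        for leaf in forest.leaves:
            if leaf.label not in self.by_label:
                raise InvalidMappingError(
                    f"gene leaf {leaf.label!r} has no species assignment"
                )
            target = self.by_label[leaf.label]
            if target not in sp_leaves:
                raise InvalidMappingError(
                    f"gene leaf {leaf.label!r} maps to unknown species {target!r}"
                )


class Mapping:
    """A (possibly partial) assignment of gene-forest nodes to species nodes.

    ``image[v]`` is a species :class:`Node` or ``None`` (undetermined).
    Event labels are derived, never stored: speciation whenever allowed.
    """

    def __init__(self, forest: Forest, species: RootedTree, leafmap: LeafMap,
                 image: Optional[dict[Node, Optional[Node]]] = None):
        self.forest = forest
        self.species = species
        self.leafmap = leafmap
        if image is None:
            image = {}
            for v in forest.nodes:
                if v.is_leaf:
                    image[v] = species.node_by_name(leafmap.species_of(v.label))
                else:
                    image[v] = None
        self.image = image

    # -- basics ------------------------------------------------------------

    def copy(self) -> "Mapping":
        return Mapping(self.forest, self.species, self.leafmap, dict(self.image))

    def __getitem__(self, v: Node) -> Optional[Node]:
        return self.image[v]

    def is_determined(self, v: Node) -> bool:
        return self.image[v] is not None

    def is_complete(self) -> bool:
        return all(s is not None for s in self.image.values())

    def remap(self, v: Node, s: Node) -> "Mapping":
        """Return a copy with v (re)mapped to s (alpha[v -> s] in the usual
        reconciliation notation)."""
        new = self.copy()
        new.image[v] = s
        return new

    def determined_internal(self) -> Iterable[Node]:
        for v in self.forest.nodes:
            if not v.is_leaf and self.image[v] is not None:
                yield v

    def minimal_bot_nodes(self) -> list[Node]:
        """Undetermined nodes whose children are both determined."""
        out = []
        for v in self.forest.nodes:
            if v.is_leaf or self.image[v] is not None:
                continue
            if all(self.image[c] is not None for c in v.children):
                out.append(v)
        return out

    # -- events ------------------------------------------------------------

    def event(self, v: Node) -> str:
        """Derived event of a determined node whose children are determined."""
        if v.is_leaf:
            return CONTEMPORARY
        a = self.image[v]
        if a is None:
            raise InvalidMappingError(f"node {v.canonical_name} is undetermined")
        a1, a2 = (self.image[c] for c in v.children)
        if a1 is None or a2 is None:
            raise InvalidMappingError(
                f"a child of {v.canonical_name} is undetermined"
            )
        S = self.species
        if not S.comparable(a1, a2) and a is S.lca(a1, a2):
            return SPECIATION
        return DUPLICATION

    def duplication_nodes(self) -> list[Node]:
        return [v for v in self.determined_internal() if self.event(v) == DUPLICATION]

    def to_tsv(self) -> str:
        """Per-node TSV: canonical gene-node name, species name, event."""
        rows = []
        for v in self.forest.postorder():
            if self.image[v] is None:
                continue
            ev = self.event(v)
            rows.append(f"{v.canonical_name}\t{self.image[v].display_name}\t{ev}")
        return "\n".join(rows) + "\n"


@dataclass
class ReconSummary:
    """Scores of a reconciliation: per-species duplication-forest heights,
    their sum d_hat, the plain duplication-node count, losses, and cost."""

    h_per_species: dict[Node, int]
    d_hat: int
    d_plain: int
    losses: int
    cost_sd: float

    def heights_by_name(self) -> dict[str, int]:
        return {s.display_name: h for s, h in self.h_per_species.items() if h > 0}

    def to_tsv(self) -> str:
        lines = ["species\tdup_height"]
        for s in sorted(self.h_per_species, key=lambda n: n.tin):
            h = self.h_per_species[s]
            if h:
                lines.append(f"{s.display_name}\t{h}")
        lines.append(f"#total_d_hat\t{self.d_hat}")
        lines.append(f"#dup_nodes\t{self.d_plain}")
        lines.append(f"#losses\t{self.losses}")
        lines.append(f"#cost_sd\t{self.cost_sd:g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def lca_mapping(forest: Forest, species: RootedTree, leafmap: LeafMap) -> Mapping:
    """The LCA-mapping mu: leaves to their species, internal nodes to the LCA
    of their children's images.  mu is the pointwise-lowest valid mapping."""
    leafmap.validate(forest, species)
    m = Mapping(forest, species, leafmap)
    for v in forest.postorder():
        if v.is_leaf:
            continue
        a1, a2 = (m.image[c] for c in v.children)
        m.image[v] = species.lca(a1, a2)
    return m


def classify_event(mapping: Mapping, v: Node) -> str:
    """Event of node v under the speciation-whenever-allowed convention."""
    return mapping.event(v)


def count_losses(mapping: Mapping) -> int:
    """Total losses over the determined part of the mapping."""
    S = mapping.species
    total = 0
    for v in mapping.determined_internal():
        a = mapping.image[v]
        d = 0
        for c in v.children:
            ac = mapping.image[c]
            if ac is None:
                raise InvalidMappingError(
                    f"determined node {v.canonical_name} has an undetermined child"
                )
            if not S.is_ancestor_or_equal(a, ac):
                raise InvalidMappingError(
                    f"child of {v.canonical_name} is mapped above its parent's image"
                )
            d += S.dist(a, ac)
        if mapping.event(v) == SPECIATION:
            d -= 2
        total += d
    return total


def _poset_height(nodes: list[Node]) -> int:
    """Height (longest chain, counted in nodes) of a set of gene nodes under
    forest ancestry.  Equals the minimum antichain partition size (Mirsky)."""
    if not nodes:
        return 0
    nodes = sorted(nodes, key=lambda n: n.depth)
    best: dict[Node, int] = {}
    out = 0
    for v in nodes:
        t = v.tree
        h = 1
        for u, hu in best.items():
            if u.tree is t and u is not v and t.is_ancestor_or_equal(u, v):
                h = max(h, hu + 1)
        best[v] = h
        out = max(out, h)
    return out


def dup_heights(mapping: Mapping) -> dict[Node, int]:
    """Per-species height of the forest induced by co-mapped duplications.

    Species with no duplications are reported with height 0.
    """
    by_species: dict[Node, list[Node]] = {s: [] for s in mapping.species.nodes}
    for v in mapping.duplication_nodes():
        by_species[mapping.image[v]].append(v)
    return {s: _poset_height(d) for s, d in by_species.items()}


def cost_sd(mapping: Mapping, costs: CostParams) -> ReconSummary:
    """Score a mapping under the segmental objective."""
    h = dup_heights(mapping)
    d_hat = sum(h.values())
    d_plain = len(mapping.duplication_nodes())
    losses = count_losses(mapping)
    return ReconSummary(
        h_per_species=h,
        d_hat=d_hat,
        d_plain=d_plain,
        losses=losses,
        cost_sd=costs.dup_cost * d_hat + costs.loss_cost * losses,
    )


def mapping_from_assignment(
    forest: Forest,
    species: RootedTree,
    leafmap: LeafMap,
    overrides: dict[str, str],
) -> Mapping:
    """Build a complete mapping from per-node species assignments.

    ``overrides`` maps gene-node names (canonical leaf-set names, ``|``-joined
    sorted leaf labels) to species-node names (explicit internal label or
    canonical name).  Nodes absent from ``overrides`` default to their
    LCA-mapping image.  The result is validated; an inconsistent assignment
    raises :class:`InvalidMappingError`.
    """
    m = lca_mapping(forest, species, leafmap)
    by_name = {v.canonical_name: v for v in forest.nodes if not v.is_leaf}
    for name, sp_name in overrides.items():
        if name not in by_name:
            raise KeyError(f"no internal gene node named {name!r}")
        m.image[by_name[name]] = species.node_by_name(sp_name)
    problem = validate_mapping(m)
    if problem:
        raise InvalidMappingError(problem)
    return m


def validate_mapping(mapping: Mapping) -> Optional[str]:
    """Diagnostic check of the mapping invariants.

    Returns None when the mapping is well-formed, else a message naming the
    first offending node.  Checks: leaf anchoring, the partial-mapping
    property (determinedness is downward-closed), and ancestor-consistency
    (every determined node's image dominates its determined descendants').
    """
    S = mapping.species
    for v in mapping.forest.postorder():
        img = mapping.image[v]
        if v.is_leaf:
            want = S.node_by_name(mapping.leafmap.species_of(v.label))
            if img is not want:
                return f"leaf {v.label} is not anchored to its species"
            continue
        child_imgs = [mapping.image[c] for c in v.children]
        if img is None:
            continue
        for c, ci in zip(v.children, child_imgs):
            if ci is None:
                return (
                    f"node {v.canonical_name} is determined but its child "
                    f"{c.canonical_name} is not (partial-mapping property)"
                )
            if not S.is_ancestor_or_equal(img, ci):
                return (
                    f"child {c.canonical_name} is mapped above the image of "
                    f"{v.canonical_name}"
                )
    return None
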