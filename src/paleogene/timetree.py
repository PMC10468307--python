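"""Dated species trees: reading, grafting, and clade enumeration.

A timetree is a rooted ultrametric phylogeny whose node heights are divergence
times in millions of years ago (MYA).  Leaves sit at age 0 and every internal
node is strictly older than its children.  Nodes may carry a taxonomic label
(e.g. a subfamily name such as *Colobinae*) and an optional 95% confidence
range on their age; every node defines one clade, the set of extant taxa
descending from it.

Newick input is parsed with dendropy; branch lengths are interpreted as
durations in MY and node ages are recovered as root-to-tip path sums.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "TreeNode",
    "TimeTree",
    "Clade",
    "read_timetree",
    "read_age_ranges",
    "graft_leaf",
    "prune_leaf",
    "enumerate_clades",
]

#: default tolerance (MY) on the spread of tip ages when validating
#: ultrametricity of newick input
DEFAULT_ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or non-ultrametric tree input."""


@dataclass
class TreeNode:
    """One node of a :class:`TimeTree`.

    ``name`` is the leaf taxon name for tips and the taxonomic label (if any)
    for internal nodes.  ``age`` is in MYA; ``age_range`` is an optional
    (min, max) confidence range bracketing ``age``.
    """

    id: int
    name: str | None
    age: float
    age_range: tuple[float, float] | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])  # type: ignore[list-item]
        out: set[str] = set()
        for child in self.children:
            out |= child.leaf_names()
        return frozenset(out)


@dataclass
class TimeTree:
    """A rooted ultrametric dated tree."""

    root: TreeNode

    def __post_init__(self) -> None:
        self.validate()

    # -- traversal -----------------------------------------------------------

    def nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())

    def node_by_name(self, name: str) -> TreeNode:
        for node in self.nodes():
            if node.name == name:
                return node
        raise KeyError(f"no node named {name!r} in tree")

    def mrca(self, names: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the given leaf taxa."""
        want = set(names)
        missing = want - set(self.leaf_names())
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        best: TreeNode | None = None
        for node in self.nodes():
            if want <= node.leaf_names():
                if best is None or node.age < best.age:
                    best = node
        assert best is not None
        return best

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf taxon names: {dupes}")
        for node in self.nodes():
            if node.is_leaf:
                if node.age != 0.0:
                    raise TreeError(
                        f"leaf {node.name!r} has age {node.age}, expected 0"
                    )
            else:
                for child in node.children:
                    if not node.age > child.age:
                        raise TreeError(
                            f"node {node.id} (age {node.age}) not strictly older "
                            f"than child {child.id} (age {child.age})"
                        )
            if node.age_range is not None:
                lo, hi = node.age_range
                if not lo <= node.age <= hi:
                    raise TreeError(
                        f"node {node.id}: age {node.age} outside its stated "
                        f"range ({lo}, {hi})"
                    )

    # -- serialization -------------------------------------------------------

    def write_newick(self) -> str:
        """Newick with branch lengths in MY and internal labels preserved."""

        def fmt(node: TreeNode, parent_age: float | None) -> str:
            label = node.name or ""
            if node.is_leaf:
                body = label
            else:
                inner = ",".join(fmt(c, node.age) for c in node.children)
                body = f"({inner}){label}"
            if parent_age is None:
                return body
            return f"{body}:{parent_age - node.age:.12g}"

        return fmt(self.root, None) + ";"

    def copy(self) -> "TimeTree":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class Clade:
    """The set of extant taxa descending from one tree node."""

    node_id: int
    leaves: frozenset[str]
    age: float
    name: str | None = None

    @property
    def size(self) -> int:
        return len(self.leaves)

    @property
    def order_key(self) -> tuple[float, str]:
        # decreasing age, ties by lexicographically smallest member name
        return (-self.age, min(self.leaves))


# ---------------------------------------------------------------------------


def read_timetree(
    newick_text: str,
    *,
    age_ranges: Mapping[str, tuple[float, float]] | None = None,
    ultrametric_tol: float = DEFAULT_ULTRAMETRIC_TOL,
) -> TimeTree:
    """Parse a newick timetree with branch lengths in MY.

    Node ages are computed from root-to-tip path sums, with tips forced to
    age 0.  Input whose tip depths spread by more than ``ultrametric_tol`` MY
    is rejected.  ``age_ranges`` optionally maps node labels (leaf taxon name,
    internal label, or ``"taxon1,taxon2"`` designating the MRCA of two leaves)
    to (min, max) MYA confidence ranges.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from None

    # depth of each dendropy node from the root
    depth: dict[int, float] = {id(dtree.seed_node): 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is dtree.seed_node:
            continue
        length = dnode.edge.length
        if length is None:
            raise TreeError(
                f"branch leading to {_dnode_label(dnode)!r} has no length"
            )
        depth[id(dnode)] = depth[id(dnode.parent_node)] + float(length)

    tip_depths = [depth[id(n)] for n in dtree.leaf_node_iter()]
    if not tip_depths:
        raise TreeError("tree has no leaves")
    root_age = max(tip_depths)
    if max(tip_depths) - min(tip_depths) > ultrametric_tol:
        raise TreeError(
            "tree is not ultrametric: tip depths spread by "
            f"{max(tip_depths) - min(tip_depths):.3g} MY "
            f"(tolerance {ultrametric_tol:g})"
        )

    counter = iter(range(10**9))

    def build(dnode, parent: TreeNode | None) -> TreeNode:
        if dnode.is_leaf():
            age = 0.0
            name = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            age = root_age - depth[id(dnode)]
            name = dnode.label
        node = TreeNode(id=next(counter), name=name, age=age, parent=parent)
        node.children = [build(c, node) for c in dnode.child_nodes()]
        return node

    tree = TimeTree(root=build(dtree.seed_node, None))
    if age_ranges:
        attach_age_ranges(tree, age_ranges)
    return tree


def _dnode_label(dnode) -> str:
    if dnode.taxon is not None:
        return dnode.taxon.label
    return dnode.label or "<unnamed>"


def attach_age_ranges(
    tree: TimeTree, ranges: Mapping[str, tuple[float, float]]
) -> None:
    """Attach (min, max) MYA ranges to nodes, in place.

    Keys are node labels; a key of the form ``"taxonA,taxonB"`` resolves to
    the MRCA of the two leaves.  Unresolvable keys raise ``KeyError``.
    """
    for key, (lo, hi) in ranges.items():
        if "," in key:
            node = tree.mrca([t.strip() for t in key.split(",")])
        else:
            node = tree.node_by_name(key)
        node.age_range = (float(lo), float(hi))
    tree.validate()


def read_age_ranges(path) -> dict[str, tuple[float, float]]:
    """Read a sidecar TSV of node age ranges: node_label, min_mya, max_mya."""
    out: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "node_label":  # header
                continue
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out


def graft_leaf(
    tree: TimeTree,
    new_taxon: str,
    sister_taxon: str,
    age: float,
    age_range: tuple[float, float] | None = None,
) -> TimeTree:
    """Attach ``new_taxon`` as sister of an existing leaf at the given age.

    Returns a new tree with one extra internal node (the MRCA of the pair) at
    ``age`` MYA; all pre-existing node ages are unchanged.  This is how a
    species absent from the main divergence-time source is integrated from a
    separately published split time.
    """
    if new_taxon in tree.leaf_names():
        raise TreeError(f"taxon {new_taxon!r} already present in tree")
    out = tree.copy()
    sister = out.node_by_name(sister_taxon)
    if not sister.is_leaf:
        raise TreeError(f"sister taxon {sister_taxon!r} is not a leaf")
    parent = sister.parent
    if parent is None:
        raise TreeError("cannot graft onto a single-leaf tree")
    if not 0.0 < age < parent.age:
        raise TreeError(
            f"graft age {age} must lie strictly between 0 and the sister's "
            f"parent age {parent.age}"
        )
    max_id = max(n.id for n in out.nodes())
    new_leaf = TreeNode(id=max_id + 1, name=new_taxon, age=0.0)
    joint = TreeNode(
        id=max_id + 2,
        name=None,
        age=float(age),
        age_range=age_range,
        parent=parent,
        children=[sister, new_leaf],
    )
    sister.parent = joint
    new_leaf.parent = joint
    parent.children[parent.children.index(sister)] = joint
    out.validate()
    return out


def prune_leaf(tree: TimeTree, taxon: str) -> TimeTree:
    """Remove a leaf and collapse its now-unary parent."""
    out = tree.copy()
    leaf = out.node_by_name(taxon)
    if not leaf.is_leaf:
        raise TreeError(f"{taxon!r} is not a leaf")
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot prune the only node of a tree")
    parent.children.remove(leaf)
    if len(parent.children) == 1:
        only = parent.children[0]
        grand = parent.parent
        only.parent = grand
        if grand is None:
            out.root = only
        else:
            grand.children[grand.children.index(parent)] = only
    out.validate()
    return out


def enumerate_clades(tree: TimeTree) -> list[Clade]:
    """One clade per node (leaves as singletons), ordered oldest first.

    Ties in age are broken by the lexicographically smallest member taxon, so
    the ordering — and every downstream tie-break keyed on it — is
    deterministic.
    """
    clades = [
        Clade(
            node_id=node.id,
            leaves=node.leaf_names(),
            age=node.age,
            name=node.name if not node.is_leaf else node.name,
        )
        for node in tree.nodes()
    ]
    clades.sort(key=lambda c: c.order_key)
    return clades
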