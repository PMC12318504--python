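"""Phylogenetic tree container and bipartition utilities.

Trees are stored rooted (every node knows its children); "unrooted" semantics
are recovered through :meth:`PhyloTree.bipartitions`, which ignores the root
placement.  Ages, when present, are in Ma and increase toward the root.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional, Sequence


class Node:
    """A tree node. Leaves carry a label; internal nodes may be unlabelled."""

    __slots__ = ("label", "children", "parent", "length", "age", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
    ) -> None:
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.age: Optional[float] = None
        self.support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class TreeError(ValueError):
    pass


class PhyloTree:
    """A (rooted representation of a) phylogenetic tree over labelled leaves."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaf_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        labels = [n.label for n in self.leaf_nodes()]
        if any(l is None for l in labels):
            raise TreeError("tree contains an unlabelled leaf")
        return labels  # type: ignore[return-value]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_nodes())

    # ------------------------------------------------------------------ #
    # structure checks
    # ------------------------------------------------------------------ #
    def is_binary_rooted(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def is_binary_unrooted(self) -> bool:
        """True if, read as unrooted, every internal vertex has degree 3."""
        for node in self.postorder():
            if node.is_leaf:
                continue
            degree = len(node.children) + (0 if node is self.root else 1)
            if node is self.root:
                if degree not in (2, 3):
                    return False
            elif degree != 3:
                return False
        return True

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.age = node.age
            new.support = node.support
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return PhyloTree(_copy(self.root))

    # ------------------------------------------------------------------ #
    # bipartitions
    # ------------------------------------------------------------------ #
    def bipartitions(self, taxa: Optional[Sequence[str]] = None) -> frozenset[int]:
        """Non-trivial unrooted splits as canonical bitmasks.

        Each split is encoded over ``taxa`` (default: sorted leaf labels) as
        the bitmask of the side NOT containing ``taxa[0]``.  Trivial splits
        (a single leaf versus the rest) are excluded, as is the root split
        duplication of a rooted representation.
        """
        if taxa is None:
            taxa = sorted(self.leaf_labels())
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        full = (1 << n) - 1
        masks: dict[int, int] = {}
        splits: set[int] = set()
        for node in self.postorder():
            if node.is_leaf:
                if node.label not in index:
                    raise TreeError(f"leaf {node.label!r} not in taxon set")
                masks[id(node)] = 1 << index[node.label]
            else:
                m = 0
                for child in node.children:
                    m |= masks[id(child)]
                masks[id(node)] = m
                if node is self.root:
                    continue
                canon = (full ^ m) if (m & 1) else m
                pc = canon.bit_count()
                if 2 <= pc <= n - 2:
                    splits.add(canon)
        return frozenset(splits)

    def topology_key(self, taxa: Optional[Sequence[str]] = None) -> frozenset[int]:
        """Hashable identity of the unrooted topology over a fixed taxon order."""
        return self.bipartitions(taxa)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree with {self.n_leaves} leaves>"


def split_to_labels(mask: int, taxa: Sequence[str]) -> frozenset[str]:
    """Decode a bipartition bitmask to the frozenset of labels on its side."""
    return frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)


def tree_from_splits(
    splits: dict[int, float],
    taxa: Sequence[str],
) -> PhyloTree:
    """Build a (possibly multifurcating) rooted tree from compatible splits.

    ``splits`` maps canonical bipartition masks (side not containing
    ``taxa[0]``) to a support value stored on the created node.  The tree is
    rooted on ``taxa[0]``'s side; incompatible splits raise ``TreeError``.
    """
    n = len(taxa)
    for a, b in itertools.combinations(splits, 2):
        if a & b and (a | b) != a and (a | b) != b:
            raise TreeError("incompatible splits supplied")
    root = Node()
    leaf_nodes = [Node(t) for t in taxa]
    # clade mask for each node; nest larger clades first
    node_for_mask: dict[int, Node] = {}
    for mask in sorted(splits, key=lambda m: -m.bit_count()):
        node = Node()
        node.support = splits[mask]
        node_for_mask[mask] = node
        # attach under the smallest strictly containing clade, else root
        parent = root
        best = None
        for other, other_node in node_for_mask.items():
            if other != mask and (mask & other) == mask:
                if best is None or other.bit_count() < best:
                    best, parent = other.bit_count(), other_node
        parent.add_child(node)
    for i, leaf in enumerate(leaf_nodes):
        bit = 1 << i
        parent = root
        best = None
        for mask, node in node_for_mask.items():
            if mask & bit:
                if best is None or mask.bit_count() < best:
                    best, parent = mask.bit_count(), node
        parent.add_child(leaf)
    return PhyloTree(root)


def random_binary_tree(labels: Sequence[str], rng) -> PhyloTree:
    """Uniform-ish random unrooted binary tree via random sequential addition."""
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need at least 3 labels")
    order = list(labels)
    rng.shuffle(order)
    root = Node()
    for lab in order[:3]:
        root.add_child(Node(lab))
    tree = PhyloTree(root)
    for lab in order[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        assert parent is not None
        new = Node()
        parent.children[parent.children.index(target)] = new
        new.parent = parent
        new.add_child(target)
        new.add_child(Node(lab))
    return tree


def enumerate_unrooted_topologies(labels: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on ``labels`` (3 -> 1, ..., 7 -> 945).

    Generated by recursive leaf insertion into every edge; used as the
    exhaustive-search oracle for small problems.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise TreeError("need at least 3 labels")

    def _grow(tree: PhyloTree, remaining: list[str]) -> Iterator[PhyloTree]:
        if not remaining:
            yield tree
            return
        lab, rest = remaining[0], remaining[1:]
        edges = [n for n in tree.postorder() if n is not tree.root]
        for i in range(len(edges)):
            t2 = tree.copy()
            edges2 = [n for n in t2.postorder() if n is not t2.root]
            target = edges2[i]
            parent = target.parent
            assert parent is not None
            new = Node()
            parent.children[parent.children.index(target)] = new
            new.parent = parent
            new.add_child(target)
            new.add_child(Node(lab))
            yield from _grow(t2, rest)

    base = Node()
    for lab in labels[:3]:
        base.add_child(Node(lab))
    yield from _grow(PhyloTree(base), labels[3:])
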