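"""Bipartition tallies and majority-rule consensus over a tree set."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .trees import PhyloTree, TreeError, tree_from_splits


class ConsensusError(ValueError):
    pass


@dataclass
class BipartitionTally:
    """Occurrence counts of non-trivial splits over a tree set."""

    taxa: list[str]
    counts: dict[int, int]
    n_trees: int

    def frequencies(self) -> dict[int, float]:
        return {m: c / self.n_trees for m, c in self.counts.items()}


def tally_bipartitions(trees: Sequence[PhyloTree]) -> BipartitionTally:
    trees = list(trees)
    if not trees:
        raise ConsensusError("empty tree set")
    taxa = sorted(trees[0].leaf_labels())
    leafset = frozenset(taxa)
    counts: dict[int, int] = {}
    for i, tree in enumerate(trees):
        if frozenset(tree.leaf_labels()) != leafset:
            raise ConsensusError(
                f"tree {i} has a different leaf set than tree 0"
            )
        for mask in tree.bipartitions(taxa):
            counts[mask] = counts.get(mask, 0) + 1
    return BipartitionTally(taxa=taxa, counts=counts, n_trees=len(trees))


def majority_rule(
    trees: Sequence[PhyloTree],
    cutoff: float = 0.5,
    strict_cutoff: bool = True,
) -> PhyloTree:
    """Majority-rule consensus: splits in more than ``cutoff`` of the trees.

    Retained clades carry their percentage on ``node.support``; everything
    else collapses into polytomies.  Splits at exactly the cutoff are
    excluded by default (strict majority); ``strict_cutoff=False`` includes
    them (only safe for ``cutoff > 0.5``).
    """
    if not (0.5 <= cutoff <= 1.0):
        raise ConsensusError("cutoff must be in [0.5, 1]")
    tally = tally_bipartitions(trees)
    keep: dict[int, float] = {}
    for mask, count in tally.counts.items():
        frac = count / tally.n_trees
        if frac > cutoff or (not strict_cutoff and frac == cutoff):
            keep[mask] = 100.0 * frac
    try:
        tree = tree_from_splits(keep, tally.taxa)
    except TreeError as exc:  # pragma: no cover - cutoff >= 0.5 guarantees compat
        raise ConsensusError(str(exc)) from exc
    return tree


def root_on_outgroup(tree: PhyloTree, outgroup: Sequence[str]) -> PhyloTree:
    """Reroot (for display) so that ``outgroup`` attaches at the root.

    The tree must already display outgroup | ingroup as a split at the root
    level or within one rotation; otherwise the tree is returned unchanged
    with its original rooting.
    """
    out = set(outgroup)
    tree = tree.copy()
    # find a maximal clade equal to the outgroup or the ingroup complement
    labels = set(tree.leaf_labels())
    if not out < labels:
        raise ConsensusError("outgroup is not a proper subset of the leaves")
    for node in tree.postorder():
        if node is tree.root:
            continue
        clade = {l.label for l in _clade_leaves(node)}
        if clade == labels - out:
            new_root = type(node)()
            parent = node.parent
            assert parent is not None
            parent.children.remove(node)
            node.parent = None
            # gather everything else under one outgroup node
            rest = tree.root
            new_root.add_child(rest)
            new_root.add_child(node)
            return PhyloTree(new_root)
    return tree


def _clade_leaves(node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)
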