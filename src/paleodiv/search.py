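"""Heuristic maximum-parsimony search: stepwise addition + TBR, and bootstrap.

The search keeps every distinct shortest tree ("swap on all" discipline):
each tree in the current optimal set is TBR-swapped until the set is closed
under equally-long neighbors or a shorter tree restarts the process.  MPT
counting applies a PAUP-like collapse rule: branches whose minimum optimized
length is zero are collapsed before deduplication (``collapse="ambzero"``,
the default; ``"none"`` keeps binary resolutions).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .parsimony import fitch_length
from .trees import Node, PhyloTree

logger = logging.getLogger(__name__)

Adjacency = dict[int, list[int]]


class SearchError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# adjacency-level machinery (leaves 0..n-1 = sorted taxon labels)
# ---------------------------------------------------------------------- #
def _score_adj(
    adj: Adjacency,
    n: int,
    leaf_masks: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Fitch length of an unrooted binary adjacency; exact (see parsimony)."""
    steps = np.zeros(leaf_masks.shape[1], dtype=np.int64)
    leaves = [u for u in adj if u < n]
    if len(leaves) == 2:
        inter = leaf_masks[leaves[0]] & leaf_masks[leaves[1]]
        return float(weights @ (inter == 0))
    start_leaf = min(leaves)
    root = adj[start_leaf][0]  # internal neighbor of the anchor leaf
    stack = [(root, start_leaf, False)]
    mask_of: dict[int, np.ndarray] = {}
    while stack:
        node, parent, expanded = stack.pop()
        if node < n:
            mask_of[node] = leaf_masks[node]
            continue
        if not expanded:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
            continue
        kids = [nb for nb in adj[node] if nb != parent]
        acc = mask_of.pop(kids[0])
        for c in kids[1:]:
            cm = mask_of.pop(c)
            inter = acc & cm
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | cm, inter)
        mask_of[node] = acc
    # combine the root vertex with the anchor leaf (rooting on that edge)
    inter = mask_of[root] & leaf_masks[start_leaf]
    steps += inter == 0
    return float(weights @ steps)


def _adj_splits(adj: Adjacency, n: int) -> frozenset[int]:
    """Canonical non-trivial bipartition masks of an unrooted adjacency."""
    full = (1 << n) - 1
    splits: set[int] = set()
    root = adj[0][0]
    stack = [(root, 0, False)]
    mask_of: dict[int, int] = {}
    while stack:
        node, parent, expanded = stack.pop()
        if node < n:
            mask_of[node] = 1 << node
            continue
        if not expanded:
            stack.append((node, parent, True))
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, False))
            continue
        m = 0
        for nb in adj[node]:
            if nb != parent:
                m |= mask_of[nb]
        mask_of[node] = m
        canon = (full ^ m) if (m & 1) else m
        if 2 <= canon.bit_count() <= n - 2:
            splits.add(canon)
    return frozenset(splits)


def _edges(adj: Adjacency) -> list[tuple[int, int]]:
    return sorted(
        (min(u, v), max(u, v)) for u in adj for v in adj[u] if u < v
    )


def _copy_adj(adj: Adjacency) -> Adjacency:
    return {u: list(vs) for u, vs in adj.items()}


def _remove_edge(adj: Adjacency, u: int, v: int) -> None:
    adj[u].remove(v)
    adj[v].remove(u)


def _add_edge(adj: Adjacency, u: int, v: int) -> None:
    adj.setdefault(u, []).append(v)
    adj.setdefault(v, []).append(u)


def _suppress_degree2(adj: Adjacency, v: int) -> None:
    if v in adj and len(adj[v]) == 2:
        a, b = adj[v]
        _remove_edge(adj, v, a)
        _remove_edge(adj, v, b)
        del adj[v]
        _add_edge(adj, a, b)


def _component(adj: Adjacency, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def _attach_leaf(adj: Adjacency, edge: tuple[int, int], leaf: int, new_id: int) -> None:
    u, v = edge
    _remove_edge(adj, u, v)
    _add_edge(adj, u, new_id)
    _add_edge(adj, new_id, v)
    _add_edge(adj, new_id, leaf)


def adjacency_to_tree(adj: Adjacency, n: int, taxa: Sequence[str]) -> PhyloTree:
    """Convert an unrooted adjacency to a rooted PhyloTree representation."""
    if n == 1:
        return PhyloTree(Node(taxa[0]))
    if n == 2:
        r = Node()
        r.add_child(Node(taxa[0]))
        r.add_child(Node(taxa[1]))
        return PhyloTree(r)
    root_id = adj[0][0]

    def build(node_id: int, parent_id: int) -> Node:
        if node_id < n:
            return Node(taxa[node_id])
        node = Node()
        for nb in adj[node_id]:
            if nb != parent_id:
                node.add_child(build(nb, node_id))
        return node

    root = Node()
    root.add_child(Node(taxa[0]))
    for nb in adj[root_id]:
        if nb != 0:
            root.add_child(build(nb, root_id))
    return PhyloTree(root)


def tree_to_adjacency(tree: PhyloTree, taxa: Sequence[str]) -> Adjacency:
    """Convert a PhyloTree to an unrooted adjacency over leaf ids 0..n-1."""
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    next_id = n
    adj: Adjacency = {}
    ids: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in index:
                raise SearchError(f"leaf {node.label!r} not in taxon set")
            ids[id(node)] = index[node.label]
        else:
            ids[id(node)] = next_id
            next_id += 1
        adj.setdefault(ids[id(node)], [])
        for child in node.children:
            _add_edge(adj, ids[id(node)], ids[id(child)])
    _suppress_degree2(adj, ids[id(tree.root)])
    return adj


# ---------------------------------------------------------------------- #
# stepwise addition
# ---------------------------------------------------------------------- #
def stepwise_addition(
    matrix: CharacterMatrix,
    order: str = "simple",
    rng: Optional[np.random.Generator] = None,
) -> PhyloTree:
    """Build a starting tree by sequential leaf insertion at the best edge.

    ``order="simple"`` adds taxa in input-file order; ``order="random"``
    shuffles the addition sequence (requires ``rng``).  Ties are broken by
    the first-encountered attachment in a sorted edge traversal.
    """
    if matrix.n_taxa < 3:
        raise SearchError("stepwise addition needs at least 3 taxa")
    taxa = sorted(matrix.taxa)
    rank = {t: i for i, t in enumerate(taxa)}
    masks_rows, _ = matrix.state_masks()
    leaf_masks = np.empty_like(masks_rows)
    for row, t in enumerate(matrix.taxa):
        leaf_masks[rank[t]] = masks_rows[row]
    assert matrix.weights is not None
    weights = matrix.weights

    addition = [rank[t] for t in matrix.taxa]
    if order == "random":
        if rng is None:
            raise SearchError("order='random' requires an rng")
        addition = list(rng.permutation(addition))
    elif order != "simple":
        raise SearchError(f"unknown addition order {order!r}")

    n = len(taxa)
    first = addition[:3]
    hub = n  # first internal node id
    adj: Adjacency = {hub: []}
    for leaf in first:
        _add_edge(adj, hub, leaf)
    next_id = n + 1
    for leaf in addition[3:]:
        best_len, best_edge = None, None
        for edge in _edges(adj):
            trial = _copy_adj(adj)
            _attach_leaf(trial, edge, leaf, next_id)
            length = _score_adj(trial, n, leaf_masks, weights)
            if best_len is None or length < best_len:
                best_len, best_edge = length, edge
        assert best_edge is not None
        _attach_leaf(adj, best_edge, leaf, next_id)
        next_id += 1
    return adjacency_to_tree(adj, n, taxa)


# ---------------------------------------------------------------------- #
# TBR
# ---------------------------------------------------------------------- #
def _tbr_neighbor_adjs(adj: Adjacency, n: int) -> Iterator[Adjacency]:
    """Distinct TBR rearrangements of an unrooted binary adjacency."""
    own = _adj_splits(adj, n)
    seen: set[frozenset[int]] = {own}
    next_id = max(adj) + 1
    for u, v in _edges(adj):
        cut = _copy_adj(adj)
        _remove_edge(cut, u, v)
        rep_u = cut[u][0] if len(cut[u]) == 2 else u
        rep_v = cut[v][0] if len(cut[v]) == 2 else v
        _suppress_degree2(cut, u)
        _suppress_degree2(cut, v)
        comp_u = _component(cut, rep_u)
        comp_v = _component(cut, rep_v)
        attach_u = _attachments(cut, comp_u, rep_u)
        attach_v = _attachments(cut, comp_v, rep_v)
        for au in attach_u:
            for av in attach_v:
                trial = _copy_adj(cut)
                pu = _attachment_point(trial, au, next_id)
                pv = _attachment_point(trial, av, next_id + 1)
                _add_edge(trial, pu, pv)
                key = _adj_splits(trial, n)
                if key not in seen:
                    seen.add(key)
                    yield trial


def _attachments(adj: Adjacency, comp: set[int], cut_end: int):
    """Attachment sites of a fragment: its edges, or the lone leaf itself."""
    if len(comp) == 1:
        return [cut_end]  # single leaf: reattach at the leaf
    return [
        (min(a, b), max(a, b))
        for a in comp
        for b in adj.get(a, ())
        if a < b
    ]


def _attachment_point(adj: Adjacency, site, new_id: int) -> int:
    if isinstance(site, int):
        return site
    a, b = site
    _remove_edge(adj, a, b)
    _add_edge(adj, a, new_id)
    _add_edge(adj, new_id, b)
    return new_id


def tbr_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """Yield every distinct TBR rearrangement of an unrooted binary tree."""
    taxa = sorted(tree.leaf_labels())
    if len(taxa) < 4:
        raise SearchError("TBR needs at least 4 leaves")
    if not tree.is_binary_unrooted():
        raise SearchError("TBR requires an unrooted binary tree")
    adj = tree_to_adjacency(tree, taxa)
    for nb in _tbr_neighbor_adjs(adj, len(taxa)):
        yield adjacency_to_tree(nb, len(taxa), taxa)


# ---------------------------------------------------------------------- #
# heuristic search
# ---------------------------------------------------------------------- #
@dataclass
class SearchResult:
    best_length: float
    mpt_set: list[PhyloTree]
    n_rearrangements: int
    seed: Optional[int]
    settings: dict = field(default_factory=dict)

    @property
    def n_mpts(self) -> int:
        return len(self.mpt_set)


def heuristic_search(
    matrix: CharacterMatrix,
    seed: Optional[int] = None,
    keep_all: bool = True,
    collapse: str = "ambzero",
    maxtrees: int = 10_000,
    addition: str = "simple",
    n_starts: int = 1,
    weights_override: Optional[np.ndarray] = None,
) -> SearchResult:
    """Stepwise addition followed by TBR swapping on all shortest trees.

    ``n_starts > 1`` adds random-addition-sequence replicates after the
    first start (the usual way to escape TBR plateaus on difficult
    matrices); the globally shortest set across starts is returned.
    Deterministic given ``seed`` and settings; ``weights_override``
    rescores with alternative character weights (used by the bootstrap)
    without re-encoding the matrix.
    """
    if matrix.n_taxa < 4:
        raise SearchError("heuristic search needs at least 4 taxa")
    if n_starts < 1:
        raise SearchError("n_starts must be >= 1")
    taxa = sorted(matrix.taxa)
    rank = {t: i for i, t in enumerate(taxa)}
    masks_rows, _ = matrix.state_masks()
    n = len(taxa)
    leaf_masks = np.empty_like(masks_rows)
    for row, t in enumerate(matrix.taxa):
        leaf_masks[rank[t]] = masks_rows[row]
    weights = (
        np.asarray(weights_override, dtype=float)
        if weights_override is not None
        else matrix.weights
    )
    assert weights is not None

    rng = np.random.default_rng(seed if seed is not None else 0)
    work = matrix if weights_override is None else CharacterMatrix(
        taxa=list(matrix.taxa), cells=[list(r) for r in matrix.cells],
        symbols=matrix.symbols, weights=weights,
    )

    best: Optional[float] = None
    optimal: dict[frozenset[int], Adjacency] = {}
    n_rearr = 0
    capped = False
    for start_i in range(n_starts):
        order = addition if start_i == 0 else "random"
        start_tree = stepwise_addition(work, order=order, rng=rng)
        start = tree_to_adjacency(start_tree, taxa)
        length = _score_adj(start, n, leaf_masks, weights)
        key0 = _adj_splits(start, n)
        if best is None or length < best:
            best = length
            optimal = {key0: start}
            queue: deque[frozenset[int]] = deque([key0])
        elif length == best and key0 not in optimal:
            optimal[key0] = start
            queue = deque([key0])
        else:
            # swap from the inferior start anyway: it may descend into a
            # better basin than the current optimum
            sub_best, sub_opt, sub_rearr, sub_capped = _swap_to_closure(
                {key0: start}, deque([key0]), length, n, leaf_masks, weights,
                keep_all, maxtrees,
            )
            n_rearr += sub_rearr
            capped = capped or sub_capped
            if sub_best < best:
                best, optimal = sub_best, sub_opt
            elif sub_best == best:
                for k, a in sub_opt.items():
                    if k not in optimal and len(optimal) < maxtrees:
                        optimal[k] = a
            continue
        best, optimal, rearr, was_capped = _swap_to_closure(
            optimal, queue, best, n, leaf_masks, weights, keep_all, maxtrees
        )
        n_rearr += rearr
        capped = capped or was_capped

    assert best is not None
    trees = [adjacency_to_tree(a, n, taxa) for a in optimal.values()]
    if collapse == "ambzero":
        mpts = collapse_zero_length(trees, work if weights_override is not None else matrix)
    elif collapse == "none":
        mpts = trees
    else:
        raise SearchError(f"unknown collapse rule {collapse!r}")
    logger.info(
        "search done: length %s, %d MPT(s) (%d before collapse), %d rearrangements",
        best, len(mpts), len(trees), n_rearr,
    )
    return SearchResult(
        best_length=best,
        mpt_set=mpts,
        n_rearrangements=n_rearr,
        seed=seed,
        settings={
            "collapse": collapse,
            "maxtrees": maxtrees,
            "addition": addition,
            "n_starts": n_starts,
            "maxtrees_hit": capped,
            "n_binary_trees": len(trees),
        },
    )


def _swap_to_closure(
    optimal: dict[frozenset[int], Adjacency],
    queue: "deque[frozenset[int]]",
    best: float,
    n: int,
    leaf_masks: np.ndarray,
    weights: np.ndarray,
    keep_all: bool,
    maxtrees: int,
) -> tuple[float, dict[frozenset[int], Adjacency], int, bool]:
    """TBR-swap every queued tree until the optimal set is closed."""
    n_rearr = 0
    capped = False
    while queue:
        key = queue.popleft()
        if key not in optimal:
            continue
        current = optimal[key]
        improved = False
        for nb in _tbr_neighbor_adjs(current, n):
            n_rearr += 1
            length = _score_adj(nb, n, leaf_masks, weights)
            if length < best:
                best = length
                k = _adj_splits(nb, n)
                optimal = {k: nb}
                queue = deque([k])
                improved = True
                logger.info(
                    "improved to length %s after %d rearrangements", best, n_rearr
                )
                break
            if keep_all and length == best:
                k = _adj_splits(nb, n)
                if k not in optimal:
                    if len(optimal) >= maxtrees:
                        if not capped:
                            logger.warning(
                                "maxtrees=%d reached; equally parsimonious "
                                "trees dropped",
                                maxtrees,
                            )
                            capped = True
                        continue
                    optimal[k] = nb
                    queue.append(k)
        if improved:
            continue
    return best, optimal, n_rearr, capped


def collapse_zero_length(
    trees: Sequence[PhyloTree], matrix: CharacterMatrix
) -> list[PhyloTree]:
    """Collapse branches whose minimum optimized length is zero; deduplicate.

    A branch has minimum length zero exactly when contracting it leaves the
    tree length unchanged, so each internal edge is tested by contraction and
    rescoring.
    """
    out: list[PhyloTree] = []
    seen: set[frozenset[int]] = set()
    taxa = sorted(trees[0].leaf_labels()) if trees else []
    for tree in trees:
        base, _ = fitch_length(tree, matrix)
        collapsed = tree.copy()
        # decide contractible edges on the binary tree, then contract them all
        to_contract = []
        for node in collapsed.postorder():
            if node.is_leaf or node is collapsed.root or node.parent is None:
                continue
            trial = _contract_once(collapsed, node)
            length, _ = fitch_length(trial, matrix)
            if length == base:
                to_contract.append(node)
        for node in to_contract:
            _contract_in_place(node)
        key = collapsed.bipartitions(taxa)
        if key not in seen:
            seen.add(key)
            out.append(collapsed)
    return out


def _contract_once(tree: PhyloTree, node: Node) -> PhyloTree:
    """Copy of ``tree`` with the branch above ``node`` contracted."""
    copy = tree.copy()
    # locate the copied node by walking both trees in parallel
    for orig, dup in zip(tree.postorder(), copy.postorder()):
        if orig is node:
            _contract_in_place(dup)
            break
    return copy


def _contract_in_place(node: Node) -> None:
    parent = node.parent
    assert parent is not None
    i = parent.children.index(node)
    parent.children[i : i + 1] = node.children
    for child in node.children:
        child.parent = parent


# ---------------------------------------------------------------------- #
# bootstrap
# ---------------------------------------------------------------------- #
@dataclass
class BootstrapSupport:
    """Bipartition support percentages from character resampling."""

    taxa: list[str]
    support: dict[int, float]  # canonical split mask -> percentage
    n_replicates: int

    def label_sets(self) -> dict[frozenset[str], float]:
        from .trees import split_to_labels

        return {
            split_to_labels(mask, self.taxa): pct
            for mask, pct in self.support.items()
        }

    def support_for(self, labels: Iterable[str] | frozenset[str]) -> float:
        """Support for the clade of ``labels`` (0 if never recovered)."""
        want = frozenset(labels)
        comp = frozenset(self.taxa) - want
        for mask, pct in self.support.items():
            side = frozenset(t for i, t in enumerate(self.taxa) if mask >> i & 1)
            if side == want or side == comp:
                return pct
        return 0.0


def bootstrap(
    matrix: CharacterMatrix,
    n_reps: int,
    seed: int = 0,
    maxtrees: int = 1_000,
) -> BootstrapSupport:
    """Nonparametric bootstrap over characters.

    Each replicate resamples the characters with replacement (implemented as
    a resampled weight vector, which preserves the base weights in
    expectation), runs the heuristic search, and tallies the strict-consensus
    bipartitions of that replicate's MPT set.  Replicate ``r`` uses a
    substream derived from ``(seed, r)``, so results are reproducible and
    order-independent across replicates.
    """
    if n_reps < 1:
        raise SearchError("n_reps must be >= 1")
    taxa = sorted(matrix.taxa)
    nchar = matrix.n_characters
    assert matrix.weights is not None
    tally: dict[int, int] = {}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, nchar, size=nchar)
        w = np.bincount(idx, minlength=nchar).astype(float) * matrix.weights
        result = heuristic_search(
            matrix, seed=None, collapse="none", maxtrees=maxtrees,
            weights_override=w,
        )
        splits = None
        for tree in result.mpt_set:
            s = tree.bipartitions(taxa)
            splits = s if splits is None else (splits & s)
        for mask in splits or ():
            tally[mask] = tally.get(mask, 0) + 1
    return BootstrapSupport(
        taxa=taxa,
        support={m: 100.0 * c / n_reps for m, c in sorted(tally.items())},
        n_replicates=n_reps,
    )
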