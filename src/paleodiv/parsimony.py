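"""Exact parsimony scoring and character-fit statistics.

Characters are unordered (non-additive, equal exchange costs).  Scoring on
binary trees uses the Fitch intersection/union pass; trees with hard
polytomies are scored exactly by a unit-cost dynamic program over states
(equivalent to Sankoff with a uniform cost matrix), which the Fitch pass is a
special case of.  Missing tips are treated as "any state", polymorphic tips
as "any member state".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable

import numpy as np

from .matrix import CharacterMatrix
from .trees import Node, PhyloTree

_INF = np.int64(1) << 30


class ParsimonyError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# scoring
# ---------------------------------------------------------------------- #
def _leaf_rows(tree: PhyloTree, matrix: CharacterMatrix) -> dict[int, int]:
    """Map id(leaf node) -> matrix row index; error on unknown leaves."""
    index = {t: i for i, t in enumerate(matrix.taxa)}
    rows = {}
    for leaf in tree.leaf_nodes():
        if leaf.label not in index:
            raise ParsimonyError(f"leaf {leaf.label!r} not in matrix")
        rows[id(leaf)] = index[leaf.label]
    return rows


def _is_fitch_safe(tree: PhyloTree) -> bool:
    """True when sequential pairwise Fitch is exact: binary except that the
    root may have degree 3 (the unrooted-representation vertex)."""
    for node in tree.postorder():
        if node.is_leaf:
            continue
        if node is tree.root:
            if len(node.children) not in (2, 3):
                return False
        elif len(node.children) != 2:
            return False
    return True


def fitch_length(
    tree: PhyloTree, matrix: CharacterMatrix
) -> tuple[float, np.ndarray]:
    """Minimum weighted state changes of ``matrix`` on ``tree``.

    Returns ``(total weighted steps, per-character unweighted steps)``.  The
    result is independent of the rooting of ``tree``.
    """
    masks, k = matrix.state_masks()
    rows = _leaf_rows(tree, matrix)
    if _is_fitch_safe(tree):
        per_char = _fitch_pass(tree, masks, rows)
    else:
        per_char = _sankoff_pass(tree, masks, k, rows)
    assert matrix.weights is not None
    return float(matrix.weights @ per_char), per_char


def _fitch_pass(tree: PhyloTree, masks: np.ndarray, rows: dict[int, int]) -> np.ndarray:
    nchar = masks.shape[1]
    steps = np.zeros(nchar, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node_mask[id(node)] = masks[rows[id(node)]]
            continue
        acc = node_mask.pop(id(node.children[0]))
        for child in node.children[1:]:
            cm = node_mask.pop(id(child))
            inter = acc & cm
            empty = inter == 0
            steps += empty
            acc = np.where(empty, acc | cm, inter)
        node_mask[id(node)] = acc
    return steps


def _sankoff_pass(
    tree: PhyloTree, masks: np.ndarray, k: int, rows: dict[int, int]
) -> np.ndarray:
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            m = masks[rows[id(node)]]
            leaf_cost = np.where(
                ((m[None, :] >> np.arange(k)[:, None]) & 1).astype(bool), 0, _INF
            )
            costs[id(node)] = leaf_cost.astype(np.int64)
            continue
        total = np.zeros((k, masks.shape[1]), dtype=np.int64)
        for child in node.children:
            c = costs.pop(id(child))
            total += np.minimum(c, c.min(axis=0, keepdims=True) + 1)
        costs[id(node)] = total
    root_cost = costs[id(tree.root)]
    return root_cost.min(axis=0)


# ---------------------------------------------------------------------- #
# per-character bounds and fit statistics
# ---------------------------------------------------------------------- #
@dataclass
class CharacterFit:
    """Per-character steps ``s`` on a tree versus conceivable bounds ``m, g``."""

    s: np.ndarray  # steps on the scored tree
    m: np.ndarray  # minimum conceivable steps on any tree
    g: np.ndarray  # steps on the completely unresolved bush
    informative: np.ndarray  # bool: s can vary across trees (g > m)
    constant: np.ndarray  # bool: no variation required at all

    def to_frame(self):
        import pandas as pd

        with np.errstate(invalid="ignore", divide="ignore"):
            ci_i = np.where(self.s > 0, self.m / np.maximum(self.s, 1), 1.0)
            denom = self.g - self.m
            ri_i = np.where(denom > 0, (self.g - self.s) / np.maximum(denom, 1), np.nan)
        return pd.DataFrame(
            {
                "character": np.arange(1, len(self.s) + 1),
                "s": self.s,
                "m": self.m,
                "g": self.g,
                "ci_i": ci_i,
                "ri_i": ri_i,
                "informative": self.informative,
            }
        )


def character_bounds(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-character minimum ``m`` and bush ``g`` conceivable steps.

    ``m`` is one less than the smallest number of states hitting every
    non-missing cell (polymorphic cells resolved to minimize); ``g`` is the
    number of non-missing cells minus the best achievable count of the most
    frequent state.  All-missing characters yield ``m = g = 0``.
    """
    nchar = matrix.n_characters
    m = np.zeros(nchar, dtype=np.int64)
    g = np.zeros(nchar, dtype=np.int64)
    for j in range(nchar):
        cells = [row[j] for row in matrix.cells if row[j] is not None]
        if not cells:
            continue
        observed = sorted({s for c in cells for s in c})
        # g: resolve every cell containing the winning state to that state
        best_freq = max(sum(1 for c in cells if s in c) for s in observed)
        g[j] = len(cells) - best_freq
        # m: smallest hitting set of the cell state-sets
        for size in range(1, len(observed) + 1):
            if any(
                all(c & set(combo) for c in cells)
                for combo in combinations(observed, size)
            ):
                m[j] = size - 1
                break
    return m, g


def character_fit(
    tree: PhyloTree, matrix: CharacterMatrix
) -> CharacterFit:
    _, s = fitch_length(tree, matrix)
    m, g = character_bounds(matrix)
    return CharacterFit(
        s=s,
        m=m,
        g=g,
        informative=g > m,
        constant=m == 0,
    )


@dataclass
class FitIndices:
    """Ensemble consistency / retention / homoplasy / rescaled-consistency."""

    ci: float
    ri: float
    hi: float
    rc: float
    tree_length: float

    def display(self) -> dict[str, float]:
        """Values rounded to 3 decimals, half-up (the usual reporting style)."""

        def r3(x: float) -> float:
            return float(Decimal(repr(x)).quantize(Decimal("0.001"), ROUND_HALF_UP))

        return {
            "CI": r3(self.ci),
            "RI": r3(self.ri),
            "HI": r3(self.hi),
            "RC": r3(self.rc),
            "tree_length": self.tree_length,
        }


def fit_indices(
    trees: PhyloTree | Iterable[PhyloTree], matrix: CharacterMatrix
) -> FitIndices:
    """Ensemble fit indices for a tree (or a set of equally long trees).

    CI = sum(m)/sum(s), RI = (sum(g)-sum(s))/(sum(g)-sum(m)), HI = 1 - CI,
    RC = CI * RI, with weighted sums over ALL characters, including
    parsimony-uninformative ones.  An all-constant matrix (sum(s) = 0) is
    reported as CI = RI = 1 with a warning.
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    trees = list(trees)
    if not trees:
        raise ParsimonyError("no trees supplied")
    assert matrix.weights is not None
    w = matrix.weights
    total0, s = fitch_length(trees[0], matrix)
    for t in trees[1:]:
        total, _ = fitch_length(t, matrix)
        if total != total0:
            raise ParsimonyError(
                f"trees have unequal lengths ({total} != {total0}); "
                "fit indices are defined for a set of equally long trees"
            )
    m, g = character_bounds(matrix)
    S, M, G = float(w @ s), float(w @ m), float(w @ g)
    if S == 0:
        warnings.warn("all characters constant: CI and RI reported as 1")
        ci = ri = 1.0
    else:
        ci = M / S
        ri = (G - S) / (G - M) if G > M else 1.0
    hi = 1.0 - ci
    rc = ci * ri
    return FitIndices(ci=ci, ri=ri, hi=hi, rc=rc, tree_length=total0)


# ---------------------------------------------------------------------- #
# ACCTRAN ancestral reconstruction
# ---------------------------------------------------------------------- #
def acctran_reconstruct(
    tree: PhyloTree, matrix: CharacterMatrix
) -> tuple[dict[int, list[str]], list[tuple[Node, int, str, str]]]:
    """Accelerated-transformation ancestral states on a rooted binary tree.

    Returns ``(states, changes)`` where ``states`` maps ``id(node)`` to the
    per-character state symbols chosen for that node and ``changes`` lists
    ``(child_node, character_index, parent_state, child_state)`` for every
    branch on which the character changes.  The assignment attains the Fitch
    length; among equally parsimonious assignments, ties are resolved by
    placing changes on the more rootward branch.
    """
    for node in tree.postorder():
        if not node.is_leaf and len(node.children) != 2:
            raise ParsimonyError(
                "ACCTRAN requires a binary rooted tree: resolve the polytomy "
                "or use length-only scoring"
            )
    masks, k = matrix.state_masks()
    rows = _leaf_rows(tree, matrix)
    syms = matrix.observed_symbols or matrix.symbols[:1]
    nchar = matrix.n_characters

    # down-pass: unit-cost subtree minima per state
    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            mrow = masks[rows[id(node)]]
            costs[id(node)] = np.where(
                ((mrow[None, :] >> np.arange(k)[:, None]) & 1).astype(bool), 0, _INF
            ).astype(np.int64)
        else:
            total = np.zeros((k, nchar), dtype=np.int64)
            for child in node.children:
                c = costs[id(child)]
                total += np.minimum(c, c.min(axis=0, keepdims=True) + 1)
            costs[id(node)] = total

    # up-pass: greedy optimal choice, accelerating changes rootward
    chosen: dict[int, np.ndarray] = {}
    chosen[id(tree.root)] = np.argmin(costs[id(tree.root)], axis=0)
    changes: list[tuple[Node, int, str, str]] = []
    state_range = np.arange(k)[:, None]
    for node in tree.preorder():
        a = chosen[id(node)]
        for child in node.children:
            c = costs[id(child)]
            penalty = (state_range != a[None, :]).astype(np.int64)
            tot = c + penalty
            # rank: minimise total, then prefer a change (accelerate), then
            # the smallest state symbol (argmin takes the first minimum)
            rank = tot * 2 + (state_range == a[None, :])
            s_child = np.argmin(rank, axis=0)
            chosen[id(child)] = s_child
            for j in np.nonzero(s_child != a)[0]:
                changes.append((child, int(j), syms[a[j]], syms[s_child[j]]))

    states = {nid: [syms[s] for s in arr] for nid, arr in chosen.items()}
    return states, changes
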