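"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation paths they check:
parsimony lengths are obtained by enumerating internal-node state
assignments, optimal trees by enumerating all unrooted topologies, and
consensus splits by a direct tally.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from paleodiv.matrix import CharacterMatrix
from paleodiv.trees import PhyloTree, enumerate_unrooted_topologies


def make_matrix(taxa: str | list[str], rows: list[str], symbols: str = "012") -> CharacterMatrix:
    """Build a matrix from per-taxon coding strings ('?' = missing)."""
    taxa_list = list(taxa)
    cells = []
    for row in rows:
        parsed = []
        i = 0
        while i < len(row):
            ch = row[i]
            if ch == "?":
                parsed.append(None)
                i += 1
            elif ch == "{":
                end = row.index("}", i)
                parsed.append(frozenset(row[i + 1 : end]))
                i = end + 1
            else:
                parsed.append(frozenset(ch))
                i += 1
        cells.append(parsed)
    return CharacterMatrix(taxa=taxa_list, cells=cells, symbols=symbols)


def exhaustive_char_length(tree: PhyloTree, matrix: CharacterMatrix, char: int) -> int:
    """Minimum changes of one character by brute force over internal states."""
    observed = sorted(
        {s for row in matrix.cells for c in [row[char]] if c is not None for s in c}
    )
    if not observed:
        return 0
    internal = [n for n in tree.postorder() if not n.is_leaf]
    tip_allowed = {}
    for leaf in tree.leaf_nodes():
        cell = matrix.row(leaf.label)[char]
        tip_allowed[id(leaf)] = set(observed) if cell is None else set(cell)
    best = None
    for combo in itertools.product(observed, repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, combo)}
        changes = 0
        for node in internal:
            for child in node.children:
                if child.is_leaf:
                    if state[id(node)] not in tip_allowed[id(child)]:
                        changes += 1
                else:
                    if state[id(node)] != state[id(child)]:
                        changes += 1
        if best is None or changes < best:
            best = changes
    return best or 0


def exhaustive_length(tree: PhyloTree, matrix: CharacterMatrix) -> float:
    assert matrix.weights is not None
    return float(
        sum(
            w * exhaustive_char_length(tree, matrix, j)
            for j, w in enumerate(matrix.weights)
        )
    )


def exhaustive_best_length(matrix: CharacterMatrix) -> float:
    """Optimal parsimony length over every unrooted topology (n <= 7)."""
    from paleodiv.parsimony import fitch_length

    best = None
    for tree in enumerate_unrooted_topologies(matrix.taxa):
        total, _ = fitch_length(tree, matrix)
        if best is None or total < best:
            best = total
    assert best is not None
    return best


def random_matrix(
    rng: np.random.Generator,
    n_taxa: int,
    n_chars: int,
    n_states: int = 3,
    missing_prob: float = 0.05,
) -> CharacterMatrix:
    symbols = "012"[:n_states]
    taxa = [f"t{i}" for i in range(n_taxa)]
    cells = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            if rng.random() < missing_prob:
                row.append(None)
            else:
                row.append(frozenset(symbols[rng.integers(n_states)]))
        cells.append(row)
    return CharacterMatrix(taxa=taxa, cells=cells, symbols=symbols)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def quartet_tree() -> PhyloTree:
    from paleodiv.io_formats import parse_newick

    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def clean_six_taxon() -> tuple[PhyloTree, CharacterMatrix]:
    """A 6-taxon tree plus a homoplasy-free matrix of clade synapomorphies."""
    from paleodiv.io_formats import parse_newick

    tree = parse_newick("(((A,B),C),((D,E),F));")
    clades = [{"A", "B"}, {"A", "B", "C"}, {"D", "E"}, {"D", "E", "F"}]
    taxa = list("ABCDEF")
    rows = []
    for t in taxa:
        # three identical diagnostic characters per clade: strong clean signal
        rows.append("".join("1" if t in clade else "0" for clade in clades for _ in range(3)))
    return tree, make_matrix(taxa, rows, symbols="01")
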