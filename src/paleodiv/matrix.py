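"""Morphological character matrix container.

Cells are frozensets of state symbols: a singleton for an ordinary coding, a
larger set for a polymorphic coding, and ``None`` for missing/inapplicable
("?" or "-").  Parsimony treats a missing tip as "any state" and a
polymorphic tip as "any member state" (the usual convention for unordered
characters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

Cell = Optional[frozenset]


class MatrixError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    taxa: list[str]
    cells: list[list[Cell]]  # taxa x characters
    symbols: str = "0123456789"
    weights: Optional[np.ndarray] = None
    _observed_symbols: str = field(init=False, repr=False, default="")

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(self.n_characters, dtype=float)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        self.validate()
        seen = {s for row in self.cells for c in row if c is not None for s in c}
        self._observed_symbols = "".join(s for s in self.symbols if s in seen)

    # ------------------------------------------------------------------ #
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    @property
    def observed_symbols(self) -> str:
        return self._observed_symbols

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixError(f"duplicate taxon label(s): {', '.join(dupes)}")
        if len(self.cells) != len(self.taxa):
            raise MatrixError(
                f"{len(self.taxa)} taxa but {len(self.cells)} matrix rows"
            )
        ncol = self.n_characters
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != ncol:
                raise MatrixError(
                    f"taxon {taxon!r}: expected {ncol} characters, got {len(row)}"
                )
            for j, cell in enumerate(row):
                if cell is None:
                    continue
                if not cell:
                    raise MatrixError(f"taxon {taxon!r}, character {j + 1}: empty state set")
                for sym in cell:
                    if sym not in self.symbols:
                        raise MatrixError(
                            f"taxon {taxon!r}, character {j + 1}: unknown symbol {sym!r}"
                        )
        assert self.weights is not None
        if len(self.weights) != ncol:
            raise MatrixError(
                f"weights length {len(self.weights)} != n_characters {ncol}"
            )
        if np.any(self.weights < 0):
            raise MatrixError("negative character weight")

    # ------------------------------------------------------------------ #
    def cell_category_counts(self) -> dict[str, int]:
        """Counts of missing / singleton / polymorphic cells (sum = taxa x chars)."""
        missing = singleton = poly = 0
        for row in self.cells:
            for cell in row:
                if cell is None:
                    missing += 1
                elif len(cell) == 1:
                    singleton += 1
                else:
                    poly += 1
        return {"missing": missing, "singleton": singleton, "polymorphic": poly}

    def state_masks(self) -> tuple[np.ndarray, int]:
        """Encode cells as bitmasks over ``observed_symbols``.

        Returns ``(masks, k)`` where ``masks`` is (n_taxa, n_characters)
        uint32 and ``k`` the number of observed states; missing cells get the
        full mask (any state).
        """
        syms = self.observed_symbols or self.symbols[:1]
        k = len(syms)
        bit = {s: 1 << i for i, s in enumerate(syms)}
        full = (1 << k) - 1
        masks = np.empty((self.n_taxa, self.n_characters), dtype=np.uint32)
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell is None:
                    masks[i, j] = full
                else:
                    m = 0
                    for sym in cell:
                        m |= bit[sym]
                    masks[i, j] = m
        return masks, k

    def row(self, taxon: str) -> list[Cell]:
        try:
            i = self.taxa.index(taxon)
        except ValueError:
            raise MatrixError(f"taxon {taxon!r} not in matrix") from None
        return self.cells[i]

    def resample_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """Column resample (bootstrap replicate); weights follow the columns."""
        idx = list(indices)
        assert self.weights is not None
        return CharacterMatrix(
            taxa=list(self.taxa),
            cells=[[row[j] for j in idx] for row in self.cells],
            symbols=self.symbols,
            weights=self.weights[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.cells == other.cells
            and np.array_equal(self.weights, other.weights)
        )
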