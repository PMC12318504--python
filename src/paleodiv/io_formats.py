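"""Readers and writers: NEXUS character matrices, Newick trees, TSV tables.

All downstream modules consume only the types defined here (plus
:class:`~paleodiv.matrix.CharacterMatrix` and
:class:`~paleodiv.trees.PhyloTree`).  TSV is the canonical tabular dialect
(UTF-8, header row required); CSV is accepted via ``sep=","``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import pandas as pd

from .matrix import CharacterMatrix
from .trees import Node, PhyloTree


class NexusParseError(ValueError):
    pass


class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (character offset {offset})")
        self.offset = offset


class TableError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# stratigraphic table row types
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class StratRange:
    """Per-taxon age-uncertainty envelope on first/last appearance (Ma)."""

    taxon: str
    fad_old: float
    fad_young: float
    lad_old: float
    lad_young: float
    source_units: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.fad_old >= self.fad_young >= 0):
            raise TableError(
                f"{self.taxon}: FAD bounds must satisfy fad_old >= fad_young >= 0 "
                f"(got {self.fad_old}, {self.fad_young})"
            )
        if not (self.lad_old >= self.lad_young >= 0):
            raise TableError(
                f"{self.taxon}: LAD bounds must satisfy lad_old >= lad_young >= 0 "
                f"(got {self.lad_old}, {self.lad_young})"
            )
        if self.fad_old < self.lad_young:
            raise TableError(
                f"{self.taxon}: empty maximal range (fad_old {self.fad_old} < "
                f"lad_young {self.lad_young})"
            )


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil occurrence: taxon x rock unit x age interval (Ma)."""

    taxon: str
    unit: str
    age_old: float
    age_young: float
    family: str | None = None

    def __post_init__(self) -> None:
        if self.age_old < self.age_young:
            raise TableError(
                f"{self.taxon} @ {self.unit}: age_old {self.age_old} < "
                f"age_young {self.age_young}"
            )


@dataclass
class StageTable:
    """Ordered chronostratigraphic stages, contiguous and strictly decreasing."""

    stages: list[tuple[str, float, float]]  # (name, old boundary, young boundary)

    def __post_init__(self) -> None:
        if not self.stages:
            raise TableError("empty stage table")
        prev_young = None
        for name, old, young in self.stages:
            if old <= young:
                raise TableError(f"stage {name}: old {old} <= young {young}")
            if prev_young is not None and abs(old - prev_young) > 1e-9:
                raise TableError(
                    f"stage {name}: not contiguous (starts {old}, previous ended {prev_young})"
                )
            prev_young = young

    @property
    def names(self) -> list[str]:
        return [s[0] for s in self.stages]

    def bounds(self, name: str) -> tuple[float, float]:
        for n, old, young in self.stages:
            if n == name:
                return old, young
        raise TableError(f"unknown stage {name!r}")

    def stages_touching(self, age_old: float, age_young: float) -> list[str]:
        """Stage names intersecting [age_old, age_young].

        An interval touches a stage only where the overlap has positive
        width (an endpoint on a boundary does not leak into the adjacent
        stage); a point occurrence follows the half-open stage convention
        ``old >= age > young``.
        """
        if age_old == age_young:
            return [
                name
                for name, old, young in self.stages
                if old >= age_old > young
            ]
        return [
            name
            for name, old, young in self.stages
            if age_old > young and age_young < old
        ]


# ---------------------------------------------------------------------- #
# NEXUS character matrix
# ---------------------------------------------------------------------- #
_COMMENT_RE = re.compile(r"\[[^\]]*\]")


def _strip_nexus_comments(text: str) -> str:
    return _COMMENT_RE.sub(" ", text)


def _tokenize_label(line: str) -> tuple[str, str]:
    """Split one MATRIX line into (taxon label, remainder)."""
    line = line.strip()
    if line.startswith("'"):
        end = line.find("'", 1)
        while end != -1 and line[end + 1 : end + 2] == "'":  # escaped ''
            end = line.find("'", end + 2)
        if end == -1:
            raise NexusParseError(f"unterminated quoted label: {line!r}")
        return line[1:end].replace("''", "'"), line[end + 1 :]
    parts = line.split(None, 1)
    if len(parts) == 1:
        return parts[0], ""
    return parts[0], parts[1]


def _parse_cells(chunk: str, taxon: str, symbols: str, missing: str, gap: str,
                 start_index: int) -> list:
    cells = []
    i = 0
    pos = start_index
    while i < len(chunk):
        ch = chunk[i]
        if ch.isspace():
            i += 1
            continue
        pos += 1
        if ch in "{(":
            close = "}" if ch == "{" else ")"
            end = chunk.find(close, i)
            if end == -1:
                raise NexusParseError(
                    f"taxon {taxon!r}: unclosed polymorphism bracket at character {pos}"
                )
            members = frozenset(c for c in chunk[i + 1 : end] if not c.isspace())
            for sym in members:
                if sym not in symbols:
                    raise NexusParseError(
                        f"taxon {taxon!r}, character {pos}: unknown symbol {sym!r}"
                    )
            if not members:
                raise NexusParseError(
                    f"taxon {taxon!r}, character {pos}: empty polymorphism set"
                )
            cells.append(members)
            i = end + 1
        elif ch == missing or ch == gap:
            cells.append(None)
            i += 1
        elif ch in symbols:
            cells.append(frozenset(ch))
            i += 1
        else:
            raise NexusParseError(
                f"taxon {taxon!r}, character {pos}: unknown symbol {ch!r}"
            )
    return cells


def parse_nexus_matrix(text: str) -> CharacterMatrix:
    """Parse a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    Interleaved and non-interleaved dialects are accepted; ``?`` and the gap
    symbol map to missing; ``{01}``/``(01)`` map to polymorphic state sets.
    """
    clean = _strip_nexus_comments(text)
    if not clean.lstrip().upper().startswith("#NEXUS"):
        raise NexusParseError("not a NEXUS document (missing #NEXUS header)")
    m = re.search(
        r"BEGIN\s+(DATA|CHARACTERS)\s*;(.*?)END\s*;",
        clean,
        re.IGNORECASE | re.DOTALL,
    )
    if not m:
        raise NexusParseError("no DATA or CHARACTERS block found")
    block = m.group(2)

    ntax = nchar = None
    dm = re.search(r"DIMENSIONS([^;]*);", block, re.IGNORECASE | re.DOTALL)
    if not dm:
        raise NexusParseError("missing DIMENSIONS command")
    dims = dm.group(1)
    mt = re.search(r"NTAX\s*=\s*(\d+)", dims, re.IGNORECASE)
    if mt:
        ntax = int(mt.group(1))
    mc = re.search(r"NCHAR\s*=\s*(\d+)", dims, re.IGNORECASE)
    if mc:
        nchar = int(mc.group(1))
    if nchar is None:
        raise NexusParseError("DIMENSIONS must declare NCHAR")

    symbols, missing, gap, interleave = "0123456789", "?", "-", False
    fm = re.search(r"FORMAT([^;]*);", block, re.IGNORECASE | re.DOTALL)
    if fm:
        fmt = fm.group(1)
        ms = re.search(r"SYMBOLS\s*=\s*\"([^\"]*)\"", fmt, re.IGNORECASE)
        if ms:
            symbols = "".join(ms.group(1).split())
        mm = re.search(r"MISSING\s*=\s*(\S)", fmt, re.IGNORECASE)
        if mm:
            missing = mm.group(1)
        mg = re.search(r"GAP\s*=\s*(\S)", fmt, re.IGNORECASE)
        if mg:
            gap = mg.group(1)
        interleave = re.search(r"INTERLEAVE", fmt, re.IGNORECASE) is not None

    mx = re.search(r"MATRIX(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mx:
        raise NexusParseError("missing MATRIX command")

    taxa: list[str] = []
    rows: dict[str, list] = {}
    for raw_line in mx.group(1).splitlines():
        line = raw_line.strip()
        if not line:
            continue
        taxon, chunk = _tokenize_label(line)
        if taxon in rows:
            if not interleave:
                raise NexusParseError(f"duplicate taxon label {taxon!r}")
        else:
            taxa.append(taxon)
            rows[taxon] = []
        rows[taxon].extend(
            _parse_cells(chunk, taxon, symbols, missing, gap, len(rows[taxon]))
        )

    if not taxa:
        raise NexusParseError("MATRIX command contains no rows")
    if ntax is not None and len(taxa) != ntax:
        raise NexusParseError(f"expected NTAX={ntax} taxa, found {len(taxa)}")
    for taxon in taxa:
        if len(rows[taxon]) != nchar:
            raise NexusParseError(
                f"taxon {taxon!r}: expected {nchar} characters, got {len(rows[taxon])}"
            )
    return CharacterMatrix(taxa=taxa, cells=[rows[t] for t in taxa], symbols=symbols)


def write_nexus_matrix(matrix: CharacterMatrix) -> str:
    """Serialize a matrix to a non-interleaved NEXUS DATA block."""
    out = io.StringIO()
    out.write("#NEXUS\n\nBEGIN DATA;\n")
    out.write(f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n")
    out.write(
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{matrix.symbols}" MISSING=? GAP=-;\n'
    )
    out.write("MATRIX\n")
    width = max(len(_quote_label(t)) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        cells = []
        for cell in row:
            if cell is None:
                cells.append("?")
            elif len(cell) == 1:
                cells.append(next(iter(cell)))
            else:
                cells.append("{" + "".join(sorted(cell)) + "}")
        out.write(f"{_quote_label(taxon):<{width}}{''.join(cells)}\n")
    out.write(";\nEND;\n")
    return out.getvalue()


def _quote_label(label: str) -> str:
    if re.search(r"[\s(){}\[\]'\";,:=]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------- #
# Newick
# ---------------------------------------------------------------------- #
_NEWICK_UNQUOTED_END = set("(),:;[]")


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree; malformed input raises with a character offset."""
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1

    def parse_label() -> str | None:
        nonlocal pos
        skip_ws()
        if pos >= len(s):
            return None
        if s[pos] == "'":
            end = s.find("'", pos + 1)
            while end != -1 and s[end + 1 : end + 2] == "'":
                end = s.find("'", end + 2)
            if end == -1:
                raise error("unterminated quoted label")
            label = s[pos + 1 : end].replace("''", "'")
            pos = end + 1
            return label
        start = pos
        while pos < len(s) and s[pos] not in _NEWICK_UNQUOTED_END and not s[pos].isspace():
            pos += 1
        return s[start:pos] if pos > start else None

    def parse_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error("malformed branch length") from None
        return None

    def parse_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= len(s):
                    raise error("unbalanced parentheses: missing ')'")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = parse_label()
            if label is not None:
                # internal labels are treated as support values when numeric
                try:
                    node.support = float(label)
                except ValueError:
                    node.label = label
        else:
            label = parse_label()
            if label is None:
                raise error("expected a taxon label")
            node.label = label
        node.length = parse_length()
        return node

    root = parse_clade()
    skip_ws()
    if pos >= len(s) or s[pos] != ";":
        raise error("missing ';' terminator" if pos >= len(s) else
                    f"unexpected character {s[pos]!r} (unbalanced parentheses?)")
    pos += 1
    skip_ws()
    if pos != len(s):
        raise error("trailing content after ';'")
    if root.is_leaf:
        raise NewickParseError("tree has a single node", 0)
    return PhyloTree(root)


def write_newick(tree: PhyloTree, include_support: bool = False) -> str:
    """Serialize to Newick; branch lengths kept to 12 significant digits."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            base = _quote_newick_label(node.label or "")
        else:
            base = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if include_support and node.support is not None:
                base += f"{node.support:.6g}"
            elif node.label:
                base += _quote_newick_label(node.label)
        if node.length is not None:
            base += f":{node.length:.12g}"
        return base

    return fmt(tree.root) + ";"


def _quote_newick_label(label: str) -> str:
    if re.search(r"[\s(),:;\[\]']", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick_trees(text: str) -> list[PhyloTree]:
    """Read a file of one Newick tree per line (blank lines skipped)."""
    return [parse_newick(line) for line in text.splitlines() if line.strip()]


# ---------------------------------------------------------------------- #
# TSV tables
# ---------------------------------------------------------------------- #
def read_ranges(source, sep: str = "\t") -> list[StratRange]:
    """Read a stratigraphic-range table into per-taxon ranges.

    Required columns: ``taxon, fad_old, fad_young``; ``lad_old, lad_young``
    default to the FAD columns (single-occurrence taxa).  An optional ``unit``
    column names the rock unit.  Taxa spanning multiple rows (multiple
    formations) are merged by the maximal-span union rule of
    :func:`paleodiv.chronos.combine_ranges`.
    """
    from .chronos import combine_ranges  # local import: avoids a module cycle

    df = _read_table(source, sep)
    required = {"taxon", "fad_old", "fad_young"}
    if not required.issubset(df.columns):
        raise TableError(
            f"range table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    per_taxon: dict[str, list[StratRange]] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        try:
            fad_old, fad_young = float(row["fad_old"]), float(row["fad_young"])
            lad_old = float(row["lad_old"]) if "lad_old" in df.columns and pd.notna(row.get("lad_old")) else fad_old
            lad_young = float(row["lad_young"]) if "lad_young" in df.columns and pd.notna(row.get("lad_young")) else fad_young
            units = (str(row["unit"]),) if "unit" in df.columns and pd.notna(row.get("unit")) else ()
            rng = StratRange(str(row["taxon"]), fad_old, fad_young, lad_old, lad_young, units)
        except (TableError, ValueError) as exc:
            raise TableError(f"range table row {i + 2}: {exc}") from None
        if rng.taxon not in per_taxon:
            order.append(rng.taxon)
        per_taxon.setdefault(rng.taxon, []).append(rng)
    return [combine_ranges(per_taxon[t]) for t in order]


def read_occurrences(source, sep: str = "\t") -> list[OccurrenceRecord]:
    """Read an occurrence table (columns: taxon, unit, age_old, age_young[, family])."""
    df = _read_table(source, sep)
    required = {"taxon", "unit", "age_old", "age_young"}
    if not required.issubset(df.columns):
        raise TableError(
            f"occurrence table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                OccurrenceRecord(
                    str(row["taxon"]),
                    str(row["unit"]),
                    float(row["age_old"]),
                    float(row["age_young"]),
                    str(row["family"]) if "family" in df.columns and pd.notna(row.get("family")) else None,
                )
            )
        except (TableError, ValueError) as exc:
            raise TableError(f"occurrence table row {i + 2}: {exc}") from None
    return records


def read_stage_table(source, sep: str = "\t") -> StageTable:
    """Read a stage table (columns: stage, old, young)."""
    df = _read_table(source, sep)
    required = {"stage", "old", "young"}
    if not required.issubset(df.columns):
        raise TableError(
            f"stage table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    return StageTable(
        [(str(r["stage"]), float(r["old"]), float(r["young"])) for _, r in df.iterrows()]
    )


def _read_table(source, sep: str) -> pd.DataFrame:
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=sep, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return df
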