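"""Bundled reference tables.

The stage tables carry the Oligocene-Miocene chronostratigraphic boundaries
(a rounded table and the ICS-2023 chart values).  The desmostylian range,
occurrence and topology files are SYNTHETIC stage-level reconstructions
compiled from published per-stage species compositions for the two families
(Paleoparadoxiidae, Desmostylidae); they stand in for the locality-level
occurrence compilation, which is not redistributed here, and are labelled
``_synthetic`` accordingly.
"""

from __future__ import annotations

from importlib import resources

from .io_formats import (
    OccurrenceRecord,
    StageTable,
    StratRange,
    read_newick_trees,
    read_occurrences,
    read_ranges,
    read_stage_table,
)
from .trees import PhyloTree


def _text(name: str) -> str:
    return (resources.files("paleodiv") / "data" / name).read_text()


def load_stage_table(which: str = "rounded") -> StageTable:
    """Stage boundaries: ``"rounded"`` (default) or ``"ics2023"``."""
    name = {"rounded": "stages.tsv", "ics2023": "stages_ics2023.tsv"}.get(which)
    if name is None:
        raise ValueError(f"unknown stage table {which!r}")
    return read_stage_table(_text(name))


def load_desmostylian_occurrences() -> list[OccurrenceRecord]:
    """Synthetic stage-level desmostylian occurrence reconstruction."""
    return read_occurrences(_text("desmostylia_occurrences_synthetic.tsv"))


def load_desmostylian_ranges() -> list[StratRange]:
    """Synthetic stage-level desmostylian range envelopes (merged per taxon)."""
    return read_ranges(_text("desmostylia_ranges_synthetic.tsv"))


def load_family_tree(family: str) -> PhyloTree:
    """Synthetic family-level topology (``"Paleoparadoxiidae"`` or
    ``"Desmostylidae"``), reconstructed from published relationships."""
    name = {
        "Paleoparadoxiidae": "paleoparadoxiidae_synthetic.nwk",
        "Desmostylidae": "desmostylidae_synthetic.nwk",
    }.get(family)
    if name is None:
        raise ValueError(f"unknown family {family!r}")
    return read_newick_trees(_text(name))[0]
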