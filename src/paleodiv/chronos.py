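"""Time-scaling against stratigraphy, stage-binned counts, richness curves.

Ages are in Ma and increase toward the past.  Node ages follow the basic
paleontological time-scaling rule: an internal node is as old as the oldest
first-appearance datum among its descendants (plus a small rootward push for
zero-length internal branches).  Lineage counts include ghost segments — the
portion of a tip's branch older than its own origination that its sister
lineage forces to exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import OccurrenceRecord, StageTable, StratRange
from .trees import Node, PhyloTree


class ChronosError(ValueError):
    pass


# ---------------------------------------------------------------------- #
# range combination
# ---------------------------------------------------------------------- #
def combine_ranges(records: Sequence[StratRange]) -> StratRange:
    """Merge per-formation ranges of one taxon into its maximal envelope.

    The first appearance is bracketed by the oldest formation (``fad_old`` =
    oldest possible, ``fad_young`` = that formation's young bound) and the
    last appearance by the youngest formation, so the combined maximal span
    runs from the oldest old-bound to the youngest young-bound.
    """
    if not records:
        raise ChronosError("no records to combine")
    taxa = {r.taxon for r in records}
    if len(taxa) > 1:
        raise ChronosError(f"records from different taxa: {sorted(taxa)}")
    units: tuple[str, ...] = tuple(
        dict.fromkeys(u for r in records for u in r.source_units)
    )
    return StratRange(
        taxon=records[0].taxon,
        fad_old=max(r.fad_old for r in records),
        fad_young=max(r.fad_young for r in records),
        lad_old=min(r.lad_old for r in records),
        lad_young=min(r.lad_young for r in records),
        source_units=units,
    )


# ---------------------------------------------------------------------- #
# time-scaling
# ---------------------------------------------------------------------- #
@dataclass
class TimeScaledTree:
    """A tree with node ages and per-tip (origination, extinction) ages."""

    tree: PhyloTree
    tip_ranges: dict[str, tuple[float, float]]  # label -> (orig, ext), Ma
    scenario: str

    @property
    def root_age(self) -> float:
        age = self.tree.root.age
        if age is None:
            lab = self.tree.root.label
            return self.tip_ranges[lab][0] if lab else 0.0
        return age


def _scenario_tip_range(rng: StratRange, scenario: str) -> tuple[float, float]:
    if scenario == "max":
        return rng.fad_old, rng.lad_young
    if scenario == "min":
        orig, ext = rng.fad_young, rng.lad_old
        if orig < ext:  # inverted: collapse to a single instant
            mid = 0.5 * (orig + ext)
            return mid, mid
        return orig, ext
    raise ChronosError(f"unknown scenario {scenario!r} (use 'min' or 'max')")


def time_scale(
    tree: PhyloTree,
    ranges: Mapping[str, StratRange],
    scenario: str = "max",
    min_branch: float = 0.1,
) -> TimeScaledTree:
    """Assign node ages from tip first-appearance data under a scenario.

    ``"max"`` uses the broadest tip ranges (oldest possible FAD to youngest
    possible LAD); ``"min"`` the narrowest.  Internal node age = oldest
    descendant origination; zero-length internal branches are extended
    rootward by ``min_branch``.  Polytomies are left as-is (soft-polytomy
    convention: children attach at the polytomy's age).
    """
    tree = tree.copy()
    tips: dict[str, tuple[float, float]] = {}
    for leaf in tree.leaf_nodes():
        assert leaf.label is not None
        if leaf.label not in ranges:
            raise ChronosError(f"no stratigraphic range for tip {leaf.label!r}")
        tips[leaf.label] = _scenario_tip_range(ranges[leaf.label], scenario)
    for node in tree.postorder():
        if node.is_leaf:
            node.age = tips[node.label][0]  # type: ignore[index]
            continue
        age = max(c.age for c in node.children)  # type: ignore[type-var]
        # a zero-length internal branch is extended rootward by min_branch
        if any(
            not c.is_leaf and c.age is not None and c.age >= age - 1e-12
            for c in node.children
        ):
            age += min_branch
        node.age = age
    return TimeScaledTree(tree=tree, tip_ranges=tips, scenario=scenario)


def lineage_count(ts: TimeScaledTree, t: float) -> int:
    """Number of lineages (branches, ghost segments included) alive at ``t``.

    A branch spanning ``[older, younger)`` contains ``t`` when
    ``older >= t > younger``.
    """
    root = ts.tree.root
    if root.is_leaf:
        orig, ext = ts.tip_ranges[root.label]  # type: ignore[index]
        return 1 if orig >= t > ext else 0
    assert root.age is not None
    if t > root.age:
        warnings.warn(f"time {t} older than root age {root.age}; count is 0")
        return 0
    count = 0
    for node in ts.tree.preorder():
        if node is root:
            continue
        parent_age = node.parent.age  # type: ignore[union-attr]
        assert parent_age is not None
        younger = (
            ts.tip_ranges[node.label][1] if node.is_leaf else node.age  # type: ignore[index]
        )
        assert younger is not None
        if parent_age >= t > younger:
            count += 1
    return count


# ---------------------------------------------------------------------- #
# richness curves
# ---------------------------------------------------------------------- #
@dataclass
class RichnessCurve:
    """Per-slice minimum and maximum lineage counts on a regular Ma grid."""

    slice_old: np.ndarray
    slice_young: np.ndarray
    min_count: np.ndarray
    max_count: np.ndarray

    @property
    def n_slices(self) -> int:
        return len(self.slice_old)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.slice_old + self.slice_young)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slice_old": self.slice_old,
                "slice_young": self.slice_young,
                "min_count": self.min_count,
                "max_count": self.max_count,
            }
        )


def richness_curves(
    trees: PhyloTree | Sequence[PhyloTree],
    ranges: Mapping[str, StratRange] | Sequence[StratRange],
    t_start: float = 35.0,
    t_end: float = 5.0,
    dt: float = 0.1,
    min_branch: float = 0.1,
) -> RichnessCurve:
    """Minimum/maximum lineage-richness curves across a tree set.

    Each slice midpoint is evaluated under the "max" scenario on every tree
    (the per-slice maximum is reported) and under the "min" scenario (the
    per-slice minimum is reported), bracketing both chronostratigraphic
    uncertainty and topology-induced ghost lineages.
    """
    if dt <= 0:
        raise ChronosError("dt must be positive")
    if t_start <= t_end:
        raise ChronosError("t_start must be older than t_end")
    if isinstance(trees, PhyloTree):
        trees = [trees]
    trees = list(trees)
    if not trees:
        raise ChronosError("no trees supplied")
    if not isinstance(ranges, Mapping):
        ranges = {r.taxon: r for r in ranges}

    n_slices = int(round((t_start - t_end) / dt))
    old = t_start - dt * np.arange(n_slices)
    young = old - dt
    mids = 0.5 * (old + young)

    min_counts = np.full(n_slices, np.iinfo(np.int64).max, dtype=np.int64)
    max_counts = np.zeros(n_slices, dtype=np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # midpoints older than root are 0
        for tree in trees:
            ts_max = time_scale(tree, ranges, "max", min_branch)
            ts_min = time_scale(tree, ranges, "min", min_branch)
            cmax = np.array([lineage_count(ts_max, t) for t in mids])
            cmin = np.array([lineage_count(ts_min, t) for t in mids])
            max_counts = np.maximum(max_counts, cmax)
            min_counts = np.minimum(min_counts, cmin)
    return RichnessCurve(
        slice_old=old, slice_young=young,
        min_count=min_counts, max_count=max_counts,
    )


# ---------------------------------------------------------------------- #
# stage-binned species counts
# ---------------------------------------------------------------------- #
@dataclass
class StageCounts:
    """Species counts per chronostratigraphic stage and per group."""

    stages: StageTable
    table: pd.DataFrame  # index: stage names (ordered); columns: groups

    def count(self, stage: str, group: str) -> int:
        return int(self.table.loc[stage, group])

    def to_frame(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(
            id_vars="stage", var_name="group", value_name="n_species"
        )
        return long


def stage_binned(
    occurrences: Iterable[OccurrenceRecord],
    stages: StageTable,
    group_by: str = "family",
) -> StageCounts:
    """Range-through species counts per stage.

    Each taxon occupies every stage between the oldest and the youngest
    stage touched by any of its occurrences (species are assumed to persist
    continuously through their confirmed temporal range).  Counts are
    aggregated per ``family`` (or a single "all" group).
    """
    occurrences = list(occurrences)
    names = stages.names
    stage_index = {s: i for i, s in enumerate(names)}
    taxon_span: dict[str, tuple[int, int]] = {}
    taxon_group: dict[str, str] = {}
    for rec in occurrences:
        touched = stages.stages_touching(rec.age_old, rec.age_young)
        if not touched:
            raise ChronosError(
                f"occurrence intersects no stage: {rec.taxon} @ {rec.unit} "
                f"[{rec.age_old}, {rec.age_young}] Ma"
            )
        lo = min(stage_index[s] for s in touched)
        hi = max(stage_index[s] for s in touched)
        if rec.taxon in taxon_span:
            plo, phi = taxon_span[rec.taxon]
            taxon_span[rec.taxon] = (min(lo, plo), max(hi, phi))
        else:
            taxon_span[rec.taxon] = (lo, hi)
        if group_by == "family" and rec.family is not None:
            taxon_group.setdefault(rec.taxon, rec.family)

    groups = sorted(set(taxon_group.values())) or ["all"]
    table = pd.DataFrame(0, index=pd.Index(names, name="stage"), columns=groups)
    for taxon, (lo, hi) in taxon_span.items():
        group = taxon_group.get(taxon, groups[0])
        for i in range(lo, hi + 1):
            table.loc[names[i], group] += 1
    return StageCounts(stages=stages, table=table)


# ---------------------------------------------------------------------- #
# optional plotting
# ---------------------------------------------------------------------- #
def plot_richness(curve: RichnessCurve, path: str, title: str = "") -> None:
    """Simple min/max richness line plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    mids = curve.midpoints
    ax.step(mids, curve.max_count, where="mid", color="firebrick", label="maximum")
    ax.step(mids, curve.min_count, where="mid", color="steelblue", label="minimum")
    ax.set_xlabel("Age (Ma)")
    ax.set_ylabel("Lineages")
    ax.invert_xaxis()
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
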