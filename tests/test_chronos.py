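"""Range combination, time-scaling, lineage counts, richness, stage bins."""

import numpy as np
import pytest

from paleodiv.chronos import (
    ChronosError,
    combine_ranges,
    lineage_count,
    richness_curves,
    stage_binned,
    time_scale,
)
from paleodiv.io_formats import (
    OccurrenceRecord,
    StageTable,
    StratRange,
    parse_newick,
)


def sr(taxon, fo, fy, lo=None, ly=None):
    if lo is None:
        lo, ly = fo, fy
    return StratRange(taxon, fo, fy, lo, ly)


class TestCombineRanges:
    def test_two_units_maximal_span(self):
        combined = combine_ranges([sr("X", 16, 14), sr("X", 13, 11)])
        assert (combined.fad_old, combined.lad_young) == (16, 11)

    def test_single_record_identity(self):
        r = sr("X", 20, 18, 12, 10)
        assert combine_ranges([r]) == r

    def test_three_overlapping_units(self):
        combined = combine_ranges(
            [sr("X", 20, 15), sr("X", 18, 12), sr("X", 14, 10)]
        )
        assert (combined.fad_old, combined.lad_young) == (20, 10)

    def test_mixed_taxa_rejected(self):
        with pytest.raises(ChronosError, match="different taxa"):
            combine_ranges([sr("X", 16, 14), sr("Y", 13, 11)])


class TestTimeScale:
    def test_cherry_node_age(self):
        tree = parse_newick("(A,B);")
        ranges = {"A": sr("A", 20, 20, 10, 10), "B": sr("B", 18, 18, 9, 9)}
        ts = time_scale(tree, ranges, "max", min_branch=0.1)
        assert ts.tree.root.age == 20.0  # oldest descendant FAD

    def test_caterpillar_with_ghost(self):
        tree = parse_newick("((A,B),C);")
        ranges = {
            "A": sr("A", 20, 20, 15, 15),
            "B": sr("B", 12, 12, 10, 10),
            "C": sr("C", 25, 25, 22, 22),
        }
        ts = time_scale(tree, ranges, "max")
        inner = next(
            n for n in ts.tree.postorder()
            if not n.is_leaf and {c.label for c in n.children} == {"A", "B"}
        )
        assert ts.tree.root.age == 25.0
        assert inner.age == 20.0
        # manual lineage-through-time trace:
        #  23 Ma: C plus the (A,B) stem lineage            -> 2
        #  21 Ma: only the (A,B) stem (C extinct at 22)    -> 1
        #  16 Ma: A plus B's ghost back to the divergence  -> 2
        assert lineage_count(ts, 23.0) == 2
        assert lineage_count(ts, 21.0) == 1
        assert lineage_count(ts, 16.0) == 2

    def test_zero_length_internal_branch_pushed(self):
        tree = parse_newick("((A,B),C);")
        ranges = {
            "A": sr("A", 20, 20, 15, 15),
            "B": sr("B", 12, 12, 10, 10),
            "C": sr("C", 18, 18, 16, 16),
        }
        ts = time_scale(tree, ranges, "max", min_branch=0.1)
        inner = next(
            n for n in ts.tree.postorder()
            if not n.is_leaf and n is not ts.tree.root
        )
        assert inner.age == 20.0
        assert ts.tree.root.age == pytest.approx(20.1)  # pushed above the child

    def test_polytomy_children_attach_at_polytomy_age(self):
        tree = parse_newick("(A,B,C);")
        ranges = {
            "A": sr("A", 20, 20, 15, 15),
            "B": sr("B", 12, 12, 10, 10),
            "C": sr("C", 18, 18, 16, 16),
        }
        ts = time_scale(tree, ranges, "max")
        assert ts.tree.root.age == 20.0
        assert lineage_count(ts, 19.0) == 3  # soft polytomy: all attach at 20

    def test_missing_range_named(self):
        tree = parse_newick("(A,B);")
        with pytest.raises(ChronosError, match="'B'"):
            time_scale(tree, {"A": sr("A", 20, 20, 10, 10)}, "max")

    def test_min_scenario_inverted_range_collapses(self):
        tree = parse_newick("(A,B);")
        ranges = {
            "A": sr("A", 20, 18, 19, 17),  # min scenario would be [18, 19]
            "B": sr("B", 20, 20, 10, 10),
        }
        ts = time_scale(tree, ranges, "min")
        orig, ext = ts.tip_ranges["A"]
        assert orig == ext == pytest.approx(18.5)  # point at the midpoint


class TestLineageCount:
    def test_single_taxon(self):
        from paleodiv.chronos import TimeScaledTree
        from paleodiv.trees import Node, PhyloTree

        single = TimeScaledTree(
            tree=PhyloTree(Node("A")), tip_ranges={"A": (20.0, 10.0)}, scenario="max"
        )
        assert lineage_count(single, 15.0) == 1
        assert lineage_count(single, 20.0) == 1  # half-open: older bound in
        assert lineage_count(single, 10.0) == 0  # ... younger bound out
        assert lineage_count(single, 10.1) == 1
        assert lineage_count(single, 25.0) == 0

    def test_cherry_ghost_counted(self):
        tree = parse_newick("(A,B);")
        ranges = {"A": sr("A", 20, 20, 15, 15), "B": sr("B", 12, 12, 10, 10)}
        ts = time_scale(tree, ranges, "max")
        assert lineage_count(ts, 17.0) == 2  # A plus B's ghost back to 20
        assert lineage_count(ts, 11.0) == 1  # only B remains
        assert lineage_count(ts, 9.0) == 0

    def test_older_than_root_warns(self):
        tree = parse_newick("(A,B);")
        ranges = {"A": sr("A", 20, 20, 15, 15), "B": sr("B", 12, 12, 10, 10)}
        ts = time_scale(tree, ranges, "max")
        with pytest.warns(UserWarning, match="older than root"):
            assert lineage_count(ts, 30.0) == 0


class TestRichnessCurves:
    def test_slice_count_grid(self):
        tree = parse_newick("(A,B);")
        ranges = [sr("A", 20, 20, 10, 10), sr("B", 18, 18, 9, 9)]
        curve = richness_curves(tree, ranges, t_start=35.0, t_end=5.0, dt=0.1)
        assert curve.n_slices == 300

    def test_exactly_known_single_taxon(self):
        from paleodiv.chronos import TimeScaledTree
        from paleodiv.trees import Node, PhyloTree

        tree = PhyloTree(Node("A"))
        ranges = [sr("A", 20, 20, 10, 10)]
        curve = richness_curves(tree, ranges, t_start=30.0, t_end=5.0, dt=0.5)
        inside = (curve.midpoints <= 20.0) & (curve.midpoints > 10.0)
        assert np.array_equal(curve.min_count, curve.max_count)
        assert np.all(curve.max_count[inside] == 1)
        assert np.all(curve.max_count[~inside] == 0)

    def test_cherry_slicewise_bracketing(self):
        tree = parse_newick("(A,B);")
        ranges = [sr("A", 20, 20, 15, 15), sr("B", 12, 12, 10, 10)]
        curve = richness_curves(tree, ranges, t_start=25.0, t_end=5.0, dt=0.5)
        mids = curve.midpoints
        expect_max = np.where((mids <= 20) & (mids > 15), 2, 0)
        expect_max = np.where((mids <= 15) & (mids > 10), 1, expect_max)
        assert np.array_equal(curve.max_count, expect_max)
        assert np.all(curve.min_count <= curve.max_count)

    def test_bad_grid_rejected(self):
        tree = parse_newick("(A,B);")
        ranges = [sr("A", 20, 20, 10, 10), sr("B", 18, 18, 9, 9)]
        with pytest.raises(ChronosError, match="dt"):
            richness_curves(tree, ranges, dt=0.0)


STAGES = StageTable(
    [("Old", 30.0, 25.0), ("Mid", 25.0, 20.0), ("Young", 20.0, 15.0)]
)


class TestStageBinned:
    def test_range_through_fills_gap(self):
        occs = [
            OccurrenceRecord("X", "u1", 29.0, 28.0, "F"),
            OccurrenceRecord("X", "u2", 17.0, 16.0, "F"),
        ]
        counts = stage_binned(occs, STAGES)
        # occurrences only in Old and Young, but the intervening stage fills
        assert counts.count("Mid", "F") == 1

    def test_empty_occurrences_zero_table(self):
        counts = stage_binned([], STAGES)
        assert counts.table.values.sum() == 0

    def test_single_stage_tally_equivalence(self, rng):
        """With single-stage occurrences, range-through = a plain tally."""
        taxa = [f"s{i}" for i in range(12)]
        occs = []
        plain = {name: 0 for name in STAGES.names}
        for i, t in enumerate(taxa):
            name, old, young = STAGES.stages[int(rng.integers(3))]
            occs.append(OccurrenceRecord(t, f"u{i}", old - 0.5, young + 0.5, "F"))
            plain[name] += 1
        counts = stage_binned(occs, STAGES)
        for name in STAGES.names:
            assert counts.count(name, "F") == plain[name]

    def test_no_intersection_is_error(self):
        occs = [OccurrenceRecord("X", "u1", 50.0, 45.0, "F")]
        with pytest.raises(ChronosError, match="intersects no stage"):
            stage_binned(occs, STAGES)

    def test_groups_kept_separate(self):
        occs = [
            OccurrenceRecord("X", "u1", 29.0, 28.0, "F1"),
            OccurrenceRecord("Y", "u2", 29.0, 28.0, "F2"),
        ]
        counts = stage_binned(occs, STAGES)
        assert counts.count("Old", "F1") == 1
        assert counts.count("Old", "F2") == 1


def test_min_max_bracketing_on_random_records(rng):
    """min_count <= max_count on every slice for random simulated inputs."""
    from paleodiv.synthetic import SimConfig, simulate_record

    for trial in range(50):
        rec = simulate_record(
            SimConfig(n_tips=6, n_characters=10, seed=int(rng.integers(2**31)))
        )
        if not rec.ranges:
            continue
        ranges = {r.taxon: r for r in rec.ranges}
        tree = _prune_to(rec.tree, set(ranges))
        if tree is None or tree.n_leaves < 2:
            continue
        curve = richness_curves(tree, ranges, t_start=36.0, t_end=5.0, dt=0.5)
        assert np.all(curve.min_count <= curve.max_count)
        assert np.all(curve.max_count <= len(ranges))


def _prune_to(tree, keep):
    """Drop leaves not in ``keep``; suppress resulting degree-1 internals."""
    from paleodiv.trees import PhyloTree

    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(t.postorder()):
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.children and node.label is None and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                idx = node.parent.children.index(node)
                node.parent.children[idx] = child
                child.parent = node.parent
                changed = True
    root = t.root
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    if root.is_leaf and root.label not in keep:
        return None
    return PhyloTree(root)


def test_richness_plot_smoke(tmp_path):
    from paleodiv.chronos import plot_richness

    tree = parse_newick("(A,B);")
    ranges = [sr("A", 20, 20, 10, 10), sr("B", 18, 18, 9, 9)]
    curve = richness_curves(tree, ranges, t_start=25.0, t_end=5.0, dt=0.5)
    out = tmp_path / "curve.png"
    plot_richness(curve, str(out), title="test")
    assert out.stat().st_size > 0
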