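"""Level consensus, anchor propagation and the two labeling approaches."""

import numpy as np
import pytest

from spinepost import (
    CorruptionSpec,
    LabelMap,
    LabelingError,
    RefineConfig,
    VertebraLevel,
    combined_approach,
    corrupt_prediction,
    level_consensus,
    propagate_labels,
    sequential_approach,
)

from conftest import TEST_SPACING, make_phantom, stacked_cubes_seg


def level_map_for(seg, codes):
    """Level-coded map painting each instance with the given code."""
    lvl = np.zeros(seg.labels.shape, dtype=np.int16)
    for inst_id, code in zip(seg.table["instance_id"], codes):
        lvl[seg.labels == inst_id] = code
    return LabelMap(lvl, spacing=seg.spacing, semantics="level")


class TestLevelConsensus:
    def test_unanimous_instance(self):
        seg = stacked_cubes_seg(1)
        lvl = level_map_for(seg, [13])
        level, conf = level_consensus(seg.mask(1), lvl)
        assert level == VertebraLevel.from_name("L1")
        assert conf == 1.0

    def test_fractional_consensus_by_voxel_count(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[0, 0, :] = True  # 10 voxels
        lvl = np.zeros((10, 10, 10), dtype=np.int16)
        lvl[0, 0, :6] = 7   # 60% T7
        lvl[0, 0, 6:] = 8   # 40% T8
        level, conf = level_consensus(mask, LabelMap(lvl, semantics="level"))
        assert level.name == "T7"
        assert conf == pytest.approx(0.6)

    def test_no_overlap_returns_none(self):
        mask = np.ones((4, 4, 4), bool)
        lvl = LabelMap(np.zeros((4, 4, 4), dtype=np.int16), semantics="level")
        assert level_consensus(mask, lvl) == (None, 0.0)

    def test_anchor_threshold_is_exact(self):
        # 950/1000 voxels agreeing is an anchor, 949/1000 is not
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        lvl = np.zeros(1000, dtype=np.int16)
        for agreeing, expect_anchor in ((950, True), (949, False)):
            lvl[:] = 8
            lvl[:1000 - agreeing] = 9
            m = LabelMap(np.resize(lvl, (10, 10, 10)), semantics="level")
            level, conf = level_consensus(mask, m)
            assert bool(conf >= 0.95) is expect_anchor


class TestPropagateLabels:
    def test_single_middle_anchor_counts_both_ways(self):
        seg = stacked_cubes_seg(5)
        consensus = [(None, 0.0)] * 5
        consensus[2] = (VertebraLevel.from_name("T8"), 1.0)
        out = propagate_labels(seg, consensus)
        assert list(out.table["level_name"]) == ["T6", "T7", "T8", "T9", "T10"]
        assert list(out.table["anchor"]) == [False, False, True, False, False]

    def test_consistent_anchors_reproduce_themselves(self):
        seg = stacked_cubes_seg(4)
        codes = [9, 10, 11, 12]
        consensus = [(VertebraLevel(c), 1.0) for c in codes]
        out = propagate_labels(seg, consensus)
        assert list(out.table["level_code"]) == codes
        assert out.table["anchor"].all()

    def test_conflicting_anchors_resolved_by_confidence(self):
        seg = stacked_cubes_seg(3)
        # inferior anchor is more confident and implies T5,T6,T7;
        # the superior anchor claims T9 and is overridden
        consensus = [(VertebraLevel.from_name("T9"), 0.95),
                     (None, 0.0),
                     (VertebraLevel.from_name("T7"), 0.99)]
        out = propagate_labels(seg, consensus)
        assert list(out.table["level_name"]) == ["T5", "T6", "T7"]
        assert any(p.get("action") == "override_anchor" for p in out.provenance)

    def test_confidence_tie_goes_to_superior_anchor(self):
        seg = stacked_cubes_seg(3)
        consensus = [(VertebraLevel.from_name("T9"), 1.0),
                     (None, 0.0),
                     (VertebraLevel.from_name("T7"), 1.0)]
        out = propagate_labels(seg, consensus)
        assert list(out.table["level_name"]) == ["T9", "T10", "T11"]

    def test_no_anchor_fails_loudly(self):
        seg = stacked_cubes_seg(3)
        consensus = [(VertebraLevel(5), 0.80), (None, 0.0), (VertebraLevel(7), 0.94)]
        with pytest.raises(LabelingError, match="anchor"):
            propagate_labels(seg, consensus)

    def test_propagation_past_t1_fails(self):
        seg = stacked_cubes_seg(4)
        consensus = [(None, 0.0)] * 4
        consensus[3] = (VertebraLevel.from_name("T2"), 1.0)  # T-1 implied above
        with pytest.raises(LabelingError, match="T1"):
            propagate_labels(seg, consensus)

    def test_levels_strictly_increase_craniocaudally(self):
        seg = stacked_cubes_seg(6)
        consensus = [(None, 0.0)] * 6
        consensus[0] = (VertebraLevel.from_name("T4"), 0.97)
        out = propagate_labels(seg, consensus)
        codes = out.table["level_code"].to_numpy()
        assert np.all(np.diff(codes) == 1)


class TestApproaches:
    def test_clean_phantom_both_approaches_agree_with_truth(self):
        _, gt, table = make_phantom(n=6, first_level="T9", seed=20)
        binary, level = corrupt_prediction(gt, table, CorruptionSpec(seed=0))
        seq = sequential_approach(binary, level)
        comb = combined_approach(level)
        for seg in (seq, comb):
            assert list(seg.table["level_code"]) == list(table["level_code"])
            assert seg.table["anchor"].all()
        assert np.array_equal(seq.labels, comb.labels)
        assert np.array_equal(seq.to_level_labelmap().values,
                              comb.to_level_labelmap().values)

    def test_sequential_geometry_comes_from_binary_only(self):
        _, gt, table = make_phantom(n=5, seed=21)
        binary, level = corrupt_prediction(
            gt, table, CorruptionSpec(dropout_fraction=0.1, seed=1))
        # hand the approach a clean level map: geometry must still match binary
        _, clean_level = corrupt_prediction(gt, table, CorruptionSpec(seed=0))
        seg = sequential_approach(binary, clean_level)
        assert np.array_equal(seg.binary(), binary.values > 0)

    def test_fusion_offsets_exactly_one_side_by_one(self):
        _, gt, table = make_phantom(n=7, first_level="T6", seed=22)
        binary, level = corrupt_prediction(
            gt, table, CorruptionSpec(fuse_pairs=((3, 4),), seed=2))
        seg = sequential_approach(binary, level,
                                  RefineConfig(split_enabled=False))
        assert seg.n_instances == 6
        true_codes = list(table["level_code"])
        got = list(seg.table["level_code"])
        # above the fusion: unchanged; merged: upper level; below: one too low
        assert got[:3] == true_codes[:3]
        assert got[3:] == [c - 1 for c in true_codes[4:]]

    def test_islands_do_not_reach_the_output(self):
        _, gt, table = make_phantom(n=5, seed=23)
        binary, level = corrupt_prediction(
            gt, table, CorruptionSpec(n_spurious_islands=3, seed=3))
        seg = sequential_approach(binary, level)
        assert seg.n_instances == 5
        assert not np.any(seg.binary() & (gt.values == 0))

    def test_combined_splits_touching_levels(self):
        _, gt, table = make_phantom(n=5, seed=24)
        _, level = corrupt_prediction(
            gt, table, CorruptionSpec(fuse_pairs=((2, 3),), seed=4))
        seg = combined_approach(level)
        assert seg.n_instances == 5
        assert list(seg.table["level_code"]) == list(table["level_code"])

    def test_misaligned_grids_rejected(self):
        _, gt, table = make_phantom(n=5, seed=25)
        binary, level = corrupt_prediction(gt, table, CorruptionSpec(seed=0))
        small = LabelMap(level.values[:-2], spacing=level.spacing, semantics="level")
        with pytest.raises(ValueError, match="misaligned"):
            sequential_approach(binary, small)
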