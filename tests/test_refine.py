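"""Instance refinement: components, candidate filtering, watershed splitting."""

import numpy as np
import pytest
from scipy import ndimage

from spinepost import (
    CorruptionSpec,
    RefineConfig,
    corrupt_prediction,
    extract_components,
    filter_candidates,
    refine_binary,
    split_fused,
)

from conftest import TEST_SPACING, binary_map, make_phantom, seg_from_labels
from oracles import flood_fill_components


class TestExtractComponents:
    def test_empty_map_gives_empty_segmentation(self):
        seg = extract_components(binary_map(np.zeros((5, 5, 5))))
        assert seg.n_instances == 0
        assert seg.table.empty

    def test_two_disjoint_cubes_counted_exactly(self):
        grid = np.zeros((10, 10, 12), dtype=np.int16)
        grid[1:4, 1:4, 8:11] = 1   # superior 3x3x3 cube
        grid[1:5, 1:5, 1:3] = 1    # inferior 4x4x2 slab
        seg = extract_components(binary_map(grid))
        assert seg.n_instances == 2
        # id 1 is the superior cube
        assert seg.table.set_index("instance_id")["n_voxels"].to_dict() == {1: 27, 2: 32}

    def test_diagonal_corner_contact_depends_on_connectivity(self):
        grid = np.zeros((6, 6, 6), dtype=np.int16)
        grid[0:2, 0:2, 0:2] = 1
        grid[2:4, 2:4, 2:4] = 1  # touches only at a corner
        assert extract_components(binary_map(grid), connectivity=26).n_instances == 1
        assert extract_components(binary_map(grid), connectivity=6).n_instances == 2

    def test_rejects_non_binary(self):
        from spinepost import LabelMap

        m = LabelMap(np.ones((3, 3, 3), dtype=np.int32) * 2, semantics="instance")
        with pytest.raises(ValueError):
            extract_components(m)

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        grid = (rng.random((12, 13, 14)) < 0.25).astype(np.int16)
        seg = extract_components(binary_map(grid), connectivity=connectivity)
        oracle = flood_fill_components(grid, connectivity)
        assert seg.n_instances == len(oracle)
        ours = {
            frozenset(zip(*np.nonzero(seg.labels == i)))
            for i in seg.table["instance_id"]
        }
        assert ours == set(oracle)


class TestFilterCandidates:
    def test_clean_phantom_fully_retained(self, clean_phantom):
        _, gt, _ = clean_phantom
        seg = extract_components(gt.binarized())
        out = filter_candidates(seg)
        assert out.n_instances == 5
        assert np.array_equal(out.binary(), seg.binary())

    def test_small_island_removed_by_size(self, clean_phantom):
        _, gt, _ = clean_phantom
        grid = (gt.values > 0).astype(np.int16)
        grid[2:5, 2:5, 2:5] = 1  # ~90 mm3 islet, far below the 5 cm3 minimum
        seg = extract_components(binary_map(grid, TEST_SPACING))
        out = filter_candidates(seg)
        assert out.n_instances == 5
        assert out.binary().sum() == (gt.values > 0).sum()
        assert any(p.get("action") == "remove" and p.get("reason") == "size"
                   for p in out.provenance)

    def test_off_axis_blob_removed_by_axis_distance(self):
        # wide volume so a size-passing blob can sit 40 mm off the spine axis
        _, gt, _ = make_phantom(n=5, seed=1, lateral_margin_mm=50.0)
        grid = (gt.values > 0).astype(np.int16)
        # ~8.6 cm3 blob (passes the size rule) 40+ mm lateral to the axis
        grid[2:12, 2:12, 30:47] = 1
        seg = extract_components(binary_map(grid, TEST_SPACING))
        out = filter_candidates(seg)
        assert out.n_instances == 5
        assert any(p.get("reason") == "axis_distance" for p in out.provenance)

    def test_edge_truncated_vertebra_kept_by_exemption(self):
        _, gt, table = make_phantom(n=5, seed=2, partial_at_edges=True)
        seg = extract_components(gt.binarized())
        vols = seg.table.set_index("instance_id")["volume_mm3"]
        # set the minimum between the truncated and the interior body volume,
        # so the truncated body passes only through the edge-contact exemption
        min_size = (vols[1] + vols[3]) / 2
        assert vols[1] < min_size < vols[3]
        config = RefineConfig(min_size_mm3=min_size, edge_min_size_mm3=1_000.0)
        out = filter_candidates(seg, config)
        assert out.n_instances == 5
        # without the exemption the truncated bodies are dropped
        strict = RefineConfig(min_size_mm3=min_size, edge_min_size_mm3=min_size)
        assert filter_candidates(seg, strict).n_instances == 3


class TestSplitFused:
    def test_fused_pair_partition_is_voxel_exact(self):
        _, gt, table = make_phantom(n=5, seed=3)
        binary, _ = corrupt_prediction(gt, table, CorruptionSpec(fuse_pairs=((2, 3),), seed=1))
        seg = extract_components(binary)
        assert seg.n_instances == 4
        fused_mask = seg.mask(2)
        out = split_fused(seg)
        assert out.n_instances == 5
        parts = (out.mask(2) | out.mask(3))
        assert np.array_equal(parts, fused_mask)
        assert np.array_equal(out.binary(), seg.binary())

    def test_chain_of_three_recovered_in_order(self):
        _, gt, table = make_phantom(n=5, seed=4)
        binary, _ = corrupt_prediction(
            gt, table, CorruptionSpec(fuse_pairs=((2, 3), (3, 4)), seed=1))
        seg = extract_components(binary)
        assert seg.n_instances == 3
        out = split_fused(seg)
        assert out.n_instances == 5
        z = out.table["centroid_z_mm"].to_numpy()
        assert np.all(np.diff(z) < 0)  # ids ordered superior to inferior

    def test_clean_instances_pass_through_unchanged(self, clean_phantom):
        _, gt, _ = clean_phantom
        seg = extract_components(gt.binarized())
        out = split_fused(seg)
        assert out.n_instances == seg.n_instances
        assert np.array_equal(out.labels, seg.labels)


class TestRefineBinary:
    def test_empty_input_empty_output(self):
        out = refine_binary(binary_map(np.zeros((6, 6, 6))))
        assert out.n_instances == 0

    def test_corrupted_phantom_recovers_instance_count(self):
        _, gt, table = make_phantom(n=5, seed=5)
        binary, _ = corrupt_prediction(
            gt, table,
            CorruptionSpec(fuse_pairs=((3, 4),), n_spurious_islands=2, seed=2))
        out = refine_binary(binary)
        assert out.n_instances == 5
        assert not np.any(out.binary() & ~(binary.values > 0))

    def test_never_adds_foreground(self):
        for seed in range(5):
            _, gt, table = make_phantom(n=4, seed=seed, first_level="T7")
            binary, _ = corrupt_prediction(
                gt, table,
                CorruptionSpec(boundary_noise_mm=1.0, dropout_fraction=0.05,
                               n_spurious_islands=1, seed=seed))
            out = refine_binary(binary)
            assert not np.any(out.binary() & ~(binary.values > 0))

    def test_idempotent_on_own_output(self):
        _, gt, table = make_phantom(n=5, seed=6)
        binary, _ = corrupt_prediction(
            gt, table, CorruptionSpec(fuse_pairs=((2, 3),), n_spurious_islands=1, seed=3))
        once = refine_binary(binary)
        again = refine_binary(binary_map(once.binary().astype(np.int16), TEST_SPACING))
        assert np.array_equal(once.labels, again.labels)
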