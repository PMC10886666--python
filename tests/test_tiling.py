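"""Patch-grid extraction, tissue filtering, clusters, and the pyramid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsimil import tiling
from wsimil.tiling import (
    MultiResInstance,
    PatchRecord,
    assign_cluster,
    build_multires_instances,
    extract_grid,
    filter_tissue,
    manifest_frame,
    records_from_frame,
    resize_to_256,
    subdivide,
    tile_wsi,
)


class TestExtractGrid:
    def test_grid_geometry_and_fractions(self, toy_image, toy_mask):
        patches = extract_grid(toy_image, toy_mask, "w1")
        assert len(patches) == 4
        by_pos = {(p.row, p.col): p for p in patches}
        assert by_pos[(0, 0)].stroma_frac == 1.0
        assert by_pos[(0, 1024)].epithelium_frac == 1.0
        assert by_pos[(1024, 0)].tissue_frac == pytest.approx(0.5)
        p = by_pos[(1024, 1024)]
        assert p.stroma_frac == pytest.approx(0.5)
        assert p.epithelium_frac == pytest.approx(0.5)

    def test_all_background_mask_gives_zero_tissue(self):
        mask = np.zeros((1024, 1024), dtype=np.uint8)
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        (patch,) = extract_grid(img, mask)
        assert patch.tissue_frac == 0.0

    def test_dimension_mismatch_rejected(self, toy_mask):
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="dimensions differ"):
            extract_grid(img, toy_mask)

    def test_indivisible_size_rejected(self):
        mask = np.zeros((1000, 1000), dtype=np.uint8)
        img = np.zeros((1000, 1000, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="does not divide"):
            extract_grid(img, mask)


class TestFilterTissue:
    def _patch(self, tissue: float) -> PatchRecord:
        return PatchRecord(wsi_id="w", level_px=1024, row=0, col=0,
                           stroma_frac=tissue, epithelium_frac=0.0)

    def test_boundary_is_inclusive(self):
        # "at least 50% tissue": 0.49 is out, 0.50 stays
        assert filter_tissue([self._patch(0.49)]) == []
        kept = filter_tissue([self._patch(0.50)])
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_tissue([]) == []

    @given(st.lists(st.floats(0, 1), max_size=30),
           st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_grows_selection(self, fracs, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        patches = [self._patch(f) for f in fracs]
        kept_hi = {id(p) for p in filter_tissue(patches, hi)}
        assert kept_hi <= {id(p) for p in filter_tissue(patches, lo)}


class TestSubdivide:
    def test_children_tile_parent(self, toy_image, toy_mask):
        parent = extract_grid(toy_image, toy_mask, "w")[3]
        children = subdivide(parent, toy_mask)
        assert len(children) == 4
        cells = {(c.row, c.col) for c in children}
        half = 512
        assert cells == {(parent.row + dr, parent.col + dc)
                         for dr in (0, half) for dc in (0, half)}
        assert all(c.parent_id == parent.patch_id for c in children)
        # pixel-count conservation: child fractions average to the parent's
        assert np.mean([c.stroma_frac for c in children]) == pytest.approx(
            parent.stroma_frac)
        assert np.mean([c.epithelium_frac for c in children]) == pytest.approx(
            parent.epithelium_frac)

    def test_recursion_yields_16_leaves(self, toy_image, toy_mask):
        parent = extract_grid(toy_image, toy_mask, "w")[0]
        leaves = [leaf for mid in subdivide(parent, toy_mask)
                  for leaf in subdivide(mid, toy_mask)]
        assert len(leaves) == 16
        assert {l.level_px for l in leaves} == {256}
        # the union of leaf extents is exactly the parent extent
        covered = np.zeros((1024, 1024), dtype=bool)
        for l in leaves:
            covered[l.row - parent.row : l.row - parent.row + 256,
                    l.col - parent.col : l.col - parent.col + 256] ^= True
        assert covered.all()

    def test_leaf_cannot_be_subdivided(self, toy_mask):
        leaf = PatchRecord(wsi_id="w", level_px=256, row=0, col=0,
                           stroma_frac=1.0, epithelium_frac=0.0)
        with pytest.raises(ValueError, match="leaves"):
            subdivide(leaf, toy_mask)


class TestAssignCluster:
    @pytest.mark.parametrize(
        "stroma,epi,expected",
        [(0.6, 0.2, "C1"), (0.2, 0.7, "C3"), (0.5, 0.5, "C2"),
         (0.0, 0.0, "C2"), (0.51, 0.0, "C1"), (0.0, 0.51, "C3")],
    )
    def test_rule(self, stroma, epi, expected):
        assert assign_cluster(stroma, epi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_cluster(1.2, 0.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_total_function(self, s, e):
        assert assign_cluster(s, e) in {"C1", "C2", "C3"}


class TestResize:
    def test_constant_image_stays_constant(self):
        img = np.full((1024, 1024, 3), 77, dtype=np.uint8)
        out = resize_to_256(img)
        assert out.shape == (256, 256, 3)
        assert np.all(out == 77)

    def test_256_input_is_identity(self):
        img = np.arange(256 * 256, dtype=np.uint8).reshape(256, 256) % 255
        assert resize_to_256(img) is img

    def test_checkerboard_downsamples_to_mean_gray(self):
        tile = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        img = np.tile(tile, (512, 512))
        out = resize_to_256(img)
        assert abs(out.astype(float).mean() - img.astype(float).mean()) < 1.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            resize_to_256(np.zeros((512, 256), dtype=np.uint8))


class TestMultiRes:
    def _pyramid_with_features(self, toy_image, toy_mask, d):
        records = tile_wsi(toy_image, toy_mask, "w")
        rng = np.random.default_rng(0)
        feats = {r.patch_id: rng.normal(size=d) for r in records}
        return records, feats

    @pytest.mark.parametrize("d", [2, 64])
    def test_concatenated_length_is_3d(self, toy_image, toy_mask, d):
        records, feats = self._pyramid_with_features(toy_image, toy_mask, d)
        instances = build_multires_instances(records, feats)
        n_leaves = sum(1 for r in records if r.level_px == 256)
        assert len(instances) == n_leaves
        assert all(inst.feature.shape == (3 * d,) for inst in instances)

    def test_concatenation_order_leaf_parent_grandparent(self, toy_image, toy_mask):
        records, feats = self._pyramid_with_features(toy_image, toy_mask, 4)
        by_id = {r.patch_id: r for r in records}
        inst = build_multires_instances(records, feats)[0]
        leaf = by_id[inst.leaf_patch_id]
        parent = by_id[leaf.parent_id]
        grand = by_id[parent.parent_id]
        expected = np.concatenate(
            [feats[leaf.patch_id], feats[parent.patch_id], feats[grand.patch_id]])
        np.testing.assert_array_equal(inst.feature, expected)
        assert inst.cluster == grand.cluster

    def test_leaves_under_excluded_top_patches_are_absent(self, toy_mask):
        # the half-background top patch fails a 0.75 threshold
        img = np.zeros((*toy_mask.shape, 3), dtype=np.uint8)
        records = tile_wsi(img, toy_mask, "w", threshold=0.75)
        tops = [r for r in records if r.level_px == 1024]
        assert len(tops) == 3
        assert all(t.tissue_frac >= 0.75 for t in tops)
        leaves = [r for r in records if r.level_px == 256]
        assert len(leaves) == 3 * 16

    def test_missing_feature_is_reported_with_leaf_id(self, toy_image, toy_mask):
        records, feats = self._pyramid_with_features(toy_image, toy_mask, 4)
        missing = next(r for r in records if r.level_px == 512)
        del feats[missing.patch_id]
        with pytest.raises(RuntimeError, match="no feature vector"):
            build_multires_instances(records, feats)


def test_manifest_round_trip(toy_image, toy_mask):
    records = tile_wsi(toy_image, toy_mask, "w")
    frame = manifest_frame(records)
    back = records_from_frame(frame)
    assert [r.patch_id for r in back] == [r.patch_id for r in records]
    assert [r.cluster for r in back] == [r.cluster for r in records]
    assert [r.parent_id for r in back] == [r.parent_id for r in records]
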