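"""Mask algebra: thresholding, the small-group filter and the exclusive
pixel-class decomposition, checked against brute-force per-pixel oracles."""

import numpy as np
import pytest

from pixelplex.core import ChannelImage, GeometryError, MarkerMask
from pixelplex.masks import (
    MCM_MARKERS,
    MCM_MASK_MARKERS,
    DegenerateThresholdError,
    ThresholdSpec,
    aggregate_case,
    decompose_pixel_classes,
    mask_class_breakdown,
    remove_small_groups,
    restrict_cd206,
    threshold_channel,
    union_masks,
)


def _channel(arr, ps=0.3, name="CD68"):
    return ChannelImage(pixels=np.asarray(arr), pixel_size_um=ps, channel=name)


class TestThreshold:
    def test_all_zero_image_gives_empty_mask(self):
        m = threshold_channel(_channel(np.zeros((4, 4))), ThresholdSpec(threshold=10))
        assert m.positive_count == 0

    def test_strict_inequality_at_threshold(self):
        m = threshold_channel(_channel(np.full((4, 4), 7.0)), ThresholdSpec(threshold=7))
        assert m.positive_count == 0

    def test_enumerated_pixels_above_threshold(self):
        img = [[0, 50, 200], [200, 50, 0], [0, 0, 255]]
        m = threshold_channel(_channel(img), ThresholdSpec(threshold=100))
        assert m.positive_count == 3

    def test_otsu_on_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            threshold_channel(_channel(np.full((4, 4), 3.0)), ThresholdSpec(threshold="otsu"))

    def test_otsu_separates_two_level_image(self):
        img = np.zeros((10, 10))
        img[:3] = 1000.0
        m = threshold_channel(_channel(img), ThresholdSpec(threshold="otsu"))
        assert m.positive_count == 30


class TestSmallGroupFilter:
    def _mask_with_components(self):
        px = np.zeros((20, 40), dtype=bool)
        px[1:3, 1:5] = True        # 8 pixels -> removed
        px[6:9, 6:9] = True        # 9 pixels -> kept
        px[12:15, 12:16] = True    # 12 pixels -> kept
        return MarkerMask(pixels=px, pixel_size_um=0.3, label="CD68")

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_components_below_nine_removed(self, connectivity):
        spec = ThresholdSpec(threshold=0, min_group_size_px=9, connectivity=connectivity)
        out = remove_small_groups(self._mask_with_components(), spec)
        assert out.positive_count == 9 + 12

    def test_empty_mask_unchanged(self):
        m = MarkerMask(pixels=np.zeros((5, 5), bool), pixel_size_um=0.3, label="m")
        assert remove_small_groups(m, ThresholdSpec()).positive_count == 0

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_solid_nine_pixel_block_kept(self, connectivity):
        px = np.zeros((8, 8), dtype=bool)
        px[2:5, 2:5] = True
        m = MarkerMask(pixels=px, pixel_size_um=0.3, label="m")
        spec = ThresholdSpec(min_group_size_px=9, connectivity=connectivity)
        assert np.array_equal(remove_small_groups(m, spec).pixels, px)

    def test_idempotent_and_monotone_on_random_masks(self, random_mask_factory):
        rng = np.random.default_rng(42)
        spec = ThresholdSpec(min_group_size_px=9)
        for _ in range(100):
            m = random_mask_factory(rng, density=rng.uniform(0.05, 0.5))
            once = remove_small_groups(m, spec)
            twice = remove_small_groups(once, spec)
            assert np.array_equal(once.pixels, twice.pixels)
            assert once.positive_count <= m.positive_count


class TestUnionAndRestrict:
    def test_union_of_empty_masks_is_empty(self, mask_factory):
        assert union_masks([mask_factory([]), mask_factory([])]).positive_count == 0

    def test_union_idempotent_on_identical_masks(self, mask_factory):
        m = mask_factory([(1, 1), (2, 2)])
        u = union_masks([m, m])
        assert np.array_equal(u.pixels, m.pixels)

    def test_union_counts_set_union(self, mask_factory):
        a = mask_factory([(0, 0), (1, 1)])
        b = mask_factory([(1, 1), (2, 2)])
        assert union_masks([a, b]).positive_count == 3

    def test_union_label_is_mcm(self, mask_factory):
        assert union_masks([mask_factory([(0, 0)])]).label == "MCM_mask"

    def test_union_geometry_mismatch(self, mask_factory):
        with pytest.raises(GeometryError):
            union_masks([mask_factory([]), mask_factory([], shape=(9, 9))])

    def test_restrict_cd206(self, mask_factory):
        cd206 = mask_factory([(0, 0), (1, 1), (2, 2)], label="CD206")
        mcm = mask_factory([(1, 1), (2, 2), (3, 3)], label="MCM_mask")
        out = restrict_cd206(cd206, mcm)
        assert out.positive_count == 2
        disjoint = mask_factory([(5, 5)], label="MCM_mask")
        assert restrict_cd206(cd206, disjoint).positive_count == 0
        superset = mask_factory([(0, 0), (1, 1), (2, 2), (3, 3)], label="MCM_mask")
        assert np.array_equal(restrict_cd206(cd206, superset).pixels, cd206.pixels)


def _oracle_counts(marker_masks, reference):
    """Independent per-pixel enumeration over all 2^5 color patterns."""
    counts = {}
    rr, cc = np.nonzero(reference.pixels)
    for r, c in zip(rr, cc):
        pattern = tuple(m for m in MCM_MARKERS if marker_masks[m].pixels[r, c])
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def _oracle_label(pattern):
    if not pattern:
        return "none"
    return "P4,5" if len(pattern) >= 4 else "/".join(pattern)


class TestDecompose:
    def test_worked_three_marker_example(self, mask_factory):
        # A={p1,p2}, B={p2,p3}, C={p3}; reference = union (3 px)
        masks = {
            "CD68": mask_factory([(0, 0), (0, 1)], label="CD68"),
            "CD163": mask_factory([(0, 1), (0, 2)], label="CD163"),
            "CD206": mask_factory([], label="CD206"),
            "CD11b": mask_factory([(0, 2)], label="CD11b"),
            "CD11c": mask_factory([], label="CD11c"),
        }
        ref = union_masks([masks[m] for m in ("CD68", "CD163", "CD11b")])
        t = decompose_pixel_classes(masks, ref)
        assert t.counts["CD68"] == 1
        assert t.counts["CD68/CD163"] == 1
        assert t.counts["CD163/CD11b"] == 1
        assert sum(t.counts.values()) == 3
        assert t.percent("CD68") == pytest.approx(100 / 3)
        assert t.percent("P2,3,4,5") == pytest.approx(200 / 3)

    def test_two_identical_masks_all_double(self, mask_factory):
        m = mask_factory([(0, 0), (3, 3)], label="CD68")
        masks = {"CD68": m, "CD163": m.with_label("CD163"),
                 "CD206": mask_factory([], label="CD206"),
                 "CD11b": mask_factory([], label="CD11b"),
                 "CD11c": mask_factory([], label="CD11c")}
        t = decompose_pixel_classes(masks, union_masks([m]))
        assert t.counts["CD68"] == 0 and t.counts["CD163"] == 0
        assert t.percent("CD68/CD163") == pytest.approx(100.0)

    def test_disjoint_masks_have_no_multicolor(self, mask_factory):
        masks = {m: mask_factory([(i, i)], label=m) for i, m in enumerate(MCM_MARKERS)}
        ref = union_masks([masks[m] for m in MCM_MASK_MARKERS])
        masks["CD206"] = restrict_cd206(masks["CD206"], ref)
        t = decompose_pixel_classes(masks, ref)
        assert t.percent("P2,3,4,5") == 0.0
        singles = sum(t.percent(m) for m in MCM_MASK_MARKERS)
        assert singles == pytest.approx(100.0)

    def test_empty_reference_flags_undefined_percentages(self, mask_factory):
        masks = {m: mask_factory([], label=m) for m in MCM_MARKERS}
        t = decompose_pixel_classes(masks, mask_factory([], label="MCM_mask"))
        assert t.reference_pixel_count == 0
        assert not t.percent_defined
        assert np.isnan(t.percent("CD68"))

    def test_matches_enumeration_oracle_on_random_instances(self, random_mask_factory):
        rng = np.random.default_rng(7)
        for _ in range(50):
            masks = {m: random_mask_factory(rng, density=rng.uniform(0.05, 0.4), label=m)
                     for m in MCM_MARKERS}
            ref = union_masks([masks[m] for m in MCM_MASK_MARKERS])
            masks["CD206"] = restrict_cd206(masks["CD206"], ref)
            t = decompose_pixel_classes(masks, ref)
            oracle = {}
            for pattern, n in _oracle_counts(masks, ref).items():
                lbl = _oracle_label(pattern)
                oracle[lbl] = oracle.get(lbl, 0) + n
            for lbl, n in oracle.items():
                assert t.counts[lbl] == n
            assert sum(t.counts.values()) == ref.positive_count

    def test_double_class_symmetric_in_marker_order(self, random_mask_factory):
        rng = np.random.default_rng(11)
        a = random_mask_factory(rng, density=0.3, label="CD68")
        b = random_mask_factory(rng, density=0.3, label="CD163")
        empty = {m: MarkerMask(pixels=np.zeros((64, 64), bool), pixel_size_um=0.3, label=m)
                 for m in ("CD206", "CD11b", "CD11c")}
        masks = {"CD68": a, "CD163": b, **empty}
        swapped = {"CD68": MarkerMask(pixels=b.pixels, pixel_size_um=0.3, label="CD68"),
                   "CD163": MarkerMask(pixels=a.pixels, pixel_size_um=0.3, label="CD163"),
                   **empty}
        ref = union_masks([a, b])
        t1 = decompose_pixel_classes(masks, ref)
        t2 = decompose_pixel_classes(swapped, ref)
        assert t1.counts["CD68/CD163"] == t2.counts["CD68/CD163"]


class TestAnchorBreakdown:
    def test_anchor_single_and_pair_percentages(self, mask_factory):
        masks = {
            "CD68": mask_factory([(0, 0), (0, 1)], label="CD68"),
            "CD163": mask_factory([(0, 1)], label="CD163"),
            "CD206": mask_factory([], label="CD206"),
            "CD11b": mask_factory([], label="CD11b"),
            "CD11c": mask_factory([], label="CD11c"),
        }
        t = mask_class_breakdown("CD68", masks)
        assert t.percent("CD68") == pytest.approx(50.0)
        assert t.percent("CD68/CD163") == pytest.approx(50.0)

    def test_empty_anchor_mask_undefined(self, mask_factory):
        masks = {m: mask_factory([], label=m) for m in MCM_MARKERS}
        t = mask_class_breakdown("CD68", masks)
        assert not t.percent_defined

    def test_all_masks_identical_forces_residual(self, mask_factory):
        base = mask_factory([(0, 0), (1, 1)], label="CD68")
        masks = {m: base.with_label(m) for m in MCM_MARKERS}
        t = mask_class_breakdown("CD68", masks)
        assert t.percent("P4,5") == pytest.approx(100.0)


class TestCaseAggregation:
    def _table(self, pct, ref=100):
        from pixelplex.masks import PixelClassTable

        count = int(round(pct * ref / 100))
        return PixelClassTable(tile_id="t", reference_label="MCM_mask",
                               reference_pixel_count=ref, counts={"CD68": count})

    def test_single_tile_mean_equals_tile_sd_zero(self):
        s = aggregate_case([self._table(40.0)], case_id="c")
        row = s.stats.set_index("class_label").loc["CD68"]
        assert row["mean_percent"] == pytest.approx(40.0)
        assert row["sd_percent"] == 0.0
        assert row["n_tiles"] == 1

    def test_two_tile_mean_and_sample_sd(self):
        s = aggregate_case([self._table(20.0), self._table(40.0)])
        row = s.stats.set_index("class_label").loc["CD68"]
        assert row["mean_percent"] == pytest.approx(30.0)
        assert row["sd_percent"] == pytest.approx(14.142135, abs=1e-4)

    def test_undefined_tiles_excluded_from_mean(self):
        s = aggregate_case([self._table(20.0), self._table(40.0), self._table(0, ref=0)])
        row = s.stats.set_index("class_label").loc["CD68"]
        assert row["n_tiles"] == 2
        assert row["mean_percent"] == pytest.approx(30.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_case([])
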