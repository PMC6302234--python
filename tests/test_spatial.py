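"""Region densities, tumor:stroma ratios, border nuclei and EDT
distances, checked against geometry and brute-force oracles."""

import numpy as np
import pytest

from pixelplex.core import MarkerMask
from pixelplex.phenotyping import NucleusRecord
from pixelplex.spatial import (
    BorderBandSpec,
    density_under_mask,
    distance_histogram,
    find_border_nuclei,
    nearest_class_distance,
    tumor_stroma_ratio,
)


def _mask(px, ps=0.3, label="m"):
    return MarkerMask(pixels=px, pixel_size_um=ps, label=label)


def _disk(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _nucleus(r, c, nid=1):
    return NucleusRecord(nucleus_id=nid, centroid_px=(float(r), float(c)),
                         area_px=10, equivalent_radius_px=1.8)


class TestDensity:
    def test_disjoint_class_gives_zero(self):
        region = _mask(_disk((32, 32), (16, 16), 8))
        cls = _mask(_disk((32, 32), (2, 2), 1))
        assert density_under_mask(cls, region) == 0.0

    def test_class_covering_region_gives_one(self):
        region = _mask(_disk((32, 32), (16, 16), 5))
        cls = _mask(_disk((32, 32), (16, 16), 10))
        assert density_under_mask(cls, region) == 1.0

    def test_fractional_density(self):
        region_px = np.zeros((32, 32), dtype=bool)
        region_px[:10, :20] = True  # 200 px
        cls_px = np.zeros((32, 32), dtype=bool)
        cls_px[0, :20] = True
        cls_px[1, :9] = True  # 29 px inside
        assert density_under_mask(_mask(cls_px), _mask(region_px)) == pytest.approx(0.145)

    def test_empty_region_is_undefined_not_zero(self):
        region = _mask(np.zeros((8, 8), bool))
        cls = _mask(np.ones((8, 8), bool))
        assert density_under_mask(cls, region) is None


class TestTumorStromaRatio:
    def _setup(self, tumor_px, stroma_cls, tumor_cls):
        tissue = np.ones((40, 40), dtype=bool)
        tumor = np.zeros((40, 40), dtype=bool)
        tumor.flat[:tumor_px] = True
        cls = np.zeros((40, 40), dtype=bool)
        cls.flat[:tumor_cls] = True
        flat = np.nonzero(~tumor.ravel())[0]
        cls.ravel()[flat[:stroma_cls]] = True
        return _mask(cls), _mask(tumor), _mask(tissue)

    def test_equal_densities_give_unity(self):
        cls, tumor, tissue = self._setup(400, stroma_cls=120, tumor_cls=40)
        # tumor 40/400 = 0.1; stroma 120/1200 = 0.1
        assert tumor_stroma_ratio(cls, tumor, tissue) == pytest.approx(1.0)

    def test_worked_ratio(self):
        cls, tumor, tissue = self._setup(100, stroma_cls=75, tumor_cls=10)
        # tumor 10/100 = 0.1; stroma 75/1500 = 0.05
        assert tumor_stroma_ratio(cls, tumor, tissue) == pytest.approx(2.0)

    def test_class_confined_to_tumor_is_undefined(self):
        cls, tumor, tissue = self._setup(100, stroma_cls=0, tumor_cls=10)
        assert tumor_stroma_ratio(cls, tumor, tissue) is None

    def test_density_bookkeeping_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tissue = np.ones((64, 64), dtype=bool)
            tumor = rng.random((64, 64)) < 0.3
            cls = rng.random((64, 64)) < 0.2
            in_tumor = int((cls & tumor).sum())
            in_stroma = int((cls & ~tumor).sum())
            assert in_tumor + in_stroma == int((cls & tissue).sum())


class TestBorderNuclei:
    def test_centroid_outside_tumor_excluded(self):
        tumor = _mask(_disk((128, 128), (64, 64), 40))
        out = find_border_nuclei([_nucleus(5, 5)], tumor, BorderBandSpec(10.0))
        assert out == []

    def test_disk_tumor_band_selects_annulus(self):
        """30 um tumor disk, 10 um band: nuclei at radial distance
        20-30 um are selected, deeper ones are not."""
        ps = 0.3
        tumor = _mask(_disk((256, 256), (128, 128), 30 / ps), ps=ps)
        selected = find_border_nuclei(
            [_nucleus(128, 128 + 25 / ps, nid=1),   # 25 um from center
             _nucleus(128, 128 + 10 / ps, nid=2),   # 10 um: deep interior
             _nucleus(128, 128 + 35 / ps, nid=3)],  # outside tumor
            tumor, BorderBandSpec(10.0))
        assert [n.nucleus_id for n in selected] == [1]

    def test_full_tile_tumor_has_no_border(self):
        """The tile edge is not a tumor border: a tumor filling the tile
        selects no nuclei."""
        tumor = _mask(np.ones((64, 64), dtype=bool), ps=0.3)
        assert find_border_nuclei([_nucleus(32, 32)], tumor, BorderBandSpec(5.0)) == []

    def test_empty_tumor_mask(self):
        tumor = _mask(np.zeros((64, 64), bool))
        assert find_border_nuclei([_nucleus(3, 3)], tumor, BorderBandSpec(5.0)) == []


class TestNearestDistance:
    def test_on_pixel_gives_zero(self):
        px = np.zeros((32, 32), dtype=bool)
        px[10, 10] = True
        assert nearest_class_distance((10, 10), _mask(px)) == 0.0

    def test_ten_pixels_along_row(self):
        px = np.zeros((32, 32), dtype=bool)
        px[5, 25] = True
        assert nearest_class_distance((5, 15), _mask(px, ps=0.3)) == pytest.approx(3.0)

    def test_empty_mask_is_missing(self):
        assert nearest_class_distance((3, 3), _mask(np.zeros((8, 8), bool))) is None

    def test_matches_brute_force_on_random_masks(self):
        """EDT distance equals the exhaustive minimum over positive
        pixels, to 1e-6 um, on 50 random 64x64 masks."""
        rng = np.random.default_rng(9)
        ps = 0.3
        for _ in range(50):
            px = rng.random((64, 64)) < 0.02
            if not px.any():
                continue
            point = (int(rng.integers(64)), int(rng.integers(64)))
            got = nearest_class_distance(point, _mask(px, ps=ps))
            rr, cc = np.nonzero(px)
            brute = np.sqrt((rr - point[0]) ** 2 + (cc - point[1]) ** 2).min() * ps
            assert got == pytest.approx(brute, abs=1e-6)


class TestDistanceHistogram:
    def test_worked_binning(self):
        h = distance_histogram([0.0, 5.0, 15.0, 25.0])
        assert h.bin_labels == ["0", "(0,20]", "(20,40]"]
        assert h.percents == [25.0, 50.0, 25.0]
        assert h.mean_distance_um == pytest.approx(11.25)

    def test_all_in_first_noncontact_bin(self):
        h = distance_histogram([1.0, 5.0, 19.9])
        assert h.percents[1] == 100.0

    def test_exact_twenty_falls_in_lower_bin(self):
        h = distance_histogram([20.0])
        assert h.bin_labels[1] == "(0,20]"
        assert h.percents[1] == 100.0

    def test_missing_values_dropped_and_counted(self):
        h = distance_histogram([None, 5.0, None])
        assert h.n_measured == 1 and h.n_missing == 2
        assert sum(h.percents) == pytest.approx(100.0)

    def test_empty_input(self):
        h = distance_histogram([None])
        assert h.n_measured == 0 and np.isnan(h.mean_distance_um)

    def test_percents_sum_to_hundred_on_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ds = list(rng.uniform(0, 200, size=rng.integers(1, 40)))
            h = distance_histogram(ds)
            assert sum(h.percents) == pytest.approx(100.0, abs=1e-9)
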