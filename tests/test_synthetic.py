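"""Simulator contracts: determinism, bookkeeping, co-expression
statistics, truth-mask consistency and the chromogenic rendition."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage, stats

from pixelplex.masks import MCM_MARKERS
from pixelplex.synthetic import (
    AcquisitionSpec,
    MorphologySpec,
    NoiseSpec,
    PlacementError,
    SimulationConfig,
    generate_tile,
)


def _small_config(**kw):
    base = dict(
        tile_height_px=256, tile_width_px=256,
        n_tumor_regions=0, tumor_area_fraction=0.0,
        n_tcells=5, n_macrophages=5, n_myeloid=5, seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_same_seed_gives_bit_identical_tiles():
    t1 = generate_tile(_small_config())
    t2 = generate_tile(_small_config())
    for ch in t1.if_channels:
        assert np.array_equal(t1.if_channels[ch].pixels, t2.if_channels[ch].pixels)
    for ch in t1.ihc_channels:
        assert np.array_equal(t1.ihc_channels[ch].pixels, t2.ihc_channels[ch].pixels)
    for m in t1.truth_marker_masks:
        assert np.array_equal(t1.truth_marker_masks[m].pixels,
                              t2.truth_marker_masks[m].pixels)


def test_different_seeds_differ():
    t1 = generate_tile(_small_config(seed=1))
    t2 = generate_tile(_small_config(seed=2))
    assert not np.array_equal(t1.if_channels["DAPI"].pixels, t2.if_channels["DAPI"].pixels)


def test_cell_count_bookkeeping():
    cfg = _small_config(n_tcells=0, n_myeloid=0, n_macrophages=50,
                        tile_height_px=512, tile_width_px=512)
    tile = generate_tile(cfg)
    assert len(tile.truth_cells) == 50
    assert all(c.cell_type == "macrophage" for c in tile.truth_cells)


def test_tcells_have_no_processes_and_cd3_only():
    tile = generate_tile(_small_config(n_tcells=8, n_macrophages=0, n_myeloid=0))
    for c in tile.truth_cells:
        assert c.process_polylines == []
        assert set(c.marker_positivity) == {"CD3"}


def test_coexpression_fraction_within_binomial_interval():
    """With P(CD68)=1 and independent P(CD163)=0.3, the CD163+ fraction of
    CD68+ cells must fall inside the two-sided 99% binomial interval."""
    cfg = _small_config(
        tile_height_px=512, tile_width_px=512,
        n_tcells=0, n_myeloid=0, n_macrophages=50,
        coexpression={
            "tcell": {"CD3": 1.0}, "myeloid": {},
            "macrophage": {"CD68": 1.0, "CD163": 0.3, "CD206": 0.0,
                           "CD11b": 0.0, "CD11c": 0.0},
        },
        seed=5,
    )
    tile = generate_tile(cfg)
    cd68 = [c for c in tile.truth_cells if c.marker_positivity["CD68"]]
    assert len(cd68) == 50
    k = sum(c.marker_positivity["CD163"] for c in cd68)
    lo, hi = stats.binom.ppf([0.005, 0.995], 50, 0.3)
    assert lo <= k <= hi


def test_placement_failure_is_explicit():
    with pytest.raises(PlacementError):
        generate_tile(_small_config(tile_height_px=64, tile_width_px=64,
                                    n_myeloid=500, max_placement_attempts=50))


def test_dapi_components_equal_cell_count():
    """Non-overlap placement conserves nuclei: one connected DAPI
    component per truth cell."""
    tile = generate_tile(_small_config(n_tcells=10, n_macrophages=10, n_myeloid=10))
    _, n = ndimage.label(tile.truth_nuclear_mask.pixels)
    assert n == len(tile.truth_cells)


def test_truth_masks_are_union_of_positive_footprints():
    tile = generate_tile(_small_config(seed=3))
    for m in MCM_MARKERS:
        mask = tile.truth_marker_masks[m]
        positive_cells = [c for c in tile.truth_cells
                          if c.marker_positivity.get(m, False)]
        if not positive_cells:
            assert mask.positive_count == 0
        else:
            # every positive cell's centroid disk is covered by the mask
            ps = mask.pixel_size_um
            for c in positive_cells:
                if c.soma_in_section:
                    r, col = int(round(c.centroid_um[0] / ps)), int(round(c.centroid_um[1] / ps))
                    assert mask.pixels[r, col]


def test_truth_masks_have_if_geometry():
    cfg = _small_config()
    tile = generate_tile(cfg)
    for m in tile.truth_marker_masks.values():
        assert m.pixel_size_um == cfg.if_pixel_size_um
        assert m.shape == (cfg.tile_height_px, cfg.tile_width_px)
    assert tile.ihc_channels["hematoxylin"].shape == cfg.ihc_shape


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        generate_tile(_small_config(tumor_area_fraction=1.5))
    bad = _small_config()
    bad.coexpression["macrophage"]["CD68"] = 1.2
    with pytest.raises(ValueError):
        generate_tile(bad)


class TestChromogenicRendition:
    def test_identity_no_noise_hematoxylin_matches_dapi(self):
        cfg = _small_config(
            ihc_pixel_size_um=0.3,
            noise=NoiseSpec(if_sd=0.0, ihc_sd=0.0),
            acquisition=AcquisitionSpec(),
        )
        tile = generate_tile(cfg)
        dapi = tile.if_channels["DAPI"].pixels.astype(float)
        hema = tile.ihc_channels["hematoxylin"].pixels.astype(float)
        assert hema.shape == dapi.shape
        d = (dapi - dapi.min()) / np.ptp(dapi)
        h = (hema - hema.min()) / np.ptp(hema)
        assert np.abs(d - h).max() < 1e-6

    def test_translation_displaces_nuclei_by_ten_pixels(self):
        shift_px = 10
        cfg = _small_config(
            ihc_pixel_size_um=0.3,
            n_tcells=0, n_macrophages=0, n_myeloid=6,
            noise=NoiseSpec(if_sd=0.0, ihc_sd=0.0),
            acquisition=AcquisitionSpec(translation_um=(shift_px * 0.3, 0.0)),
        )
        tile = generate_tile(cfg)
        hema = tile.ihc_channels["hematoxylin"].pixels
        ps = cfg.if_pixel_size_um
        # each truth nucleus must reappear in hematoxylin at centroid - 10 rows
        for c in tile.truth_cells:
            r = int(round(c.centroid_um[0] / ps)) - shift_px
            col = int(round(c.centroid_um[1] / ps))
            if 0 <= r < hema.shape[0]:
                assert hema[r, col] > 100

    def test_pixel_size_change_rescales_disk_diameter(self):
        """A 20 IF px diameter nucleus appears ~12 px wide at 0.5 um/px."""
        cfg = _small_config(
            tile_height_px=128, tile_width_px=128,
            n_tcells=0, n_macrophages=0, n_myeloid=1,
            morphology={**SimulationConfig().morphology,
                        "myeloid": MorphologySpec(nuclear_radius_um=(3.0, 0.0))},
            noise=NoiseSpec(if_sd=0.0, ihc_sd=0.0),
        )
        tile = generate_tile(cfg)
        hema = tile.ihc_channels["hematoxylin"].pixels
        rows = np.nonzero((hema > 100).any(axis=1))[0]
        diameter = rows.max() - rows.min() + 1
        assert abs(diameter - 12) <= 1


def test_standalone_rerender_is_deterministic():
    from pixelplex.synthetic import render_chromogenic_view

    cfg = _small_config()
    tile = generate_tile(cfg)
    again = render_chromogenic_view(dataclasses.replace(tile, ihc_channels={}), cfg)
    for ch in tile.ihc_channels:
        assert np.array_equal(tile.ihc_channels[ch].pixels, again.ihc_channels[ch].pixels)
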