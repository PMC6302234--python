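"""Seeded in-silico validation studies.

Each function runs one self-contained synthetic experiment end to end —
simulate tiles, run the measurement path under test, summarize — and
returns plain numbers.  They define the package's reference study
conditions (tile sizes, cell counts, co-expression settings) in one
place, shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .core import MarkerMask
from .masks import (
    MCM_MASK_MARKERS,
    ThresholdSpec,
    decompose_pixel_classes,
    remove_small_groups,
    restrict_cd206,
    threshold_channel,
    union_masks,
)
from .phenotyping import DoughnutSpec, correlate_counts, phenotype_tile, segment_nuclei
from .registration import corner_displacement_um, estimate_affine
from .spatial import (
    BorderBandSpec,
    distance_histogram,
    distance_map_um,
    find_border_nuclei,
    nearest_class_distance,
)
from .synthetic import (
    AcquisitionSpec,
    MorphologySpec,
    PlacementSpec,
    SimulationConfig,
    SyntheticTile,
    generate_tile,
)

__all__ = [
    "child_seeds",
    "measure_marker_masks",
    "affine_recovery_experiment",
    "class_proportion_experiment",
    "morphology_correlation_experiment",
    "spatial_ordering_experiment",
    "uniform_density_experiment",
]

#: Fixed intensity threshold used for the simulator's 16-bit channels:
#: midway between the two-level background (300) and signal (20000)
#: plateaus, far above the noise floor on either side.
IF_THRESHOLD = 10000.0


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def measure_marker_masks(
    tile: SyntheticTile,
    markers: tuple[str, ...],
    spec: ThresholdSpec | None = None,
) -> dict[str, MarkerMask]:
    """Threshold + small-group-filter the fluorescent marker channels."""
    spec = spec or ThresholdSpec(threshold=IF_THRESHOLD)
    out = {}
    for m in markers:
        mask = threshold_channel(tile.if_channels[m], spec)
        out[m] = remove_small_groups(mask, spec)
    return out


# ----------------------------------------------------------------------
def affine_recovery_experiment(n_pairs: int = 20, seed: int = 0) -> dict:
    """Recover known affine motions between synthetic IF/IHC pairs.

    Each pair is a 384x384 IF tile (0.3 µm/px) with >= 100 compact
    nuclei, re-rendered chromogenically at 0.5 µm/px after a random
    rotation (<= 10 deg) and translation (<= 20 IF px).  Registration
    runs on DAPI vs hematoxylin; success means a mean corner
    displacement <= 1 IF pixel (0.3 µm) against the generating
    transform.
    """
    errors_um = []
    rng = np.random.default_rng(seed)
    for s in child_seeds(seed, n_pairs):
        rot = float(rng.uniform(-10.0, 10.0))
        trans = tuple(rng.uniform(-4.0, 4.0, size=2))  # |t| <= ~19 IF px
        cfg = SimulationConfig(
            tile_height_px=384, tile_width_px=384,
            n_tumor_regions=0, tumor_area_fraction=0.0,
            n_tcells=0, n_macrophages=0, n_myeloid=120,
            morphology={
                **SimulationConfig().morphology,
                "myeloid": MorphologySpec(nuclear_radius_um=(2.5, 0.3)),
            },
            acquisition=AcquisitionSpec(rotation_deg=rot, translation_um=trans),
            seed=s,
        )
        tile = generate_tile(cfg)
        est, quality = estimate_affine(
            tile.ihc_channels["hematoxylin"], tile.if_channels["DAPI"],
            truth=tile.truth_transform,
        )
        errors_um.append(quality.corner_error_um)
    errors_um = np.asarray(errors_um)
    if_px = 0.3
    return {
        "n_pairs": n_pairs,
        "corner_errors_um": errors_um.tolist(),
        "mean_corner_error_um": float(errors_um.mean()),
        "recovery_rate_percent": float(100.0 * (errors_um <= if_px).mean()),
    }


# ----------------------------------------------------------------------
def class_proportion_experiment(n_seeds: int = 10, seed: int = 0) -> dict:
    """Recover generative co-expression proportions from pixel classes.

    Myeloid cells on 512x512 tiles carry CD68 with probability 1 and
    CD163 independently with probability 0.3; the expected exclusive
    class proportions of the MC&M mask are therefore 70% CD68-single
    and 30% CD68/CD163-double.  The estimate runs the full measurement
    path (threshold, small-group filter, union, CD206 restriction,
    decomposition) and averages percentages over seeds.
    """
    p_double = 0.3
    singles, doubles = [], []
    for s in child_seeds(seed, n_seeds):
        cfg = SimulationConfig(
            n_tumor_regions=0, tumor_area_fraction=0.0,
            n_tcells=0, n_macrophages=0, n_myeloid=60,
            coexpression={
                "tcell": {"CD3": 1.0},
                "macrophage": {},
                "myeloid": {"CD68": 1.0, "CD163": p_double, "CD206": 0.0,
                            "CD11b": 0.0, "CD11c": 0.0},
            },
            seed=s,
        )
        tile = generate_tile(cfg)
        masks = measure_marker_masks(tile, ("CD68", "CD163", "CD206", "CD11b", "CD11c"))
        mcm = union_masks([masks[m] for m in MCM_MASK_MARKERS])
        masks["CD206"] = restrict_cd206(masks["CD206"], mcm)
        table = decompose_pixel_classes(masks, mcm)
        singles.append(table.percent("CD68"))
        doubles.append(table.percent("CD68/CD163"))
    return {
        "n_seeds": n_seeds,
        "expected_single_percent": 100.0 * (1 - p_double),
        "expected_double_percent": 100.0 * p_double,
        "estimated_single_percent": float(np.mean(singles)),
        "estimated_double_percent": float(np.mean(doubles)),
    }


# ----------------------------------------------------------------------
def _correlation_configs(seed: int, n_tiles: int) -> list[tuple[int, int, int]]:
    """Per-tile (seed, n_cells, process_count) for the morphology study."""
    # Tiles emulate fields sampled from one tissue region: cellularity
    # varies moderately (20-40 cells) while process elaboration varies
    # strongly (0-8 processes per cell, drawn per tile).
    rng = np.random.default_rng(seed)
    out = []
    for s in child_seeds(seed, n_tiles):
        n_cells = int(rng.integers(20, 41))
        k = int(rng.integers(0, 9))
        out.append((s, n_cells, k))
    return out


def morphology_correlation_experiment(n_tiles: int = 28, seed: int = 0) -> dict:
    """Cell-count vs pixel-area correlation for compact vs stellate cells.

    Matched tile layouts (same seeds, same cell counts) are rendered
    twice: once with compact CD68+ cells whose signal is perinuclear,
    once with stellate cells whose processes are ~5x the nuclear radius
    long, with per-tile randomized process counts, and whose nucleus or
    soma may fall outside the virtual section.  Cell counts come from
    doughnut classification on DAPI, pixel counts from the thresholded
    CD68 mask; compact cells should correlate strongly, stellate cells
    substantially less.
    """
    compact_mo = MorphologySpec(nuclear_radius_um=(3.0, 0.4))
    cell_counts = {"compact": [], "stellate": []}
    pixel_counts = {"compact": [], "stellate": []}
    for s, n_cells, k in _correlation_configs(seed, n_tiles):
        for scenario in ("compact", "stellate"):
            if scenario == "compact":
                mo = compact_mo
            else:
                mo = MorphologySpec(
                    nuclear_radius_um=(3.0, 0.4),
                    process_count=(k, k),
                    process_length_um=(12.0, 18.0),  # ~5x the 3 µm nuclear radius
                    process_width_px=(1, 2),
                    nucleus_out_of_section_prob=0.35,
                    soma_out_of_section_prob=0.35,
                )
            cfg = SimulationConfig(
                n_tumor_regions=0, tumor_area_fraction=0.0,
                n_tcells=0, n_myeloid=0, n_macrophages=n_cells,
                coexpression={
                    "tcell": {"CD3": 1.0}, "myeloid": {},
                    "macrophage": {"CD68": 1.0, "CD163": 0.0, "CD206": 0.0,
                                   "CD11b": 0.0, "CD11c": 0.0},
                },
                morphology={**SimulationConfig().morphology, "macrophage": mo},
                seed=s,
            )
            tile = generate_tile(cfg)
            mask = measure_marker_masks(tile, ("CD68",))["CD68"]
            _, _, table = phenotype_tile(
                tile.if_channels["DAPI"], {"CD68": mask},
                doughnut_spec=DoughnutSpec(density_threshold=0.1),
            )
            n_pos = int(table["CD68_positive"].sum()) if len(table) else 0
            cell_counts[scenario].append(n_pos)
            pixel_counts[scenario].append(mask.positive_count)
    r = {
        sc: correlate_counts(cell_counts[sc], pixel_counts[sc], marker="CD68").pearson_r
        for sc in ("compact", "stellate")
    }
    return {
        "n_tiles": n_tiles,
        "compact_pearson_r": r["compact"],
        "stellate_pearson_r": r["stellate"],
        "r_gap": r["compact"] - r["stellate"],
    }


# ----------------------------------------------------------------------
def spatial_ordering_experiment(n_runs: int = 20, seed: int = 0) -> dict:
    """Near vs far marker groups around the tumor border.

    CD68/CD163+ macrophages are placed in the stroma with density
    decaying over 10 µm from the tumor border, CD11b/CD11c+ myeloid
    cells with a 60 µm decay.  Distances from tumor-border nuclei to
    the nearest pixel of each marker mask should then be ordered
    (near group < far group); the run-level ordering rate and the
    histogram percent sums are reported.
    """
    near, far = ("CD68", "CD163"), ("CD11b", "CD11c")
    orderings = []
    mean_near_all, mean_far_all = [], []
    histogram_percent_sums = []
    for s in child_seeds(seed, n_runs):
        cfg = SimulationConfig(
            n_tumor_regions=1, tumor_area_fraction=0.2,
            n_tcells=60, n_macrophages=25, n_myeloid=25,
            coexpression={
                "tcell": {"CD3": 1.0},
                "macrophage": {"CD68": 1.0, "CD163": 1.0, "CD206": 0.0,
                               "CD11b": 0.0, "CD11c": 0.0},
                "myeloid": {"CD68": 0.0, "CD163": 0.0, "CD206": 0.0,
                            "CD11b": 1.0, "CD11c": 1.0},
            },
            placement={
                "tcell": PlacementSpec(mode="uniform"),
                "macrophage": PlacementSpec(mode="tumor_border", decay_length_um=10.0),
                "myeloid": PlacementSpec(mode="tumor_border", decay_length_um=60.0),
            },
            seed=s,
        )
        tile = generate_tile(cfg)
        masks = measure_marker_masks(tile, near + far)
        nuclei, _, _ = segment_nuclei(tile.if_channels["DAPI"])
        border = find_border_nuclei(nuclei, tile.truth_tumor_mask, BorderBandSpec(10.0))
        if not border:
            continue
        means = {}
        for m in near + far:
            dmap = distance_map_um(masks[m])
            ds = [nearest_class_distance(n.centroid_px, masks[m], _dmap=dmap)
                  for n in border]
            hist = distance_histogram(ds, marker=m)
            if hist.n_measured:
                histogram_percent_sums.append(float(np.sum(hist.percents)))
            means[m] = hist.mean_distance_um
        mean_near = np.nanmean([means[m] for m in near])
        mean_far = np.nanmean([means[m] for m in far])
        mean_near_all.append(mean_near)
        mean_far_all.append(mean_far)
        orderings.append(bool(mean_near < mean_far))
    return {
        "n_runs": len(orderings),
        "ordering_rate_percent": float(100.0 * np.mean(orderings)) if orderings else float("nan"),
        "mean_distance_near_um": float(np.mean(mean_near_all)),
        "mean_distance_far_um": float(np.mean(mean_far_all)),
        "histogram_percent_sums": histogram_percent_sums,
    }


# ----------------------------------------------------------------------
def uniform_density_experiment(n_tiles: int = 10, seed: int = 0) -> dict:
    """Tumor:stroma ratio under spatially uniform marker placement.

    Small CD68+ myeloid cells are placed uniformly over the tile, so
    the expected class density is identical inside and outside the
    tumor mask and the pooled tumor:stroma ratio should be ~1.  The
    exact bookkeeping |class∩tumor| + |class∩stroma| = |class∩tissue|
    is checked per tile.
    """
    counts = {"tumor": 0, "stroma": 0, "tumor_px": 0, "stroma_px": 0}
    bookkeeping_exact = True
    class_pixels = 0
    for s in child_seeds(seed, n_tiles):
        cfg = SimulationConfig(
            n_tumor_regions=1, tumor_area_fraction=0.3,
            n_tcells=0, n_macrophages=0, n_myeloid=400,
            morphology={
                **SimulationConfig().morphology,
                "myeloid": MorphologySpec(nuclear_radius_um=(0.8, 0.1)),
            },
            coexpression={
                "tcell": {"CD3": 1.0}, "macrophage": {},
                "myeloid": {"CD68": 1.0, "CD163": 0.0, "CD206": 0.0,
                            "CD11b": 0.0, "CD11c": 0.0},
            },
            seed=s,
        )
        tile = generate_tile(cfg)
        mask = measure_marker_masks(tile, ("CD68",))["CD68"]
        tumor = tile.truth_tumor_mask.pixels
        stroma = ~tumor
        in_tumor = int((mask.pixels & tumor).sum())
        in_stroma = int((mask.pixels & stroma).sum())
        bookkeeping_exact &= in_tumor + in_stroma == mask.positive_count
        counts["tumor"] += in_tumor
        counts["stroma"] += in_stroma
        counts["tumor_px"] += int(tumor.sum())
        counts["stroma_px"] += int(stroma.sum())
        class_pixels += mask.positive_count
    ratio = (counts["tumor"] / counts["tumor_px"]) / (counts["stroma"] / counts["stroma_px"])
    return {
        "n_tiles": n_tiles,
        "class_pixels": class_pixels,
        "tumor_stroma_ratio": float(ratio),
        "bookkeeping_exact": bool(bookkeeping_exact),
    }
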