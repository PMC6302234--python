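"""Seeded synthetic-tissue tile simulator with full ground truth.

Real multiplexed IF/IHC tiles of the myeloid compartment have three
properties that drive every downstream analysis choice and that this
simulator reproduces:

* **morphology contrast** — T cells are compact and round with all
  marker signal perinuclear, while macrophages are stellate: stained
  processes extend tens of micrometers from the nucleus and, in a thin
  physical section, are frequently captured without their nucleus (or
  the nucleus without its processes);
* **marker co-expression** — each myeloid cell is positive for a random
  subset of {CD68, CD163, CD206, CD11b, CD11c} drawn from configurable
  per-cell-type probabilities, producing the single/double/triple pixel
  classes measured downstream;
* **two renditions of one scene** — the fluorescent channels are
  acquired at 0.3 µm/px (16-bit) and the chromogenic channels at
  0.5 µm/px (8-bit) after an unknown affine motion; the simulator
  renders the chromogenic view through a known ground-truth transform.

Everything is a deterministic function of ``(config, seed)``: the same
configuration produces bit-identical tiles.  Independent random streams
are used for tumor geometry, cell placement, nuclear radii, marker
draws, process morphology and noise, so that e.g. changing only the
process parameters leaves the cell layout untouched (useful for matched
morphology comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

from .core import AffineTransform, ChannelImage, MarkerMask, PixelplexError
from .masks import MCM_MARKERS

__all__ = [
    "SimulationConfig",
    "MorphologySpec",
    "PlacementSpec",
    "AcquisitionSpec",
    "NoiseSpec",
    "CellSpec",
    "SyntheticTile",
    "PlacementError",
    "generate_tile",
    "render_chromogenic_view",
]

IF_CHANNELS = ("DAPI",) + MCM_MARKERS
IHC_CHANNELS = ("hematoxylin", "CD3", "HMW_CK", "LMW_CK")
CELL_TYPES = ("tcell", "macrophage", "myeloid")


class PlacementError(PixelplexError):
    """Requested cell count cannot be placed without overlap."""


@dataclass(frozen=True)
class MorphologySpec:
    """Shape parameters for one cell type.

    ``nuclear_radius_um`` is (mean, sd) of a clipped-normal nuclear
    radius.  Stellate cells additionally grow ``process_count`` polyline
    processes of length ``process_length_um`` rendered at
    ``process_width_px``.  ``cytoplasm_factor`` scales the nuclear
    radius to the radius of the stained perinuclear cytoplasm disk.

    The two ``*_out_of_section_prob`` fields emulate thin physical
    sectioning of large stellate cells: with the first probability the
    nucleus lies outside the section (the marker footprint is rendered
    without a nucleus), with the second the soma does (the nucleus is
    rendered but the marker signal is reduced to the processes alone).
    Both default to 0 so that, by default, every simulated cell has
    exactly one nucleus in the tile.
    """

    nuclear_radius_um: tuple[float, float] = (3.0, 0.4)
    process_count: tuple[int, int] = (0, 0)
    process_length_um: tuple[float, float] = (10.0, 40.0)
    process_width_px: tuple[int, int] = (1, 2)
    cytoplasm_factor: float = 1.6
    nucleus_out_of_section_prob: float = 0.0
    soma_out_of_section_prob: float = 0.0


@dataclass(frozen=True)
class PlacementSpec:
    """Where cells of one type go: uniform over the tile, or biased
    toward the tumor border with density ~ exp(-d/decay_length) in the
    stroma, d being the distance to the tumor mask."""

    mode: Literal["uniform", "tumor_border"] = "uniform"
    decay_length_um: float = 20.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """Rigid/affine motion between the fluorescent scene and its
    chromogenic re-acquisition (rotation about the field center, then
    translation, optional shear), expressed in physical units."""

    rotation_deg: float = 0.0
    translation_um: tuple[float, float] = (0.0, 0.0)
    shear: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    """Two-level (background/signal) intensity model with additive
    Gaussian noise, clipped to the dtype range.  Fluorescent channels
    are 16-bit, chromogenic channels 8-bit."""

    if_background: float = 300.0
    if_signal: float = 20000.0
    if_sd: float = 400.0
    ihc_background: float = 15.0
    ihc_signal: float = 200.0
    ihc_sd: float = 6.0


def _default_coexpression() -> dict[str, dict[str, float]]:
    return {
        "tcell": {"CD3": 1.0},
        "macrophage": {"CD68": 0.9, "CD163": 0.6, "CD206": 0.4, "CD11b": 0.5, "CD11c": 0.3},
        "myeloid": {"CD68": 0.15, "CD163": 0.1, "CD206": 0.05, "CD11b": 0.85, "CD11c": 0.7},
    }


def _default_morphology() -> dict[str, MorphologySpec]:
    return {
        "tcell": MorphologySpec(nuclear_radius_um=(2.5, 0.3)),
        "macrophage": MorphologySpec(
            nuclear_radius_um=(3.5, 0.5), process_count=(3, 6)
        ),
        "myeloid": MorphologySpec(nuclear_radius_um=(3.0, 0.4)),
    }


def _default_placement() -> dict[str, PlacementSpec]:
    return {t: PlacementSpec() for t in CELL_TYPES}


@dataclass
class SimulationConfig:
    """Full description of one synthetic tile.

    Pixel sizes default to the instruments emulated: 0.3 µm/px for the
    fluorescent rendition, 0.5 µm/px for the chromogenic one.
    ``min_separation_factor`` scales the required centroid separation
    (factor x the sum of the two nuclear radii) during rejection
    placement, keeping nuclei disjoint by default.
    """

    tile_height_px: int = 512
    tile_width_px: int = 512
    if_pixel_size_um: float = 0.3
    ihc_pixel_size_um: float = 0.5
    n_tumor_regions: int = 1
    tumor_area_fraction: float = 0.25
    n_tcells: int = 20
    n_macrophages: int = 20
    n_myeloid: int = 20
    coexpression: dict[str, dict[str, float]] = field(default_factory=_default_coexpression)
    morphology: dict[str, MorphologySpec] = field(default_factory=_default_morphology)
    placement: dict[str, PlacementSpec] = field(default_factory=_default_placement)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    min_separation_factor: float = 1.5
    max_placement_attempts: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if self.tile_height_px < 1 or self.tile_width_px < 1:
            raise ValueError("tile dimensions must be positive")
        if self.if_pixel_size_um <= 0 or self.ihc_pixel_size_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if not 0.0 <= self.tumor_area_fraction <= 1.0:
            raise ValueError("tumor_area_fraction must lie in [0, 1]")
        if min(self.n_tcells, self.n_macrophages, self.n_myeloid, self.n_tumor_regions) < 0:
            raise ValueError("counts must be non-negative")
        for ct, probs in self.coexpression.items():
            for m, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"coexpression[{ct}][{m}]={p} outside [0, 1]")
        for ct, mo in self.morphology.items():
            if mo.nuclear_radius_um[0] <= 0:
                raise ValueError(f"nuclear radius mean for {ct} must be positive")
            if not 0 <= mo.nucleus_out_of_section_prob <= 1:
                raise ValueError("nucleus_out_of_section_prob must lie in [0, 1]")
            if not 0 <= mo.soma_out_of_section_prob <= 1:
                raise ValueError("soma_out_of_section_prob must lie in [0, 1]")
        for ct, pl in self.placement.items():
            if pl.mode == "tumor_border" and pl.decay_length_um <= 0:
                raise ValueError("decay_length_um must be positive")

    @property
    def ihc_shape(self) -> tuple[int, int]:
        sc = self.if_pixel_size_um / self.ihc_pixel_size_um
        return (
            max(1, int(round(self.tile_height_px * sc))),
            max(1, int(round(self.tile_width_px * sc))),
        )


@dataclass
class CellSpec:
    """Ground truth for one simulated cell.

    ``process_polylines`` are (k, 2) arrays of (row_um, col_um) vertices
    (empty for compact cells).  ``nucleus_in_section`` / ``soma_in_section``
    record the sectioning outcome used during rendering.
    """

    cell_type: str
    centroid_um: tuple[float, float]
    nuclear_radius_um: float
    marker_positivity: dict[str, bool]
    process_polylines: list[np.ndarray] = field(default_factory=list)
    nucleus_in_section: bool = True
    soma_in_section: bool = True


@dataclass
class SyntheticTile:
    """One simulated scene in both renditions, with complete truth.

    All truth masks are in fluorescent (IF) geometry at the IF pixel
    size; ``truth_transform`` maps chromogenic µm coordinates to
    fluorescent µm coordinates.
    """

    config: SimulationConfig
    if_channels: dict[str, ChannelImage]
    ihc_channels: dict[str, ChannelImage]
    truth_cells: list[CellSpec]
    truth_tumor_mask: MarkerMask
    truth_nuclear_mask: MarkerMask
    truth_transform: AffineTransform
    truth_marker_masks: dict[str, MarkerMask]
    tile_id: str = "tile"


# ----------------------------------------------------------------------
# rasterization helpers (IF pixel grid; µm -> px via the IF pixel size)

def _add_disk(mask: np.ndarray, center_px: tuple[float, float], radius_px: float) -> None:
    h, w = mask.shape
    cr, cc = center_px
    r0, r1 = max(0, int(np.floor(cr - radius_px))), min(h - 1, int(np.ceil(cr + radius_px)))
    c0, c1 = max(0, int(np.floor(cc - radius_px))), min(w - 1, int(np.ceil(cc + radius_px)))
    if r0 > r1 or c0 > c1:
        return
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    mask[r0 : r1 + 1, c0 : c1 + 1] |= (yy - cr) ** 2 + (xx - cc) ** 2 <= radius_px**2


def _add_polyline(mask: np.ndarray, polyline_px: np.ndarray, width_px: float) -> None:
    # stamp disks of radius width/2 along the polyline, 0.5 px steps
    rad = max(0.5, width_px / 2.0)
    for a, b in zip(polyline_px[:-1], polyline_px[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        n = max(2, int(np.ceil(length / 0.5)) + 1)
        for t in np.linspace(0.0, 1.0, n):
            _add_disk(mask, tuple(a + t * seg), rad)


def _make_tumor_mask(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.tile_height_px, cfg.tile_width_px
    mask = np.zeros((h, w), dtype=bool)
    if cfg.n_tumor_regions == 0 or cfg.tumor_area_fraction == 0:
        return mask
    # ellipses whose summed area targets the requested fraction (overlap
    # and tile clipping make the realized fraction approximate)
    target = cfg.tumor_area_fraction * h * w / cfg.n_tumor_regions
    base_r = np.sqrt(target / np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(cfg.n_tumor_regions):
        cy, cx = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
        a = base_r * rng.uniform(0.8, 1.25)
        b = target / np.pi / a
        th = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _place_cells(
    cfg: SimulationConfig,
    tumor: np.ndarray,
    radii_um: list[tuple[str, float]],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Rejection-sample centroids (µm) honoring the minimum separation
    and, per cell type, the placement model."""
    ps = cfg.if_pixel_size_um
    h_um = (cfg.tile_height_px - 1) * ps
    w_um = (cfg.tile_width_px - 1) * ps
    dist_um = None
    if any(cfg.placement[ct].mode == "tumor_border" for ct, _ in radii_um):
        if not tumor.any():
            raise PlacementError("tumor_border placement requested but tumor mask is empty")
        dist_um = ndimage.distance_transform_edt(~tumor, sampling=ps)
    placed: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for ct, r_um in radii_um:
        spec = cfg.placement[ct]
        margin = r_um + ps
        ok = False
        for _ in range(cfg.max_placement_attempts):
            p = (
                rng.uniform(margin, h_um - margin),
                rng.uniform(margin, w_um - margin),
            )
            if spec.mode == "tumor_border":
                pr = int(round(p[0] / ps))
                pc = int(round(p[1] / ps))
                d = dist_um[pr, pc]
                if d == 0.0:  # inside tumor: these cells live in the stroma
                    continue
                if rng.uniform() > np.exp(-d / spec.decay_length_um):
                    continue
            sep_ok = True
            for q, rq in zip(placed, placed_r):
                min_sep = cfg.min_separation_factor * (r_um + rq)
                if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < min_sep**2:
                    sep_ok = False
                    break
            if sep_ok:
                placed.append(p)
                placed_r.append(r_um)
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a {ct} cell after {cfg.max_placement_attempts} attempts; "
                "reduce cell counts or the separation factor"
            )
    return placed


def _draw_processes(
    centroid_um: tuple[float, float],
    r_um: float,
    mo: MorphologySpec,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    k_lo, k_hi = mo.process_count
    k = int(rng.integers(k_lo, k_hi + 1)) if k_hi > 0 else 0
    polylines = []
    for _ in range(k):
        theta = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(*mo.process_length_um)
        pts = [np.array(centroid_um) + r_um * np.array([np.sin(theta), np.cos(theta)])]
        seg = length / 3.0
        for _ in range(3):
            theta += rng.uniform(-0.35, 0.35)
            pts.append(pts[-1] + seg * np.array([np.sin(theta), np.cos(theta)]))
        polylines.append(np.array(pts))
    return polylines


def _footprint(
    shape: tuple[int, int],
    cell: CellSpec,
    mo: MorphologySpec,
    ps: float,
) -> np.ndarray:
    """Noise-free stained footprint of one cell (IF grid)."""
    fp = np.zeros(shape, dtype=bool)
    c_px = (cell.centroid_um[0] / ps, cell.centroid_um[1] / ps)
    if cell.soma_in_section:
        _add_disk(fp, c_px, mo.cytoplasm_factor * cell.nuclear_radius_um / ps)
    for poly in cell.process_polylines:
        w = (mo.process_width_px[0] + mo.process_width_px[1]) / 2.0
        _add_polyline(fp, poly / ps, w)
    return fp


def generate_tile(config: SimulationConfig, tile_id: str = "tile") -> SyntheticTile:
    """Simulate one tile: tumor geometry, cells, fluorescent channels,
    ground-truth masks, and the chromogenic rendition.

    Raises
    ------
    PlacementError
        If the requested cell count cannot be placed without violating
        the minimum-separation rule within the attempt budget.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_tumor, r_radius, r_place, r_marker, r_proc, r_noise_if, r_noise_ihc = (
        np.random.default_rng(s) for s in ss.spawn(7)
    )
    ps = config.if_pixel_size_um
    shape = (config.tile_height_px, config.tile_width_px)

    tumor = _make_tumor_mask(config, r_tumor)

    # nuclear radii first (own stream, so layouts survive morphology edits)
    counts = {"tcell": config.n_tcells, "macrophage": config.n_macrophages,
              "myeloid": config.n_myeloid}
    radii_um: list[tuple[str, float]] = []
    for ct in CELL_TYPES:
        mean, sd = config.morphology[ct].nuclear_radius_um
        for _ in range(counts[ct]):
            r = float(np.clip(r_radius.normal(mean, sd), max(0.45, mean - 2.5 * sd),
                              mean + 2.5 * sd))
            radii_um.append((ct, r))

    centroids = _place_cells(config, tumor, radii_um, r_place)

    cells: list[CellSpec] = []
    for (ct, r_um), centroid in zip(radii_um, centroids):
        probs = config.coexpression.get(ct, {})
        positivity = {m: bool(r_marker.uniform() < p) for m, p in probs.items()}
        mo = config.morphology[ct]
        polylines = _draw_processes(centroid, r_um, mo, r_proc) if ct != "tcell" else []
        nuc_in = not (mo.nucleus_out_of_section_prob > 0
                      and r_proc.uniform() < mo.nucleus_out_of_section_prob)
        soma_in = True
        if nuc_in and mo.soma_out_of_section_prob > 0:
            soma_in = not r_proc.uniform() < mo.soma_out_of_section_prob
        cells.append(
            CellSpec(
                cell_type=ct,
                centroid_um=(float(centroid[0]), float(centroid[1])),
                nuclear_radius_um=r_um,
                marker_positivity=positivity,
                process_polylines=polylines,
                nucleus_in_section=nuc_in,
                soma_in_section=soma_in,
            )
        )

    # --- truth masks ---------------------------------------------------
    nuclear = np.zeros(shape, dtype=bool)
    for cell in cells:
        if cell.nucleus_in_section:
            _add_disk(nuclear, (cell.centroid_um[0] / ps, cell.centroid_um[1] / ps),
                      cell.nuclear_radius_um / ps)

    marker_fields: dict[str, np.ndarray] = {m: np.zeros(shape, dtype=bool)
                                            for m in MCM_MARKERS + ("CD3",)}
    for cell in cells:
        positive = [m for m, v in cell.marker_positivity.items() if v]
        if not positive:
            continue
        fp = _footprint(shape, cell, config.morphology[cell.cell_type], ps)
        for m in positive:
            marker_fields[m] |= fp

    def _mask(arr: np.ndarray, label: str) -> MarkerMask:
        return MarkerMask(pixels=arr, pixel_size_um=ps, label=label, tile_id=tile_id)

    truth_marker_masks = {m: _mask(marker_fields[m], m) for m in marker_fields}

    # --- fluorescent channels (16-bit, two-level + Gaussian noise) ------
    nz = config.noise
    if_channels: dict[str, ChannelImage] = {}
    for ch in IF_CHANNELS:
        fld = nuclear if ch == "DAPI" else marker_fields[ch]
        img = np.where(fld, nz.if_signal, nz.if_background).astype(float)
        if nz.if_sd > 0:
            img += r_noise_if.normal(0.0, nz.if_sd, size=shape)
        if_channels[ch] = ChannelImage(
            pixels=np.clip(img, 0, 65535).astype(np.uint16),
            pixel_size_um=ps, channel=ch, tile_id=tile_id,
        )

    # --- ground-truth transform (IHC µm -> IF µm) -----------------------
    center = ((config.tile_height_px - 1) * ps / 2.0, (config.tile_width_px - 1) * ps / 2.0)
    transform = AffineTransform.from_params(
        rotation_deg=config.acquisition.rotation_deg,
        translation_um=config.acquisition.translation_um,
        shear=config.acquisition.shear,
        center_um=center,
        source_pixel_size_um=config.ihc_pixel_size_um,
        target_pixel_size_um=ps,
    )

    tile = SyntheticTile(
        config=config,
        if_channels=if_channels,
        ihc_channels={},
        truth_cells=cells,
        truth_tumor_mask=_mask(tumor, "tumor"),
        truth_nuclear_mask=_mask(nuclear, "nuclei"),
        truth_transform=transform,
        truth_marker_masks=truth_marker_masks,
        tile_id=tile_id,
    )
    return render_chromogenic_view(tile, config, rng=r_noise_ihc)


def render_chromogenic_view(
    tile: SyntheticTile,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticTile:
    """Fill ``ihc_channels`` by pushing the noise-free truth fields
    through the ground-truth transform onto the chromogenic pixel grid.

    Hematoxylin depicts the same nuclei as DAPI, CD3 only the T cells,
    and both cytokeratin channels the tumor-epithelium mask; intensities
    are resampled bilinearly and re-noised on the 8-bit grid.
    """
    config = config or tile.config
    if rng is None:
        # stand-alone call: derive the chromogenic noise stream from the seed
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])
    nz = config.noise
    out_shape = config.ihc_shape
    lin_px, off_px = tile.truth_transform.pixel_matrix()

    def _warp(field: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            field.astype(float), lin_px, offset=off_px,
            output_shape=out_shape, order=1, mode="constant", cval=0.0,
        )

    sources = {
        "hematoxylin": tile.truth_nuclear_mask.pixels,
        "CD3": tile.truth_marker_masks["CD3"].pixels,
        "HMW_CK": tile.truth_tumor_mask.pixels,
        "LMW_CK": tile.truth_tumor_mask.pixels,
    }
    ihc_channels: dict[str, ChannelImage] = {}
    for ch in IHC_CHANNELS:
        img = nz.ihc_background + (nz.ihc_signal - nz.ihc_background) * _warp(sources[ch])
        if nz.ihc_sd > 0:
            img += rng.normal(0.0, nz.ihc_sd, size=out_shape)
        ihc_channels[ch] = ChannelImage(
            pixels=np.clip(img, 0, 255).astype(np.uint8),
            pixel_size_um=config.ihc_pixel_size_um,
            channel=ch, tile_id=tile.tile_id,
        )
    return replace(tile, ihc_channels=ihc_channels)
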