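"""Spatial statistics of myeloid pixel classes relative to tumor and
T-cell masks: region densities, tumor:stroma ratios, tumor-border
nuclei, nearest-class distances and binned distance histograms.

Distances are computed in the fluorescent geometry (after mask
transfer) via the two-dimensional Euclidean distance transform of the
complement of a class mask, sampled at each reference nucleus, and
reported in micrometers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import MarkerMask, require_same_geometry
from .phenotyping import NucleusRecord

__all__ = [
    "BorderBandSpec",
    "DistanceHistogram",
    "density_under_mask",
    "tumor_stroma_ratio",
    "find_border_nuclei",
    "nearest_class_distance",
    "distance_map_um",
    "distance_histogram",
]


@dataclass(frozen=True)
class BorderBandSpec:
    """Width of the tumor-border band (inward isometric offset of the
    tumor boundary) whose nuclei anchor the distance measurements."""

    band_width_um: float = 10.0

    def __post_init__(self) -> None:
        if self.band_width_um <= 0:
            raise ValueError("band_width_um must be positive")


@dataclass
class DistanceHistogram:
    """Distances binned as {0} (exact contact), (0,20], (20,40], ... µm.

    Percentages are over measured distances; missing values (empty
    class masks) are dropped and counted in ``n_missing``.
    """

    marker: str
    bin_width_um: float
    bin_labels: list[str]
    percents: list[float]
    counts: list[int]
    n_measured: int
    n_missing: int
    mean_distance_um: float  # NaN when nothing measured

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "count": self.counts, "percent": self.percents}
        ).assign(marker=self.marker, n_measured=self.n_measured,
                 n_missing=self.n_missing, mean_distance_um=self.mean_distance_um)


def density_under_mask(class_mask: MarkerMask, region_mask: MarkerMask) -> float | None:
    """Fraction of region pixels covered by the class mask.

    Returns ``None`` (undefined, not zero) for an empty region.
    """
    require_same_geometry(class_mask, region_mask)
    region = int(region_mask.pixels.sum())
    if region == 0:
        return None
    inside = int((class_mask.pixels & region_mask.pixels).sum())
    return inside / region


def tumor_stroma_ratio(
    class_mask: MarkerMask, tumor_mask: MarkerMask, tissue_mask: MarkerMask
) -> float | None:
    """density(class, tumor) / density(class, tissue - tumor).

    Stroma is the tissue with the tumor area subtracted.  Undefined
    (``None``) when the stroma is empty or holds no class pixels.
    """
    require_same_geometry(class_mask, tumor_mask, tissue_mask)
    stroma = MarkerMask(
        pixels=tissue_mask.pixels & ~tumor_mask.pixels,
        pixel_size_um=tissue_mask.pixel_size_um,
        label="stroma",
        tile_id=tissue_mask.tile_id,
    )
    d_tumor = density_under_mask(class_mask, tumor_mask)
    d_stroma = density_under_mask(class_mask, stroma)
    if d_tumor is None or d_stroma is None or d_stroma == 0.0:
        return None
    return d_tumor / d_stroma


def _inward_distance_um(tumor: np.ndarray, pixel_size_um: float, pad_px: int) -> np.ndarray:
    """Distance (µm) from each tumor pixel to the tumor boundary,
    with edge replication so that a tumor cropped by the tile edge does
    not acquire an artificial border along that edge."""
    padded = np.pad(tumor, pad_px, mode="edge")
    d = ndimage.distance_transform_edt(padded, sampling=pixel_size_um)
    return d[pad_px:-pad_px, pad_px:-pad_px]


def find_border_nuclei(
    nuclei: list[NucleusRecord],
    tumor_mask: MarkerMask,
    spec: BorderBandSpec = BorderBandSpec(),
) -> list[NucleusRecord]:
    """Select nuclei inside the tumor mask within the border band.

    A nucleus qualifies when its centroid pixel lies in the tumor mask
    and its inward Euclidean distance from the tumor boundary is at
    most ``band_width_um``.  The tile edge is not treated as a tumor
    border, so a tumor mask filling the whole tile selects no nuclei.
    """
    tumor = tumor_mask.pixels
    if not tumor.any():
        return []
    ps = tumor_mask.pixel_size_um
    pad = int(math.ceil(spec.band_width_um / ps)) + 2
    inward = _inward_distance_um(tumor, ps, pad)
    out = []
    h, w = tumor.shape
    for nuc in nuclei:
        r = int(round(nuc.centroid_px[0]))
        c = int(round(nuc.centroid_px[1]))
        if not (0 <= r < h and 0 <= c < w):
            continue
        if tumor[r, c] and inward[r, c] <= spec.band_width_um:
            out.append(nuc)
    return out


def distance_map_um(class_mask: MarkerMask) -> np.ndarray | None:
    """EDT of the mask complement in µm: per-pixel distance to the
    nearest class-positive pixel center.  ``None`` for an empty mask."""
    if not class_mask.pixels.any():
        return None
    return ndimage.distance_transform_edt(
        ~class_mask.pixels, sampling=class_mask.pixel_size_um
    )


def nearest_class_distance(
    reference_point_px: tuple[float, float],
    class_mask: MarkerMask,
    _dmap: np.ndarray | None = None,
) -> float | None:
    """Distance (µm) from a reference point to the nearest positive
    pixel of a class mask, via the Euclidean distance transform.

    The reference point (row, col in pixels, e.g. a nucleus centroid)
    is snapped to its nearest pixel center before sampling the distance
    map.  An empty class mask yields ``None`` — a missing value, not 0
    and not infinity.  Pass a precomputed ``distance_map_um`` result as
    ``_dmap`` when measuring many points against one mask.
    """
    dmap = _dmap if _dmap is not None else distance_map_um(class_mask)
    if dmap is None:
        return None
    h, w = class_mask.shape
    r = min(max(int(round(reference_point_px[0])), 0), h - 1)
    c = min(max(int(round(reference_point_px[1])), 0), w - 1)
    return float(dmap[r, c])


def distance_histogram(
    distances: "list[float | None]",
    marker: str = "",
    bin_width_um: float = 20.0,
) -> DistanceHistogram:
    """Bin nearest-class distances as {0}, (0,20], (20,40], ... µm.

    Exact contact (d = 0) gets its own bin; subsequent bins are
    half-open with inclusive upper edge, so d = 20 µm falls in (0,20].
    Missing values are dropped and counted.  Percentages sum to 100
    whenever anything was measured.
    """
    measured = [d for d in distances if d is not None]
    n_missing = len(distances) - len(measured)
    if not measured:
        return DistanceHistogram(
            marker=marker, bin_width_um=bin_width_um, bin_labels=[], percents=[],
            counts=[], n_measured=0, n_missing=n_missing, mean_distance_um=float("nan"),
        )
    arr = np.asarray(measured, dtype=float)
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    n_bins = max(1, int(math.ceil(arr.max() / bin_width_um)))
    labels = ["0"] + [
        f"({i * bin_width_um:g},{(i + 1) * bin_width_um:g}]" for i in range(n_bins)
    ]
    counts = [int((arr == 0).sum())]
    for i in range(n_bins):
        lo, hi = i * bin_width_um, (i + 1) * bin_width_um
        counts.append(int(((arr > lo) & (arr <= hi)).sum()))
    percents = [100.0 * c / len(arr) for c in counts]
    return DistanceHistogram(
        marker=marker, bin_width_um=bin_width_um, bin_labels=labels,
        percents=percents, counts=counts, n_measured=len(arr),
        n_missing=n_missing, mean_distance_um=float(arr.mean()),
    )
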