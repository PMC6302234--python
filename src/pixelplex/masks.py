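"""Marker-mask algebra: thresholding, small-group filtering and the
decomposition of overlapping marker masks into exclusive pixel classes.

The myeloid/macrophage compartment is read out through five antibodies
(CD68, CD163, CD206, CD11b, CD11c).  The reference area for class
percentages is the *MC&M mask*: the union of the CD68/CD163/CD11b/CD11c
masks.  CD206 additionally stains vasculature, so CD206 pixels enter the
class decomposition only after intersection with the MC&M mask
(:func:`restrict_cd206`); within the reference a CD206-only pixel can
therefore not occur and the exclusive single classes are the four
MC&M-defining markers.

Each pixel of the reference is assigned the exclusive combination of
markers staining it ("single", "double", "triple" classes and a residual
``P4,5`` class for four or five colors); the aggregate ``P2,3,4,5`` class
collects every pixel with at least two colors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import ChannelImage, MarkerMask, PixelplexError, require_same_geometry

__all__ = [
    "MCM_MARKERS",
    "MCM_MASK_MARKERS",
    "ThresholdSpec",
    "PixelClassTable",
    "CaseSummary",
    "DegenerateThresholdError",
    "threshold_channel",
    "remove_small_groups",
    "union_masks",
    "restrict_cd206",
    "decompose_pixel_classes",
    "mask_class_breakdown",
    "aggregate_case",
]

#: Canonical marker order used for class labels.
MCM_MARKERS: tuple[str, ...] = ("CD68", "CD163", "CD206", "CD11b", "CD11c")
#: Markers whose union defines the MC&M reference mask (CD206 excluded:
#: it co-stains vessels and is restricted to the mask instead).
MCM_MASK_MARKERS: tuple[str, ...] = ("CD68", "CD163", "CD11b", "CD11c")

#: Residual label for pixels positive for >= 4 markers.
RESIDUAL_LABEL = "P4,5"
#: Aggregate (non-exclusive) label for pixels positive for >= 2 markers.
MULTI_LABEL = "P2,3,4,5"


class DegenerateThresholdError(PixelplexError):
    """Automatic threshold undefined (e.g. Otsu on a constant image)."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Per-channel binarization and cleanup parameters.

    ``threshold`` is either a fixed intensity or the token ``"otsu"``.
    Positivity is strict: a pixel is positive iff intensity > threshold.
    ``min_group_size_px`` is the minimum connected-component size kept by
    :func:`remove_small_groups` (components with fewer pixels are treated
    as staining artifacts and cleared).
    """

    threshold: float | str = "otsu"
    min_group_size_px: int = 9
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_group_size_px < 1:
            raise ValueError("min_group_size_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold!r}")


def _class_label(pattern: tuple[str, ...]) -> str:
    if len(pattern) == 0:
        return "none"
    if len(pattern) >= 4:
        return RESIDUAL_LABEL
    return "/".join(pattern)


def class_labels(markers: tuple[str, ...] = MCM_MARKERS) -> list[str]:
    """All exclusive class labels for a marker panel, in canonical order."""
    labels = [m for m in markers]
    for k in (2, 3):
        labels += ["/".join(c) for c in itertools.combinations(markers, k)]
    labels.append(RESIDUAL_LABEL)
    return labels


@dataclass
class PixelClassTable:
    """Per-tile pixel counts and percentages for exclusive pixel classes.

    ``counts`` maps exclusive class label -> pixel count; these classes
    partition the reference mask.  ``aggregates`` holds non-exclusive
    aggregate classes (currently ``P2,3,4,5``).  Percentages are relative
    to ``reference_pixel_count``; with an empty reference they are
    undefined and reported as NaN.
    """

    tile_id: str
    reference_label: str
    reference_pixel_count: int
    counts: dict[str, int]
    aggregates: dict[str, int] = field(default_factory=dict)

    @property
    def percent_defined(self) -> bool:
        return self.reference_pixel_count > 0

    def percent(self, label: str) -> float:
        n = self.counts.get(label, self.aggregates.get(label))
        if n is None:
            raise KeyError(label)
        if not self.percent_defined:
            return float("nan")
        return 100.0 * n / self.reference_pixel_count

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, n in self.counts.items():
            rows.append((label, n, self.percent(label), True))
        for label, n in self.aggregates.items():
            rows.append((label, n, self.percent(label), False))
        return pd.DataFrame(
            rows, columns=["class_label", "pixel_count", "percent_of_reference", "exclusive"]
        ).assign(tile_id=self.tile_id, reference_label=self.reference_label,
                 reference_pixel_count=self.reference_pixel_count)


@dataclass
class CaseSummary:
    """Across-tile mean/sd of class percentages for one case.

    Tiles whose percentage is undefined (empty reference) are excluded
    from the mean and the per-class ``n_tiles`` is decremented
    accordingly.  The sample (n-1) standard deviation is reported, 0 for
    a single tile.
    """

    case_id: str
    reference_label: str
    stats: pd.DataFrame  # columns: class_label, mean_percent, sd_percent, n_tiles


def threshold_channel(image: ChannelImage, spec: ThresholdSpec) -> MarkerMask:
    """Binarize one grayscale channel.

    A pixel is positive iff its intensity is strictly greater than the
    threshold; an image whose every pixel equals the threshold value
    therefore yields an empty mask.

    Raises
    ------
    DegenerateThresholdError
        If ``spec.threshold == "otsu"`` and the image is constant.
    """
    px = np.asarray(image.pixels)
    if spec.threshold == "otsu":
        if px.min() == px.max():
            raise DegenerateThresholdError(
                f"Otsu threshold undefined for constant channel {image.channel!r}"
            )
        thr = float(threshold_otsu(px))
    else:
        thr = float(spec.threshold)
    return MarkerMask(
        pixels=px > thr,
        pixel_size_um=image.pixel_size_um,
        label=image.channel,
        tile_id=image.tile_id,
    )


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def remove_small_groups(mask: MarkerMask, spec: ThresholdSpec) -> MarkerMask:
    """Clear connected pixel groups smaller than ``spec.min_group_size_px``.

    Components are found with the declared connectivity (8 by default);
    components of size >= the minimum are left untouched, so the
    operation is idempotent and never increases the positive count.
    """
    labels, n = ndimage.label(mask.pixels, structure=_structure(spec.connectivity))
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= spec.min_group_size_px
    keep[0] = False
    return MarkerMask(
        pixels=keep[labels],
        pixel_size_um=mask.pixel_size_um,
        label=mask.label,
        tile_id=mask.tile_id,
    )


def union_masks(masks: list[MarkerMask], label: str = "MCM_mask") -> MarkerMask:
    """Logical OR of marker masks (the MC&M reference mask)."""
    if not masks:
        raise ValueError("union_masks needs at least one mask")
    require_same_geometry(*masks)
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        out |= m.pixels
    return MarkerMask(
        pixels=out,
        pixel_size_um=masks[0].pixel_size_um,
        label=label,
        tile_id=masks[0].tile_id,
    )


def restrict_cd206(cd206: MarkerMask, mcm: MarkerMask) -> MarkerMask:
    """Intersect the CD206 mask with the MC&M mask.

    CD206 also stains vessel endothelium; only CD206 signal underneath
    the myeloid/macrophage reference area is interpretable as an MC&M
    pixel class, so CD206 enters the decomposition via this restriction.
    """
    require_same_geometry(cd206, mcm)
    return MarkerMask(
        pixels=cd206.pixels & mcm.pixels,
        pixel_size_um=cd206.pixel_size_um,
        label=cd206.label,
        tile_id=cd206.tile_id,
    )


def _pattern_counts(
    marker_masks: dict[str, MarkerMask],
    reference: MarkerMask,
    markers: tuple[str, ...],
) -> dict[tuple[str, ...], int]:
    """Count reference pixels per exclusive marker combination.

    Encodes each pixel's marker pattern as a bit code and histograms the
    codes over the reference support.
    """
    require_same_geometry(reference, *[marker_masks[m] for m in markers if m in marker_masks])
    ref = reference.pixels
    code = np.zeros(ref.shape, dtype=np.uint8)
    for i, m in enumerate(markers):
        if m in marker_masks:
            code |= marker_masks[m].pixels.astype(np.uint8) << i
    hist = np.bincount(code[ref].ravel(), minlength=1 << len(markers))
    out: dict[tuple[str, ...], int] = {}
    for pattern_code, n in enumerate(hist):
        if n == 0:
            continue
        pattern = tuple(m for i, m in enumerate(markers) if pattern_code >> i & 1)
        out[pattern] = int(n)
    return out


def decompose_pixel_classes(
    marker_masks: dict[str, MarkerMask],
    reference: MarkerMask,
    markers: tuple[str, ...] = MCM_MARKERS,
) -> PixelClassTable:
    """Stratify the reference mask into exclusive single/double/triple
    classes plus the ``P4,5`` residual, and the ``P2,3,4,5`` aggregate.

    ``marker_masks`` must already be per-antibody cleaned masks, with
    CD206 restricted via :func:`restrict_cd206`.  The exclusive classes
    (including, if present, a ``"none"`` class for reference pixels with
    no positive marker) partition the reference exactly.
    """
    patterns = _pattern_counts(marker_masks, reference, markers)
    counts = {label: 0 for label in class_labels(markers)}
    multi = 0
    for pattern, n in patterns.items():
        counts[_class_label(pattern)] = counts.get(_class_label(pattern), 0) + n
        if len(pattern) >= 2:
            multi += n
    return PixelClassTable(
        tile_id=reference.tile_id,
        reference_label=reference.label,
        reference_pixel_count=reference.positive_count,
        counts=counts,
        aggregates={MULTI_LABEL: multi},
    )


def mask_class_breakdown(
    anchor: str,
    marker_masks: dict[str, MarkerMask],
    markers: tuple[str, ...] = MCM_MARKERS,
) -> PixelClassTable:
    """Decompose the pixels of one antibody's mask (the anchor) into the
    anchor-single class, anchor pairs, anchor triples and the residual.

    Same engine as :func:`decompose_pixel_classes` but with the anchor
    mask as the reference; every reference pixel carries the anchor color
    so the classes reported are exactly those that include the anchor.
    """
    if anchor not in marker_masks:
        raise KeyError(f"anchor marker {anchor!r} not among the provided masks")
    reference = marker_masks[anchor].with_label(f"{anchor}_mask")
    patterns = _pattern_counts(marker_masks, reference, markers)
    others = [m for m in markers if m != anchor]
    counts: dict[str, int] = {anchor: 0}
    for o in others:
        counts[_class_label(tuple(m for m in markers if m in (anchor, o)))] = 0
    for pair in itertools.combinations(others, 2):
        keep = tuple(m for m in markers if m == anchor or m in pair)
        counts[_class_label(keep)] = 0
    counts[RESIDUAL_LABEL] = 0
    multi = 0
    for pattern, n in patterns.items():
        counts[_class_label(pattern)] = counts.get(_class_label(pattern), 0) + n
        if len(pattern) >= 2:
            multi += n
    return PixelClassTable(
        tile_id=reference.tile_id,
        reference_label=reference.label,
        reference_pixel_count=reference.positive_count,
        counts=counts,
        aggregates={MULTI_LABEL: multi},
    )


def aggregate_case(tables: list[PixelClassTable], case_id: str = "") -> CaseSummary:
    """Average class percentages across the tiles of one case.

    Unweighted mean and sample (n-1) standard deviation of
    ``percent_of_reference`` per class.  Tiles with an undefined
    percentage (zero reference pixels) are dropped from that class's
    average and its ``n_tiles`` reduced accordingly.
    """
    if not tables:
        raise ValueError("aggregate_case needs at least one tile table")
    ref_labels = {t.reference_label for t in tables}
    if len(ref_labels) != 1:
        raise ValueError(f"tables mix reference labels: {sorted(ref_labels)}")
    frames = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    frames = frames.dropna(subset=["percent_of_reference"])
    grouped = frames.groupby("class_label", sort=False)["percent_of_reference"]
    stats = pd.DataFrame(
        {
            "mean_percent": grouped.mean(),
            "sd_percent": grouped.std(ddof=1).fillna(0.0),
            "n_tiles": grouped.size(),
        }
    ).reset_index()
    return CaseSummary(case_id=case_id, reference_label=ref_labels.pop(), stats=stats)
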