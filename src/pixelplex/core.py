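"""Core containers shared by every stage of the pipeline.

Coordinate convention (used everywhere in this package): images are 2-D
arrays indexed ``[row, col]``, 0-based, with the pixel *center* of pixel
``(r, c)`` located at physical position ``(r * pixel_size_um,
c * pixel_size_um)`` in micrometers.  Row = y increases downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelImage",
    "MarkerMask",
    "AffineTransform",
    "GeometryError",
    "PixelplexError",
]


class PixelplexError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(PixelplexError):
    """Two images/masks that must share a pixel grid do not."""


@dataclass(frozen=True)
class ChannelImage:
    """One grayscale channel of one tile.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (any numeric dtype).
    pixel_size_um
        Physical edge length of a (square) pixel, in micrometers.
    channel
        Marker / stain label, e.g. ``"CD68"`` or ``"DAPI"``.
    tile_id
        Identifier of the tile this channel belongs to.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str
    tile_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"channel image must be 2-D and non-empty, got shape {px.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def same_geometry(self, other: "ChannelImage | MarkerMask") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size_um, other.pixel_size_um
        )


@dataclass(frozen=True)
class MarkerMask:
    """Binary positive-pixel mask for one marker or derived pixel class."""

    pixels: np.ndarray
    pixel_size_um: float
    label: str
    tile_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if px.dtype != bool:
            px = px.astype(bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def positive_count(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.positive_count * self.pixel_size_um**2

    def same_geometry(self, other: "ChannelImage | MarkerMask") -> bool:
        return self.shape == other.shape and np.isclose(
            self.pixel_size_um, other.pixel_size_um
        )

    def with_label(self, label: str) -> "MarkerMask":
        return replace(self, label=label)


def require_same_geometry(*objs: "ChannelImage | MarkerMask") -> None:
    first = objs[0]
    for other in objs[1:]:
        if not first.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {first.shape}@{first.pixel_size_um}um vs "
                f"{other.shape}@{other.pixel_size_um}um"
            )


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map between the physical (µm) frames of two renditions.

    ``matrix`` is a 2x3 array mapping homogeneous source-space points to
    target-space points, both expressed in micrometers with the (row, col)
    convention of :mod:`pixelplex.core`:

        ``[r', c']^T = matrix @ [r, c, 1]^T``

    In the co-registration setting the *source* is the chromogenic (IHC)
    tile and the *target* the fluorescent (IF) tile.
    """

    matrix: np.ndarray
    source_pixel_size_um: float
    target_pixel_size_um: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("linear part of the affine transform is singular")
        object.__setattr__(self, "matrix", m)

    # ------------------------------------------------------------------
    @classmethod
    def identity(cls, source_pixel_size_um: float, target_pixel_size_um: float) -> "AffineTransform":
        return cls(
            matrix=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            source_pixel_size_um=source_pixel_size_um,
            target_pixel_size_um=target_pixel_size_um,
        )

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        translation_um: tuple[float, float] = (0.0, 0.0),
        scale: tuple[float, float] = (1.0, 1.0),
        shear: float = 0.0,
        center_um: tuple[float, float] = (0.0, 0.0),
        source_pixel_size_um: float = 1.0,
        target_pixel_size_um: float = 1.0,
    ) -> "AffineTransform":
        """Build a transform as rotation/scale/shear about ``center_um``
        followed by translation:  ``x' = A (x - c) + c + t``."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = rot @ np.diag(scale) @ np.array([[1.0, shear], [0.0, 1.0]])
        c = np.asarray(center_um, dtype=float)
        t = np.asarray(translation_um, dtype=float)
        offset = -lin @ c + c + t
        return cls(
            matrix=np.column_stack([lin, offset]),
            source_pixel_size_um=source_pixel_size_um,
            target_pixel_size_um=target_pixel_size_um,
        )

    # ------------------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset_um(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (row_um, col_um) source points to target space."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return pts @ self.linear.T + self.offset_um

    def inverse(self) -> "AffineTransform":
        inv_lin = np.linalg.inv(self.linear)
        inv_off = -inv_lin @ self.offset_um
        return AffineTransform(
            matrix=np.column_stack([inv_lin, inv_off]),
            source_pixel_size_um=self.target_pixel_size_um,
            target_pixel_size_um=self.source_pixel_size_um,
        )

    def pixel_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Linear part and offset mapping source *pixel* indices to target
        *pixel* indices (combining the µm map with both pixel sizes)."""
        lin = self.linear * (self.source_pixel_size_um / self.target_pixel_size_um)
        off = self.offset_um / self.target_pixel_size_um
        return lin, off

    def to_dict(self) -> dict:
        return {
            "matrix": self.matrix.tolist(),
            "source_pixel_size_um": self.source_pixel_size_um,
            "target_pixel_size_um": self.target_pixel_size_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(
            matrix=np.asarray(d["matrix"], dtype=float),
            source_pixel_size_um=float(d["source_pixel_size_um"]),
            target_pixel_size_um=float(d["target_pixel_size_um"]),
        )
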