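"""Affine co-registration of the chromogenic and fluorescent renditions
of one tile, driven by the nuclear counterstains (hematoxylin vs DAPI).

The two renditions of one scene differ by an unknown rigid/affine
motion and by pixel size (0.5 µm/px chromogenic vs 0.3 µm/px
fluorescent).  Both depict the same nuclei, so the transform is
estimated by maximizing the normalized cross-correlation (NCC) of the
smoothed counterstain intensities over the six affine parameters.  The
search is fully deterministic: a fixed grid of candidate rotations,
each initialized by phase-correlation for translation, followed by
derivative-free (Powell) refinement of all parameters.

The canonical frame is physical (µm) coordinates; the difference in
pixel size is folded into the transform, so a mask is resampled exactly
once when transferred between geometries (nearest-neighbor for binary
masks, bilinear for intensities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core import AffineTransform, ChannelImage, MarkerMask, PixelplexError

__all__ = [
    "RegistrationOptions",
    "RegistrationQuality",
    "RegistrationError",
    "estimate_affine",
    "transfer_mask",
    "corner_displacement_um",
]


class RegistrationError(PixelplexError):
    """Registration failed (objective below the acceptance floor)."""


@dataclass(frozen=True)
class RegistrationOptions:
    """Deterministic search settings.

    ``rotation_grid_deg`` is the fixed multi-start grid of candidate
    rotations; ``ncc_floor`` is the minimum acceptable NCC at the
    optimum — below it the registration is reported as failed rather
    than silently returning a bad transform.
    """

    smooth_sigma_um: float = 0.9
    rotation_grid_deg: tuple[float, ...] = tuple(np.arange(-10.0, 10.5, 2.5))
    ncc_floor: float = 0.2
    min_overlap_fraction: float = 0.25
    refine: bool = True
    max_refine_iter: int = 120


@dataclass
class RegistrationQuality:
    """Objective value at the optimum, plus truth-based error when a
    ground-truth transform is available (synthetic data only)."""

    ncc: float
    corner_error_um: float | None = None


def _params_to_transform(
    p: np.ndarray,
    center_src_um: np.ndarray,
    center_tgt_um: np.ndarray,
    src_ps: float,
    tgt_ps: float,
) -> AffineTransform:
    """(theta_deg, t_row_um, t_col_um, log_sr, log_sc, shear) -> transform.

    x_tgt = A (x_src - c_src) + c_tgt + t, i.e. at p = 0 the transform
    maps the source field center onto the target field center.
    """
    th = np.deg2rad(p[0])
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    lin = rot @ np.diag(np.exp(p[3:5])) @ np.array([[1.0, p[5]], [0.0, 1.0]])
    offset = -lin @ center_src_um + center_tgt_um + p[1:3]
    return AffineTransform(
        matrix=np.column_stack([lin, offset]),
        source_pixel_size_um=src_ps,
        target_pixel_size_um=tgt_ps,
    )


def _resample_to_target(
    moving: np.ndarray, transform: AffineTransform, out_shape: tuple[int, int]
) -> np.ndarray:
    """Pull the moving (source-grid) image onto the target grid; NaN
    marks pixels with no source coverage."""
    lin_px, off_px = transform.inverse().pixel_matrix()
    return ndimage.affine_transform(
        moving, lin_px, offset=off_px, output_shape=out_shape,
        order=1, mode="constant", cval=np.nan,
    )


def _ncc(a: np.ndarray, b: np.ndarray, min_overlap_fraction: float) -> float:
    valid = ~np.isnan(a)
    if valid.mean() < min_overlap_fraction:
        return -1.0
    x = a[valid]
    y = b[valid]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return -1.0
    return float((x * y).sum() / denom)


def estimate_affine(
    moving: ChannelImage,
    fixed: ChannelImage,
    options: RegistrationOptions = RegistrationOptions(),
    truth: AffineTransform | None = None,
) -> tuple[AffineTransform, RegistrationQuality]:
    """Estimate the affine map from the moving (chromogenic) to the
    fixed (fluorescent) physical frame from nuclear counterstains.

    Raises
    ------
    RegistrationError
        If the best NCC stays below ``options.ncc_floor`` — never falls
        back silently.
    ValueError
        If either image is constant.
    """
    mov = np.asarray(moving.pixels, dtype=float)
    fix = np.asarray(fixed.pixels, dtype=float)
    if np.ptp(mov) == 0 or np.ptp(fix) == 0:
        raise ValueError("registration needs non-constant images")
    src_ps, tgt_ps = moving.pixel_size_um, fixed.pixel_size_um
    mov_s = ndimage.gaussian_filter(mov, options.smooth_sigma_um / src_ps)
    fix_s = ndimage.gaussian_filter(fix, options.smooth_sigma_um / tgt_ps)
    c_src = np.array([(mov.shape[0] - 1) / 2.0, (mov.shape[1] - 1) / 2.0]) * src_ps
    c_tgt = np.array([(fix.shape[0] - 1) / 2.0, (fix.shape[1] - 1) / 2.0]) * tgt_ps

    def objective(p: np.ndarray) -> float:
        t = _params_to_transform(p, c_src, c_tgt, src_ps, tgt_ps)
        warped = _resample_to_target(mov_s, t, fix_s.shape)
        return -_ncc(warped, fix_s, options.min_overlap_fraction)

    # multi-start over rotations; translation from phase correlation
    best_p, best_val = None, np.inf
    for theta in options.rotation_grid_deg:
        p0 = np.array([theta, 0.0, 0.0, 0.0, 0.0, 0.0])
        t0 = _params_to_transform(p0, c_src, c_tgt, src_ps, tgt_ps)
        warped = _resample_to_target(mov_s, t0, fix_s.shape)
        filled = np.nan_to_num(warped, nan=float(np.nanmean(warped)))
        shift, *_ = phase_cross_correlation(fix_s, filled, upsample_factor=8,
                                            normalization=None)
        p0[1:3] = np.asarray(shift) * tgt_ps
        val = objective(p0)
        if val < best_val:
            best_p, best_val = p0, val

    if options.refine:
        res = optimize.minimize(
            objective, best_p, method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": options.max_refine_iter},
        )
        if res.fun < best_val:
            best_p, best_val = res.x, res.fun

    ncc = -best_val
    if ncc < options.ncc_floor:
        raise RegistrationError(
            f"registration failed: best NCC {ncc:.3f} below floor {options.ncc_floor}"
        )
    transform = _params_to_transform(best_p, c_src, c_tgt, src_ps, tgt_ps)
    err = None
    if truth is not None:
        err = corner_displacement_um(transform, truth, mov.shape, src_ps)
    return transform, RegistrationQuality(ncc=ncc, corner_error_um=err)


def corner_displacement_um(
    estimated: AffineTransform,
    truth: AffineTransform,
    source_shape: tuple[int, int],
    source_pixel_size_um: float,
) -> float:
    """Mean displacement (µm) between the two transforms' images of the
    source tile corners — the registration error metric for synthetic
    pairs with known truth."""
    h, w = source_shape
    corners = np.array(
        [[0.0, 0.0], [0.0, w - 1.0], [h - 1.0, 0.0], [h - 1.0, w - 1.0]]
    ) * source_pixel_size_um
    d = estimated.apply(corners) - truth.apply(corners)
    return float(np.linalg.norm(d, axis=1).mean())


def transfer_mask(
    mask: MarkerMask,
    transform: AffineTransform,
    target_shape: tuple[int, int],
    target_pixel_size_um: float,
) -> tuple[MarkerMask, MarkerMask]:
    """Resample a binary mask from the transform's source geometry into
    the target grid (nearest neighbor).

    Returns ``(transferred, covered)`` where ``covered`` marks target
    pixels that map inside the source field of view; outside it the
    transferred mask is false.  Density and distance analyses should be
    restricted to the covered (co-registered) area.
    """
    if not np.isclose(transform.source_pixel_size_um, mask.pixel_size_um):
        raise PixelplexError(
            f"mask pixel size {mask.pixel_size_um} does not match transform source "
            f"pixel size {transform.source_pixel_size_um}"
        )
    if not np.isclose(transform.target_pixel_size_um, target_pixel_size_um):
        raise PixelplexError("target pixel size does not match the transform")
    # target px -> target µm -> source µm -> source px
    lin_px, off_px = transform.inverse().pixel_matrix()
    transferred = ndimage.affine_transform(
        mask.pixels.astype(np.uint8), lin_px, offset=off_px,
        output_shape=target_shape, order=0, mode="constant", cval=0,
    ).astype(bool)
    covered = ndimage.affine_transform(
        np.ones(mask.shape, dtype=np.uint8), lin_px, offset=off_px,
        output_shape=target_shape, order=0, mode="constant", cval=0,
    ).astype(bool)
    out = MarkerMask(
        pixels=transferred, pixel_size_um=target_pixel_size_um,
        label=mask.label, tile_id=mask.tile_id,
    )
    cov = MarkerMask(
        pixels=covered, pixel_size_um=target_pixel_size_um,
        label="covered", tile_id=mask.tile_id,
    )
    return out, cov
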