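"""Shared image-grid utilities.

All images in this package follow one coordinate convention: pixel-centered,
0-based, row-major with y increasing down rows, and the physical origin at the
grid center (the ring-array center).  Pixel (i, j) of an N×M grid with spacing
h therefore sits at x = (j - (M-1)/2)·h, y = (i - (N-1)/2)·h.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pixel_coords", "resample_nearest", "center_crop", "resample_for_network"]


def pixel_coords(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (y, x) physical coordinates (mm) of pixel centers."""
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    return y[:, None], x[None, :]


def resample_nearest(img: np.ndarray, spacing: float, target_shape: tuple[int, int],
                     target_spacing: float) -> np.ndarray:
    """Nearest-neighbour resampling that preserves the physical extent.

    Pixel centers of the target grid are mapped to source pixel indices; both
    grids share the same physical center.
    """
    ny, nx = img.shape
    ty, tx = target_shape
    yy = (np.arange(ty) - (ty - 1) / 2.0) * target_spacing
    xx = (np.arange(tx) - (tx - 1) / 2.0) * target_spacing
    iy = np.clip(np.rint(yy / spacing + (ny - 1) / 2.0).astype(int), 0, ny - 1)
    ix = np.clip(np.rint(xx / spacing + (nx - 1) / 2.0).astype(int), 0, nx - 1)
    return img[np.ix_(iy, ix)]


def center_crop(img: np.ndarray, crop_shape: tuple[int, int]) -> np.ndarray:
    cy, cx = crop_shape
    ny, nx = img.shape
    if cy > ny or cx > nx:
        raise ValueError(f"crop {crop_shape} larger than image {img.shape}")
    oy = (ny - cy) // 2
    ox = (nx - cx) // 2
    return img[oy:oy + cy, ox:ox + cx]


def resample_for_network(img: np.ndarray, spacing: float, target_shape: tuple[int, int],
                         target_spacing: float, crop: tuple[int, int] | None = None) -> np.ndarray:
    """Nearest-neighbour upscale to the network grid, then center crop.

    Mirrors the preprocessing applied to both reconstruction outputs and target
    maps before they enter the image-to-image network: e.g. a 256² map at 1 mm
    is replicated onto a 1024² grid at 0.25 mm and cropped to 592² to drop the
    uniform water bath.
    """
    out = img
    if img.shape != tuple(target_shape) or spacing != target_spacing:
        out = resample_nearest(img, spacing, tuple(target_shape), target_spacing)
    if crop is not None:
        out = center_crop(out, tuple(crop))
    return out
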