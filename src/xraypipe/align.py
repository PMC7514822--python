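"""Rotation-invariant preprocessing.

The collimation box (the exposed radiation field) is the only bright region on
an otherwise black frame, so its principal axis defines the image orientation.
The stage pads the frame, binarises, closes small artefacts, estimates the box
axis with PCA and rotates the image upright using Lanczos resampling over an
8x8 neighbourhood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from xraypipe.errors import ValidationError

__all__ = [
    "OrientationResult",
    "pad_border",
    "binarise",
    "close_artifacts",
    "pca_orientation",
    "rotate_lanczos",
    "align_image",
]

#: relative eigenvalue gap below which the box orientation is undefined
_DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class OrientationResult:
    """Principal-axis estimate of the collimation box.

    ``alpha`` is the angle (degrees, in (-90, 90]) between the first principal
    component and the horizontal image axis, measured counter-clockwise in
    display coordinates (y pointing up).  ``rotation_applied`` is the
    counter-clockwise display rotation, ``90 - alpha`` folded into
    (-90, 90], that brings the axis vertical.  ``center`` is the white-pixel
    centroid as (row, col).
    """

    alpha: float
    rotation_applied: float
    center: tuple[float, float]
    degenerate: bool = False


def _as_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError(f"expected 2D grayscale image, got shape {img.shape}")
    return img


def pad_border(img: np.ndarray, pad: int = 10) -> np.ndarray:
    """Surround the image with ``pad`` black pixels on every side."""
    if pad < 0:
        raise ValidationError("pad must be >= 0")
    img = _as_gray(img)
    return np.pad(img, pad, mode="constant", constant_values=0)


def binarise(img: np.ndarray) -> np.ndarray:
    """Map every nonzero pixel to 255 and keep zeros at 0."""
    img = _as_gray(img)
    return np.where(img > 0, 255, 0).astype(np.uint8)


def close_artifacts(binary: np.ndarray, kernel: int = 10) -> np.ndarray:
    """Morphological closing with an all-ones ``kernel`` x ``kernel`` element.

    Dilation uses border value 0 (the black frame stays black) and erosion
    border value 1, so white content touching the border is not eaten away and
    closing stays extensive.
    """
    binary = _as_gray(binary)
    vals = np.unique(binary)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValidationError("close_artifacts expects a binary {0,255} image")
    structure = np.ones((kernel, kernel), dtype=bool)
    fg = binary > 0
    dil = ndimage.binary_dilation(fg, structure=structure, border_value=0)
    ero = ndimage.binary_erosion(dil, structure=structure, border_value=1)
    return np.where(ero, 255, 0).astype(np.uint8)


def pca_orientation(binary: np.ndarray) -> OrientationResult:
    """Orientation of the white region treated as a point cloud.

    White-pixel coordinates are the observations; the eigenvector of their
    covariance with the largest eigenvalue is the box axis.
    """
    binary = _as_gray(binary)
    rows, cols = np.nonzero(binary)
    if rows.size < 2:
        raise ValidationError("no box found: fewer than 2 white pixels")
    # display coordinates: x right, y up
    x = cols.astype(float)
    y = -rows.astype(float)
    center = (float(rows.mean()), float(cols.mean()))
    cov = np.cov(np.stack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    gap = evals[1] - evals[0]
    if gap <= _DEGENERACY_RTOL * max(evals[1], 1.0):
        warnings.warn("degenerate box: equal principal variances, no rotation applied")
        return OrientationResult(alpha=90.0, rotation_applied=0.0, center=center, degenerate=True)
    vx, vy = evecs[:, 1]  # eigenvector of the largest eigenvalue
    alpha = math.degrees(math.atan2(vy, vx))
    if alpha <= -90.0:
        alpha += 180.0
    elif alpha > 90.0:
        alpha -= 180.0
    rotation = 90.0 - alpha
    if rotation > 90.0:
        rotation -= 180.0
    return OrientationResult(alpha=alpha, rotation_applied=rotation, center=center)


def _lanczos_kernel(t: np.ndarray, a: int) -> np.ndarray:
    return np.where(np.abs(t) < a, np.sinc(t) * np.sinc(t / a), 0.0)


def rotate_lanczos(img: np.ndarray, angle_deg: float, a: int = 4) -> np.ndarray:
    """Rotate ``img`` counter-clockwise (display sense) with Lanczos-``a``.

    The canvas expands to the rotated bounding box; uncovered pixels are 0.
    ``a=4`` samples an 8x8 source neighbourhood per output pixel.
    """
    img = _as_gray(img).astype(np.float64)
    h, w = img.shape
    if angle_deg == 0.0:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    phi = math.radians(angle_deg)
    c, s = math.cos(phi), math.sin(phi)
    nw = int(math.ceil(abs(c) * w + abs(s) * h))
    nh = int(math.ceil(abs(c) * h + abs(s) * w))
    cy_in, cx_in = (h - 1) / 2.0, (w - 1) / 2.0
    cy_o, cx_o = (nh - 1) / 2.0, (nw - 1) / 2.0

    ro, co = np.meshgrid(np.arange(nh), np.arange(nw), indexing="ij")
    dy = ro - cy_o
    dx = co - cx_o
    # inverse map of a display-CCW rotation (array y points down)
    sx = c * dx - s * dy + cx_in
    sy = s * dx + c * dy + cy_in

    inside = (sx >= -1) & (sx <= w) & (sy >= -1) & (sy <= h)
    sx = np.where(inside, sx, 0.0)
    sy = np.where(inside, sy, 0.0)
    fx = np.floor(sx).astype(np.int64)
    fy = np.floor(sy).astype(np.int64)
    tx = sx - fx
    ty = sy - fy

    pad = a + 1
    padded = np.pad(img, pad, mode="constant", constant_values=0.0)
    acc = np.zeros((nh, nw))
    wsum = np.zeros((nh, nw))
    offsets = np.arange(-a + 1, a + 1)
    wys = [_lanczos_kernel(ty - k, a) for k in offsets]
    wxs = [_lanczos_kernel(tx - k, a) for k in offsets]
    for ky, wy in zip(offsets, wys):
        yy = np.clip(fy + ky + pad, 0, padded.shape[0] - 1)
        for kx, wx in zip(offsets, wxs):
            xx = np.clip(fx + kx + pad, 0, padded.shape[1] - 1)
            wgt = wy * wx
            acc += wgt * padded[yy, xx]
            wsum += wgt
    out = acc / np.where(np.abs(wsum) > 1e-12, wsum, 1.0)
    out[~inside] = 0.0
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def align_image(
    img: np.ndarray, pad: int = 10, kernel: int = 10
) -> tuple[np.ndarray, OrientationResult]:
    """Full alignment: pad, binarise, close, PCA, rotate upright.

    Returns the rotated 8-bit image (canvas expanded, new pixels black) and the
    orientation estimate.
    """
    padded = pad_border(img, pad)
    binary = binarise(padded)
    closed = close_artifacts(binary, kernel)
    orient = pca_orientation(closed)
    if orient.degenerate or abs(orient.rotation_applied) < 1e-9:
        return padded.astype(np.uint8), orient
    aligned = rotate_lanczos(padded, orient.rotation_applied)
    return aligned, orient
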