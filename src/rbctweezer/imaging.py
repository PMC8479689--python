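"""Synthetic micrograph rendering and cell morphometry.

Replaces interactive image-analysis measurement with a reproducible
pipeline: render an elliptical cell on a grayscale frame, segment it by
Otsu thresholding, and measure area and equivalent-ellipse semi-axes
from second central moments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu

from .errors import GeometryError, InvalidArgumentError, SegmentationError
from .records import GeometryMeasurement


@dataclass(frozen=True)
class CellImage:
    """Grayscale frame plus its physical pixel size (μm/px)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidArgumentError(f"pixel_size must be > 0, got {self.pixel_size}")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise InvalidArgumentError("pixels must be a nonempty 2-D grid")
        if not np.all(np.isfinite(px)):
            raise InvalidArgumentError("pixel intensities must be finite")


@dataclass(frozen=True)
class EllipseShape:
    """Elliptical cell outline: semi-axes in μm, orientation in radians,
    centre in μm from the frame's top-left corner (row, col order)."""

    semi_major_um: float
    semi_minor_um: float
    orientation: float = 0.0
    center_um: tuple[float, float] | None = None


def render_cell(
    shape: EllipseShape,
    pixel_size: float,
    image_size: int = 256,
    foreground: float = 1.0,
    background: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CellImage:
    """Render an anti-aliased ellipse with Gaussian pixel noise.

    The edge is a 1-px linear ramp computed from the approximate signed
    Euclidean distance to the ellipse boundary, so a threshold at half
    contrast recovers the analytic outline to sub-pixel accuracy.
    Deterministic for a given ``seed``.
    """
    if pixel_size <= 0:
        raise InvalidArgumentError("pixel_size must be > 0")
    a = shape.semi_major_um / pixel_size
    b = shape.semi_minor_um / pixel_size
    if min(a, b) < 2.0:
        raise GeometryError(
            f"semi-axes must be >= 2 px after conversion; got ({a:.2f}, {b:.2f}) px")
    if shape.center_um is None:
        cr = cc = image_size / 2.0
    else:
        cr = shape.center_um[0] / pixel_size
        cc = shape.center_um[1] / pixel_size
    if (cr - a < 1.0 or cc - a < 1.0
            or cr + a > image_size - 2.0 or cc + a > image_size - 2.0):
        raise GeometryError(
            f"cell (semi-major {a:.1f} px at ({cr:.1f}, {cc:.1f})) does not fit "
            f"inside a {image_size}-px frame")

    rows, cols = np.mgrid[0:image_size, 0:image_size].astype(float)
    dr = rows - cr
    dc = cols - cc
    # rotate into the ellipse frame; orientation measured from the column axis
    ct, st = math.cos(shape.orientation), math.sin(shape.orientation)
    u = dc * ct + dr * st      # along semi-major
    v = -dc * st + dr * ct     # along semi-minor
    f = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # approximate signed pixel distance to the boundary: (1 - f) / |grad f|
    grad = np.sqrt((u / a ** 2) ** 2 + (v / b ** 2) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(grad > 0, (1.0 - f) * f / np.maximum(grad, 1e-12), a)
    alpha = np.clip(dist + 0.5, 0.0, 1.0)
    img = background + (foreground - background) * alpha
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return CellImage(pixels=img, pixel_size=pixel_size)


def segment_cell(image: CellImage) -> np.ndarray:
    """Binary cell mask via Otsu thresholding.

    The threshold maximises between-class variance; polarity (bright or
    dark cell) is inferred from the frame border, the largest connected
    foreground component is kept and its holes filled.
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.max() == px.min():
        raise SegmentationError("uniform image: no foreground to segment")
    thresh = threshold_otsu(px)
    border = np.concatenate([px[0, :], px[-1, :], px[:, 0], px[:, -1]])
    if np.median(border) > thresh:  # dark cell on bright background
        mask = px < thresh
    else:
        mask = px > thresh
    if not mask.any():
        raise SegmentationError("no foreground pixels after thresholding")
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def measure_geometry(mask: np.ndarray, pixel_size: float) -> GeometryMeasurement:
    """Area and equivalent-ellipse semi-axes of a binary mask.

    Area is the pixel count times the pixel area; the semi-axes and
    orientation come from the second central moments (the ellipse with
    the same moments as the mask), which is robust to boundary noise.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("mask is empty")
    if pixel_size <= 0:
        raise InvalidArgumentError("pixel_size must be > 0")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    area = float(props.area) * pixel_size ** 2
    r_max = props.axis_major_length / 2.0 * pixel_size
    r_min = props.axis_minor_length / 2.0 * pixel_size
    r_equiv = math.sqrt(area / math.pi)
    if r_min <= 0.0:  # degenerate (e.g. single-pixel) mask
        r_max = r_min = r_equiv
    # regionprops measures from the row axis; report from the column axis
    # (the renderer's convention), folded into [0, pi)
    orientation = float((math.pi / 2.0 - props.orientation) % math.pi)
    return GeometryMeasurement(r_max=r_max, r_min=r_min, area=area,
                               orientation=orientation)


def measure_image(image: CellImage) -> GeometryMeasurement:
    """Convenience: segment then measure one image."""
    return measure_geometry(segment_cell(image), image.pixel_size)
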