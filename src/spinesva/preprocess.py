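"""Deterministic resize/pad with invertible landmark transforms, plus training augmentation.

Radiographs arrive at arbitrary resolutions (clinical whole-spine images
average around 3552x1434).  Before entering the network every image is
resized, possibly anisotropically, to a fixed inner region (default 768x340)
and then zero-padded symmetrically in width to the network canvas (default
768x448).  The generous horizontal padding matters during training: images
are rotated by up to +/-30 degrees and the spine must not be clipped.

Coordinate frames
-----------------
* "original": pixel coordinates in the unresized image, 0-based, x = column,
  pixel centers at integer coordinates.
* "canvas": coordinates on the padded network input, same conventions.

The forward map is ``x' = (x + 0.5) * scale_x - 0.5 + pad_left`` (half-pixel
centers, matching the image resampling), and analogously for y.  The map is
recorded per image and inverted exactly when predictions are converted back
to the original resolution for millimetre evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .heatmaps import LandmarkPoint

__all__ = [
    "AugmentParams",
    "ImageRecord",
    "PreprocessSpec",
    "ResizePadTransform",
    "augment",
    "draw_augment_values",
    "invert_coordinates",
    "load_image",
    "resize_pad",
]


@dataclass
class ImageRecord:
    """A grayscale image with physical scale, patient orientation and optional landmarks.

    ``pixels`` are floats in [0, 1] (integer images are normalized by bit
    depth on loading).  ``facing`` states which way the patient faces in the
    image; it fixes the anterior direction and hence the sign of SVA.
    Landmarks, when present, are in the original-resolution frame.
    """

    pixels: np.ndarray
    mm_per_pixel_x: float
    mm_per_pixel_y: float
    facing: str = "right"
    landmarks: Sequence[LandmarkPoint] | None = None
    image_path: str | None = None

    def __post_init__(self) -> None:
        if self.pixels is not None:
            px = np.asarray(self.pixels)
            if px.ndim != 2 or px.size == 0:
                raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
            self.pixels = px
        if not (self.mm_per_pixel_x > 0 and self.mm_per_pixel_y > 0):
            raise ValueError("mm-per-pixel factors must be positive")
        if self.facing not in ("left", "right"):
            raise ValueError(f"facing must be 'left' or 'right', got {self.facing!r}")
        if self.landmarks is not None and self.pixels is not None:
            h, w = self.pixels.shape
            for p in self.landmarks:
                if not (0 <= p.x < w and 0 <= p.y < h):
                    raise ValueError(
                        f"landmark ({p.x}, {p.y}) outside the {h}x{w} image bounds"
                    )


@dataclass(frozen=True)
class PreprocessSpec:
    """Canvas geometry: resize to (canvas_height x inner_width), pad to canvas_width."""

    canvas_height: int = 768
    canvas_width: int = 448
    inner_width: int = 340

    def __post_init__(self) -> None:
        if self.inner_width > self.canvas_width:
            raise ValueError("inner_width cannot exceed canvas_width")

    @property
    def pad_left(self) -> int:
        return (self.canvas_width - self.inner_width) // 2

    @classmethod
    def for_canvas(cls, height: int, width: int) -> "PreprocessSpec":
        """Scale the default 768x448 geometry (inner width 340) to another canvas."""
        inner = int(round(width * 340 / 448))
        return cls(canvas_height=height, canvas_width=width, inner_width=inner)


@dataclass(frozen=True)
class ResizePadTransform:
    """Affine original->canvas coordinate map; exactly invertible."""

    scale_x: float
    scale_y: float
    pad_left: int
    pad_top: int = 0

    def apply(self, point: LandmarkPoint) -> LandmarkPoint:
        return LandmarkPoint(
            x=(point.x + 0.5) * self.scale_x - 0.5 + self.pad_left,
            y=(point.y + 0.5) * self.scale_y - 0.5 + self.pad_top,
        )

    def invert(self, point: LandmarkPoint) -> LandmarkPoint:
        return LandmarkPoint(
            x=(point.x - self.pad_left + 0.5) / self.scale_x - 0.5,
            y=(point.y - self.pad_top + 0.5) / self.scale_y - 0.5,
        )


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as float in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype in (np.uint16, np.int32):
        return arr.astype(np.float32) / 65535.0
    arr = arr.astype(np.float32)
    peak = arr.max()
    return arr / peak if peak > 1 else arr


def resize_pad(
    record: ImageRecord, spec: PreprocessSpec = PreprocessSpec()
) -> tuple[np.ndarray, list[LandmarkPoint] | None, ResizePadTransform]:
    """Resize to the fixed inner region, pad symmetrically to the canvas.

    Returns the canvas image (canvas_height x canvas_width), the landmarks
    mapped into canvas coordinates (or None), and the recorded transform.
    """
    img = record.pixels
    h, w = img.shape
    if (h, w) == (spec.canvas_height, spec.canvas_width):
        # Already canvas-sized (e.g. phantoms rendered on the network canvas):
        # pass through untouched with an identity transform.
        canvas = img.astype(np.float32)
        transform = ResizePadTransform(scale_x=1.0, scale_y=1.0, pad_left=0)
        points = None
        if record.landmarks is not None:
            points = list(record.landmarks)
        return canvas, points, transform
    target = (spec.canvas_height, spec.inner_width)
    resized = _sk_resize(
        img.astype(np.float32), target, order=1, anti_aliasing=(h > target[0] or w > target[1]),
        preserve_range=True,
    ).astype(np.float32)
    pad_left = spec.pad_left
    pad_right = spec.canvas_width - spec.inner_width - pad_left
    canvas = np.pad(resized, ((0, 0), (pad_left, pad_right)))
    transform = ResizePadTransform(
        scale_x=spec.inner_width / w,
        scale_y=spec.canvas_height / h,
        pad_left=pad_left,
    )
    points = None
    if record.landmarks is not None:
        points = [transform.apply(p) for p in record.landmarks]
    return canvas, points, transform


def invert_coordinates(point: LandmarkPoint, transform: ResizePadTransform) -> LandmarkPoint:
    """Map a canvas-frame point back to the original-resolution frame.

    The result may fall outside the original image bounds (e.g. a point in
    the padding region maps to a negative x); callers flag such points.
    """
    return transform.invert(point)


@dataclass(frozen=True)
class AugmentParams:
    """Uniform draw ranges for training augmentation."""

    scale_range: tuple[float, float] = (0.9, 1.1)
    angle_range_deg: tuple[float, float] = (-30.0, 30.0)
    blur_range: tuple[float, float] = (0.0, 0.5)


def draw_augment_values(
    params: AugmentParams, rng: np.random.Generator
) -> tuple[float, float, float]:
    """One (scale, angle_deg, blur_sigma) draw, each uniform within its range."""
    scale = rng.uniform(*params.scale_range)
    angle = rng.uniform(*params.angle_range_deg)
    blur = rng.uniform(*params.blur_range)
    return scale, angle, blur


def _affine_about_center(
    scale: float, angle_deg: float, height: int, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward map p' = A p + t, scaling then rotating about the canvas center."""
    theta = math.radians(angle_deg)
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    a = rot * scale
    center = np.array([(width - 1) / 2.0, (height - 1) / 2.0])
    t = center - a @ center
    return a, t


def _apply_affine(
    image: np.ndarray,
    landmarks: Sequence[LandmarkPoint],
    scale: float,
    angle_deg: float,
) -> tuple[np.ndarray, list[LandmarkPoint]]:
    h, w = image.shape
    a, t = _affine_about_center(scale, angle_deg, h, w)
    # ndimage.affine_transform pulls from input coords: needs the inverse map
    # in (row, col) order.
    a_inv = np.linalg.inv(a)
    a_inv_rc = a_inv[::-1, ::-1]  # swap x/y axes to row/col
    t_rc = (-a_inv @ t)[::-1]
    warped = ndimage.affine_transform(
        image.astype(np.float32), a_inv_rc, offset=t_rc, order=1, mode="constant", cval=0.0
    ).astype(np.float32)
    moved = [
        LandmarkPoint(*(a @ np.array([p.x, p.y]) + t)) for p in landmarks
    ]
    return warped, moved


def augment(
    image: np.ndarray,
    landmarks: Sequence[LandmarkPoint],
    params: AugmentParams = AugmentParams(),
    seed: int = 0,
) -> tuple[np.ndarray, list[LandmarkPoint]]:
    """Seeded scale -> rotate -> blur augmentation with co-transformed landmarks.

    The geometric part is one combined affine pass (bilinear, zero fill)
    about the canvas center; blur is a Gaussian filter and leaves landmarks
    untouched.  If a draw would move any landmark off the canvas, the next
    substream draw is tried (up to 10 times) before falling back to the
    identity, so the training-set size never shrinks.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError(f"augment expects a 2-D canvas image, got shape {img.shape}")
    h, w = img.shape
    for attempt in range(10):
        rng = np.random.default_rng([int(seed), attempt])
        scale, angle, blur = draw_augment_values(params, rng)
        if scale == 1.0 and angle == 0.0:
            warped, moved = img, list(landmarks)
        else:
            warped, moved = _apply_affine(img, landmarks, scale, angle)
        if all(0 <= p.x < w and 0 <= p.y < h for p in moved):
            if blur > 0:
                warped = ndimage.gaussian_filter(warped, sigma=blur).astype(np.float32)
            return warped, moved
    return img.copy(), list(landmarks)
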