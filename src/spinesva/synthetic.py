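"""Seeded spine-phantom generator with exact ground-truth landmarks.

Clinical whole-spine radiographs cannot be redistributed, so every stage of
the toolkit is exercised on synthetic phantoms that copy the *structure* of
the clinical data: a chain of bright vertebra-like bodies along a smooth,
variably curved and leaning axis (vertebrae shrink toward the neck), a
wedge-shaped sacrum whose posterior-superior vertex is the second landmark,
a background gradient with white noise, and optional nuisance structures -
a bright ellipse occluding the C7 region ("shoulder") and a bright rod along
the spine ("implant").  The C7-analogue landmark is the centroid of the
topmost full vertebral body.  Ground truth is exact by construction; an
optional jitter emulates inter-rater annotation variation.

Determinism: phantom ``i`` of a dataset draws from the substream
``default_rng([seed, i])``, so the first ``m`` phantoms of a size-``n``
dataset equal an independent size-``m`` dataset with the same seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .heatmaps import LandmarkPoint
from .preprocess import ImageRecord

__all__ = [
    "SpinePhantomParams",
    "SyntheticAnnotatedImage",
    "generate_dataset",
    "generate_phantom",
    "write_dataset",
]


@dataclass(frozen=True)
class SpinePhantomParams:
    """Generation controls; defaults are the desk-scale study conditions.

    The default 192x112 canvas (divisible by 16) lets a reduced-width network
    train on a CPU in minutes; 768x448 is supported for full-scale runs.
    """

    height: int = 192
    width: int = 112
    n_vertebrae: int = 18
    curvature_amplitude: float | None = None  # pixels; default 0.08 * width
    noise_sd: float = 0.03
    occlusion_prob: float = 0.2
    implant_prob: float = 0.2
    mm_per_pixel_range: tuple[float, float] = (0.8, 1.2)
    annotation_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("canvas must be at least 32x32")
        for p in (self.occlusion_prob, self.implant_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        if self.n_vertebrae < 3:
            raise ValueError("need at least 3 vertebrae")
        # Each body needs a couple of pixels of height along the axis span.
        if self.n_vertebrae * 4 > self.height:
            raise ValueError(
                f"canvas height {self.height} too small to place {self.n_vertebrae} vertebrae"
            )

    @property
    def curvature(self) -> float:
        return (
            self.curvature_amplitude
            if self.curvature_amplitude is not None
            else 0.08 * self.width
        )


@dataclass
class SyntheticAnnotatedImage:
    record: ImageRecord
    metadata: dict = field(default_factory=dict)

    @property
    def c7(self) -> LandmarkPoint:
        return self.record.landmarks[0]

    @property
    def s1(self) -> LandmarkPoint:
        return self.record.landmarks[1]

    @property
    def sva_mm(self) -> float:
        """Ground-truth signed SVA analogue in mm."""
        sign = 1.0 if self.record.facing == "right" else -1.0
        return (self.c7.x - self.s1.x) * self.record.mm_per_pixel_x * sign


def _rounded_body_mask(
    yy: np.ndarray, xx: np.ndarray, cx: float, cy: float, hw: float, hh: float, angle: float
) -> np.ndarray:
    """Superellipse (rounded-rectangle) mask rotated by the local axis tangent."""
    dx = xx - cx
    dy = yy - cy
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    return (np.abs(u) / hw) ** 4 + (np.abs(v) / hh) ** 4 <= 1.0


def generate_phantom(
    params: SpinePhantomParams, seed: int, index: int = 0
) -> SyntheticAnnotatedImage:
    """One phantom, deterministic in ``(params, seed, index)``."""
    rng = np.random.default_rng([int(seed), int(index)])
    h, w = params.height, params.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # Background: mild vertical gradient plus white noise, structures added on top.
    base = rng.uniform(0.08, 0.18)
    tilt = rng.uniform(-0.05, 0.05)
    img = base + tilt * (yy / h - 0.5)

    # Spine axis from caudal (t=0, bottom) to cranial (t=1, top): a low-order
    # sine for scoliosis-like curvature plus a linear lean so the signed SVA
    # analogue spans both signs across a dataset.
    n = params.n_vertebrae
    # Framing varies between radiographs: the cranial and caudal margins are
    # drawn per image so landmark rows are not constant across a dataset.
    t_top = rng.uniform(0.80, 0.94)
    t_bot = rng.uniform(0.08, 0.20)
    amp = params.curvature * rng.uniform(0.3, 1.0)
    freq = rng.uniform(0.8, 1.6)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    lean = rng.uniform(-0.12, 0.12) * w if params.curvature > 0 else 0.0
    cx0 = w / 2.0 + rng.uniform(-0.04, 0.04) * w

    def axis_x(t: np.ndarray | float) -> np.ndarray | float:
        return cx0 + amp * np.sin(freq * np.pi * np.asarray(t) + phase) + lean * np.asarray(t)

    def axis_y(t: np.ndarray | float) -> np.ndarray | float:
        return (1.0 - np.asarray(t)) * (h * (1 - t_bot)) + np.asarray(t) * (h * (1 - t_top))

    ts = np.linspace(0.0, 1.0, n)
    span = axis_y(0.0) - axis_y(1.0)
    pitch = span / (n - 1)
    contrast = rng.uniform(0.3, 0.7)

    centers = []
    for i, t in enumerate(ts):
        cx, cy = float(axis_x(t)), float(axis_y(t))
        # Bodies shrink toward the neck (cranial end).
        size_factor = 1.0 - 0.45 * t
        hh_i = 0.36 * pitch * size_factor
        hw_i = 0.17 * w * size_factor
        eps = 1e-3
        tangent = np.arctan2(
            float(axis_y(t + eps) - axis_y(t - eps)), float(axis_x(t + eps) - axis_x(t - eps))
        )
        angle = tangent + np.pi / 2.0  # body's long (width) axis is normal to the spine
        mask = _rounded_body_mask(yy, xx, cx, cy, hw_i, hh_i, angle)
        img[mask] += contrast
        centers.append((cx, cy, hw_i, hh_i, angle))

    # Topmost full vertebra is the C7 analogue; its centroid is the landmark.
    c7 = LandmarkPoint(x=centers[-1][0], y=centers[-1][1])

    # Sacrum: bright wedge below the lowest body; the posterior-superior
    # vertex is the landmark.  Drawn facing 'right' (anterior toward +x), so
    # posterior is the -x side; a facing-'left' phantom is mirrored at the end.
    sac_cx, sac_cy = float(axis_x(0.0)), float(axis_y(0.0))
    sw = 0.30 * w
    sh = 0.10 * h
    post_x = sac_cx - sw * 0.45
    top_y = sac_cy + 0.45 * pitch
    v_post = np.array([post_x, top_y])  # posterior-superior corner
    v_ant = np.array([sac_cx + sw * 0.55, top_y + 0.35 * sh])
    v_inf = np.array([sac_cx - sw * 0.05, top_y + sh])
    d1 = (xx - v_post[0]) * (v_ant[1] - v_post[1]) - (yy - v_post[1]) * (v_ant[0] - v_post[0])
    d2 = (xx - v_ant[0]) * (v_inf[1] - v_ant[1]) - (yy - v_ant[1]) * (v_inf[0] - v_ant[0])
    d3 = (xx - v_inf[0]) * (v_post[1] - v_inf[1]) - (yy - v_inf[1]) * (v_post[0] - v_inf[0])
    wedge = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | ((d1 <= 0) & (d2 <= 0) & (d3 <= 0))
    img[wedge] += contrast
    s1 = LandmarkPoint(x=float(v_post[0]), y=float(v_post[1]))

    occluded = rng.random() < params.occlusion_prob
    if occluded:
        # Bright ellipse over the shoulder region near C7.
        ecx = c7.x + rng.uniform(-0.1, 0.1) * w
        ecy = c7.y + rng.uniform(0.0, 0.08) * h
        ea, eb = 0.28 * w, 0.07 * h
        ell = ((xx - ecx) / ea) ** 2 + ((yy - ecy) / eb) ** 2 <= 1.0
        img[ell] += rng.uniform(0.2, 0.4)

    implanted = rng.random() < params.implant_prob
    if implanted:
        # Bright rod alongside a mid-spine segment.
        t0, t1 = sorted(rng.uniform(0.1, 0.8, size=2))
        tr = np.linspace(min(t0, t1 - 0.2), t1, 64)
        rod_x = np.asarray(axis_x(tr)) + 0.06 * w
        rod_y = np.asarray(axis_y(tr))
        rod_mask = np.zeros_like(img, dtype=bool)
        r2 = (0.03 * w) ** 2
        for rx, ry in zip(rod_x, rod_y):
            rod_mask |= (xx - rx) ** 2 + (yy - ry) ** 2 <= r2
        img[rod_mask] += 0.45

    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    facing = "right" if rng.random() < 0.5 else "left"
    if facing == "left":
        img = img[:, ::-1].copy()
        c7 = LandmarkPoint(x=w - 1 - c7.x, y=c7.y)
        s1 = LandmarkPoint(x=w - 1 - s1.x, y=s1.y)

    if params.annotation_jitter_sd > 0:
        jit = rng.normal(0.0, params.annotation_jitter_sd, size=4)
        c7 = LandmarkPoint(x=c7.x + jit[0], y=c7.y + jit[1])
        s1 = LandmarkPoint(x=s1.x + jit[2], y=s1.y + jit[3])

    mmx = rng.uniform(*params.mm_per_pixel_range)
    mmy = rng.uniform(*params.mm_per_pixel_range)
    record = ImageRecord(
        pixels=img.astype(np.float32),
        mm_per_pixel_x=float(mmx),
        mm_per_pixel_y=float(mmy),
        facing=facing,
        landmarks=[c7, s1],
    )
    return SyntheticAnnotatedImage(
        record=record,
        metadata={
            "seed": int(seed),
            "index": int(index),
            "occluded": bool(occluded),
            "implanted": bool(implanted),
            "contrast": float(contrast),
            # Geometry of the designated C7-analogue body, pre-mirroring:
            # (cx, cy, half_width, half_height, angle).
            "c7_body": tuple(float(v) for v in centers[-1]),
            "mirrored": facing == "left",
        },
    )


def generate_dataset(
    n: int, params: SpinePhantomParams, seed: int
) -> list[SyntheticAnnotatedImage]:
    """``n`` phantoms from independent substreams of ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_phantom(params, seed, index=i) for i in range(n)]


def write_dataset(
    images: Sequence[SyntheticAnnotatedImage], out_dir: str | Path
) -> Path:
    """Write 16-bit PNGs plus an annotations CSV in the standard format.

    The CSV is the same schema the prediction pipeline reads, so synthetic
    and real data share one loader.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "annotations.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "image_path",
                "c7_x",
                "c7_y",
                "s1_x",
                "s1_y",
                "mm_per_pixel_x",
                "mm_per_pixel_y",
                "facing",
            ]
        )
        for i, im in enumerate(images):
            name = f"phantom_{i:04d}.png"
            arr = np.clip(im.record.pixels, 0.0, 1.0)
            Image.fromarray((arr * 65535).astype(np.uint16)).save(out_dir / name)
            writer.writerow(
                [
                    name,
                    f"{im.c7.x:.4f}",
                    f"{im.c7.y:.4f}",
                    f"{im.s1.x:.4f}",
                    f"{im.s1.y:.4f}",
                    f"{im.record.mm_per_pixel_x:.6f}",
                    f"{im.record.mm_per_pixel_y:.6f}",
                    im.record.facing,
                ]
            )
    return csv_path
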