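"""Regression-target heatmaps for landmark detection.

Instead of regressing landmark coordinates directly, the network is trained to
reproduce a smooth target image peaked at each landmark.  Two target families
are provided:

* a radially symmetric **Gaussian**, ``G(x, y) = c * exp(-((x-xk)^2 + (y-yk)^2) / (2 sigma^2))``;
* an **exponential** with an L1 (cross-shaped) profile,
  ``E(x, y) = c * exp(-alpha * (|x-xk| + |y-yk|))``.

The exponential's decay rate ``alpha`` is never chosen independently: it is
coupled to ``sigma`` so that both families reach half of their maximum at the
same four axis points ``(xk +/- sigma*sqrt(2 ln 2), yk)`` and
``(xk, yk +/- sigma*sqrt(2 ln 2))``.  With matched half-maximum contours the
exponential has a sharper peak but decays more slowly along the axes, which is
what makes narrow exponential targets easier to learn than narrow Gaussians.

Pixel convention: 0-based grid, the pixel in column ``i`` and row ``j`` is
sampled at the integer coordinate ``(i, j)``; ``x`` is the column coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "HALF_MAX_DISTANCE_FACTOR",
    "HeatmapSpec",
    "LandmarkPoint",
    "TargetStack",
    "alpha_from_sigma",
    "build_targets",
    "exponential_heatmap",
    "gaussian_heatmap",
    "make_heatmap",
]

#: Axis distance, in units of sigma, at which a Gaussian falls to half maximum.
HALF_MAX_DISTANCE_FACTOR = math.sqrt(2.0 * math.log(2.0))

Family = Literal["gaussian", "exponential"]


@dataclass(frozen=True)
class LandmarkPoint:
    """A continuous (column, row) location; subpixel values permitted."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"landmark coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class HeatmapSpec:
    """Target-function family, width and amplitude.

    ``sigma`` is the Gaussian width in pixels; for the exponential family the
    decay rate is derived from it via :func:`alpha_from_sigma` and never stored
    independently.  ``amplitude`` is the peak value ``c``; the default follows
    the convention of a large constant (1000) so that pixels near the landmark
    dominate a mean-squared-error loss.
    """

    family: Family = "exponential"
    sigma: float = 1.57
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "exponential"):
            raise ValueError(f"unknown heatmap family: {self.family!r}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")

    @property
    def alpha(self) -> float:
        """Decay rate of the matched exponential."""
        return alpha_from_sigma(self.sigma)


@dataclass
class TargetStack:
    """Per-landmark target heatmaps stacked along the last axis (H x W x K)."""

    values: np.ndarray
    landmark_order: Sequence[str] = field(default_factory=tuple)

    @property
    def n_landmarks(self) -> int:
        return self.values.shape[-1]

    def channel(self, k: int) -> np.ndarray:
        return self.values[..., k]


def alpha_from_sigma(sigma: float) -> float:
    """Decay rate alpha matching the exponential's axis half-maximum to a Gaussian of width sigma.

    The defining constraint is ``exp(-alpha * sigma * sqrt(2 ln 2)) = 1/2``,
    i.e. both families reach half maximum at the same axis distance
    ``sigma * sqrt(2 ln 2)``.  Solving gives ``alpha = sqrt(ln 2 / 2) / sigma``.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return math.sqrt(math.log(2.0) / 2.0) / sigma


def _grid_offsets(
    center: LandmarkPoint, height: int, width: int
) -> tuple[np.ndarray, np.ndarray]:
    if height < 1 or width < 1:
        raise ValueError(f"canvas must be at least 1x1, got {height}x{width}")
    dx = np.arange(width, dtype=float) - center.x
    dy = np.arange(height, dtype=float) - center.y
    return dx, dy


def gaussian_heatmap(
    center: LandmarkPoint, spec: HeatmapSpec, height: int, width: int
) -> np.ndarray:
    """Gaussian target of shape (height, width) peaked at ``center``."""
    if spec.family != "gaussian":
        raise ValueError(f"spec.family must be 'gaussian', got {spec.family!r}")
    dx, dy = _grid_offsets(center, height, width)
    r2 = dy[:, None] ** 2 + dx[None, :] ** 2
    return spec.amplitude * np.exp(-r2 / (2.0 * spec.sigma**2))


def exponential_heatmap(
    center: LandmarkPoint, spec: HeatmapSpec, height: int, width: int
) -> np.ndarray:
    """Exponential (L1-profile) target of shape (height, width) peaked at ``center``."""
    if spec.family != "exponential":
        raise ValueError(f"spec.family must be 'exponential', got {spec.family!r}")
    dx, dy = _grid_offsets(center, height, width)
    l1 = np.abs(dy)[:, None] + np.abs(dx)[None, :]
    return spec.amplitude * np.exp(-spec.alpha * l1)


def make_heatmap(
    center: LandmarkPoint, spec: HeatmapSpec, height: int, width: int
) -> np.ndarray:
    """Dispatch on ``spec.family``."""
    if spec.family == "gaussian":
        return gaussian_heatmap(center, spec, height, width)
    return exponential_heatmap(center, spec, height, width)


def build_targets(
    landmarks: Sequence[LandmarkPoint],
    spec: HeatmapSpec,
    height: int,
    width: int,
    landmark_order: Sequence[str] | None = None,
) -> TargetStack:
    """Stack one single-landmark heatmap per landmark, channels independent.

    Each landmark is rendered on its own channel so localization never has to
    separate or identify peaks on a shared map.  The default channel order for
    SVA is ``("c7", "s1")``.
    """
    if landmark_order is None:
        landmark_order = ("c7", "s1") if len(landmarks) == 2 else tuple(
            f"landmark_{k}" for k in range(len(landmarks))
        )
    if len(landmark_order) != len(landmarks):
        raise ValueError("landmark_order length must match number of landmarks")
    channels = []
    for label, point in zip(landmark_order, landmarks):
        if not (0 <= point.x < width and 0 <= point.y < height):
            raise ValueError(
                f"landmark {label!r} at ({point.x}, {point.y}) lies outside the "
                f"{height}x{width} canvas"
            )
        channels.append(make_heatmap(point, spec, height, width))
    values = np.stack(channels, axis=-1)
    return TargetStack(values=values, landmark_order=tuple(landmark_order))
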