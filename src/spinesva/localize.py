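"""Subpixel landmark localization from predicted heatmap channels.

Because each landmark lives on its own channel, localization never has to
separate peaks: the channel is simply fitted, in a window around its argmax,
with the same function family the network was trained to reproduce (Gaussian
or exponential), and the fitted center is the landmark estimate.  The
Gaussian fit is a smooth nonlinear least-squares problem; the exponential's
L1 offset makes the residual non-differentiable at the peak, so that family
is fitted with a derivative-free simplex search on the squared-error
objective.  An integer argmax serves as fallback whenever fitting fails or
wanders out of the window.

Localization operates on the raw predicted heatmap; the probability-map
normalization here is for interpretation and visualization only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .heatmaps import LandmarkPoint, alpha_from_sigma

__all__ = [
    "DegenerateMapError",
    "LocalizationResult",
    "argmax_localize",
    "fit_localize",
    "normalize_to_probability",
]


class DegenerateMapError(ValueError):
    """Raised when a heatmap carries no positive signal to localize."""


@dataclass(frozen=True)
class LocalizationResult:
    point: LandmarkPoint
    method: Literal["fit", "argmax"]
    fit_quality: float = float("nan")


def normalize_to_probability(heatmap: np.ndarray) -> np.ndarray:
    """Clip negatives to zero and normalize to a unit-sum probability map."""
    hm = np.asarray(heatmap, dtype=float)
    clipped = np.clip(hm, 0.0, None)
    total = clipped.sum()
    if not total > 0:
        raise DegenerateMapError("heatmap has no positive values after clipping")
    return clipped / total


def argmax_localize(heatmap: np.ndarray) -> LocalizationResult:
    """Integer-pixel peak location; ties resolve to the smallest row-major index."""
    hm = np.asarray(heatmap)
    if hm.size == 0:
        raise ValueError("empty heatmap")
    flat = int(np.argmax(hm))
    row, col = divmod(flat, hm.shape[1])
    return LocalizationResult(
        point=LandmarkPoint(x=float(col), y=float(row)), method="argmax"
    )


def _gaussian_model(params: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    cx, cy, amp, sigma = params
    return amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sigma**2))


def _exponential_model(params: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    cx, cy, amp, sigma = params
    alpha = alpha_from_sigma(abs(sigma))
    return amp * np.exp(-alpha * (np.abs(xs - cx) + np.abs(ys - cy)))


def fit_localize(
    heatmap: np.ndarray,
    family: Literal["gaussian", "exponential"],
    sigma_init: float = 1.57,
) -> LocalizationResult:
    """Fit the target-family function around the peak; return the fitted center.

    Free parameters: center (x, y), amplitude, and width.  The fit window is
    a square of half-width ``max(7, ceil(4 * sigma_init))`` centered on the
    argmax.  If the optimizer fails or the fitted center leaves the window,
    the argmax location is returned with ``method='argmax'``.
    """
    hm = np.asarray(heatmap, dtype=float)
    if hm.ndim != 2 or hm.size == 0:
        raise ValueError(f"heatmap must be a non-empty 2-D array, got shape {hm.shape}")
    peak_val = hm.max()
    if not peak_val > 0:
        raise DegenerateMapError("heatmap has no positive values; cannot fit")
    fallback = argmax_localize(hm)
    px, py = fallback.point.x, fallback.point.y

    half = max(7, math.ceil(4.0 * sigma_init))
    h, w = hm.shape
    x0, x1 = int(max(0, px - half)), int(min(w, px + half + 1))
    y0, y1 = int(max(0, py - half)), int(min(h, py + half + 1))
    window = hm[y0:y1, x0:x1]
    ys, xs = np.mgrid[y0:y1, x0:x1].astype(float)

    p0 = np.array([px, py, peak_val, sigma_init], dtype=float)
    try:
        if family == "gaussian":
            res = optimize.least_squares(
                lambda p: (_gaussian_model(p, xs, ys) - window).ravel(),
                p0,
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
            )
            popt, cost = res.x, math.sqrt(2.0 * res.cost)
            ok = res.success or res.status > 0
        elif family == "exponential":
            # Non-smooth at the peak: derivative-free simplex on the SSE.
            def sse(p):
                return float(np.sum((_exponential_model(p, xs, ys) - window) ** 2))

            res = optimize.minimize(
                sse,
                p0,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000, "maxfev": 6000},
            )
            popt, cost = res.x, math.sqrt(max(res.fun, 0.0))
            ok = bool(res.success) or res.fun <= sse(p0)
        else:
            raise ValueError(f"unknown family {family!r}")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "family" in str(exc):
            raise
        return fallback

    cx, cy = float(popt[0]), float(popt[1])
    inside_window = (x0 - 0.5 <= cx <= x1 - 0.5) and (y0 - 0.5 <= cy <= y1 - 0.5)
    if not (ok and inside_window and math.isfinite(cx) and math.isfinite(cy)):
        return fallback
    cx = min(max(cx, 0.0), w - 1.0)
    cy = min(max(cy, 0.0), h - 1.0)
    return LocalizationResult(
        point=LandmarkPoint(x=cx, y=cy), method="fit", fit_quality=cost
    )
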