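"""Classical depixelation baseline.

Per-core intensities are extracted from the honeycomb frame, divided by the
reference-derived transmissivity (with a floor to bound noise amplification
at dark cores), and interpolated from the scattered core centers onto a
regular grid — by default barycentric (piecewise-linear) interpolation over
the Delaunay triangulation, which is exact for affine intensity fields.
"""

from __future__ import annotations

from typing import NamedTuple
import warnings

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    LinearNDInterpolator,
    NearestNDInterpolator,
)
from scipy.spatial import QhullError

from .geometry import FiberLayout, TransmissivityMap
from .reference import disk_means
from .simulate import MCFImage

__all__ = [
    "extract_core_values",
    "correct_transmissivity",
    "interpolate_depixelate",
    "classical_reconstruct",
    "CorrectedValues",
]

GAIN_FLOOR = 0.05  # default divisor floor for transmissivity correction


def _pixels(image: np.ndarray | MCFImage) -> np.ndarray:
    return image.pixels if isinstance(image, MCFImage) else np.asarray(image, dtype=float)


def extract_core_values(
    mcf_image: np.ndarray | MCFImage,
    layout: FiberLayout,
    aperture_radius_px: float | None = None,
) -> np.ndarray:
    """Mean intensity in a disk aperture around each core center."""
    if aperture_radius_px is None:
        aperture_radius_px = max(1.0, layout.core_radius)
    values, _ = disk_means(_pixels(mcf_image), layout.core_centers, aperture_radius_px)
    return np.clip(values, 0.0, 1.0)


class CorrectedValues(NamedTuple):
    values: np.ndarray
    low_gain: np.ndarray  # cores whose gain fell below the floor (divided by the floor)


def correct_transmissivity(
    core_values: np.ndarray,
    tmap: TransmissivityMap,
    floor: float = GAIN_FLOOR,
) -> CorrectedValues:
    """Divide each core value by max(gain, floor); clip to [0, 1]."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    core_values = np.asarray(core_values, dtype=float).ravel()
    if core_values.size != tmap.n_cores:
        raise ValueError("core value / gain length mismatch")
    denom = np.maximum(tmap.gains, floor)
    return CorrectedValues(
        values=np.clip(core_values / denom, 0.0, 1.0),
        low_gain=tmap.gains < floor,
    )


def interpolate_depixelate(
    core_values: np.ndarray,
    layout: FiberLayout,
    out_shape: tuple[int, int] | None = None,
    method: str = "linear",
) -> np.ndarray:
    """Scattered-data interpolation of core values onto a regular grid.

    ``method``: "linear" (barycentric over the Delaunay triangulation,
    default), "cubic" (Clough-Tocher C1), or "nearest".  Outside the convex
    hull of the cores the nearest-core value is used.  Fewer than 3
    non-collinear cores fall back to nearest-core with a warning.
    """
    core_values = np.asarray(core_values, dtype=float).ravel()
    if core_values.size != layout.n_cores:
        raise ValueError("core value length does not match layout")
    if out_shape is None:
        out_shape = layout.canvas_shape
    pts = layout.core_centers.copy()
    # map core coordinates into the output grid when it differs from the canvas
    if tuple(out_shape) != tuple(layout.canvas_shape):
        sr = (out_shape[0] - 1) / max(1, layout.canvas_shape[0] - 1)
        sc = (out_shape[1] - 1) / max(1, layout.canvas_shape[1] - 1)
        pts = pts * np.array([sr, sc])

    grid_r, grid_c = np.mgrid[0:out_shape[0], 0:out_shape[1]]
    nearest = NearestNDInterpolator(pts, core_values)

    if method == "nearest" or core_values.size < 3:
        if core_values.size < 3 and method != "nearest":
            warnings.warn("fewer than 3 cores: falling back to nearest-core interpolation")
        out = nearest(grid_r, grid_c)
        return np.clip(out, 0.0, 1.0)

    interp_cls = {"linear": LinearNDInterpolator, "cubic": CloughTocher2DInterpolator}
    if method not in interp_cls:
        raise ValueError(f"unknown interpolation method {method!r}")
    try:
        interp = interp_cls[method](pts, core_values)
        out = interp(grid_r, grid_c)
    except QhullError:
        warnings.warn("degenerate (collinear) layout: falling back to nearest-core")
        out = nearest(grid_r, grid_c)
        return np.clip(out, 0.0, 1.0)
    hole = ~np.isfinite(out)
    if hole.any():
        out[hole] = nearest(grid_r[hole], grid_c[hole])
    return np.clip(out, 0.0, 1.0)


def classical_reconstruct(
    mcf_image: np.ndarray | MCFImage,
    layout: FiberLayout,
    tmap: TransmissivityMap | None = None,
    out_shape: tuple[int, int] | None = None,
    method: str = "linear",
    floor: float = GAIN_FLOOR,
    aperture_radius_px: float | None = None,
) -> np.ndarray:
    """extract -> (optional transmissivity correction) -> interpolate."""
    values = extract_core_values(mcf_image, layout, aperture_radius_px)
    if tmap is not None:
        values = correct_transmissivity(values, tmap, floor=floor).values
    return interpolate_depixelate(values, layout, out_shape=out_shape, method=method)
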