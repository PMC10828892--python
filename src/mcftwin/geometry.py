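"""Fiber-bundle geometry: core layouts and per-core transmissivity.

A multi-core fiber (MCF) is modelled as a disk-shaped bundle of independent
light-guiding cores.  The layout stores floating-point core centers in pixel
units (row, col; origin at the top-left pixel center), the nominal pitch
(center-to-center spacing) and the core radius.  Manufacturing disorder is
emulated by isotropic Gaussian jitter on a hexagonal lattice; inhomogeneous
transmission by a clipped-normal per-core gain vector.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FiberLayout",
    "TransmissivityMap",
    "GeometryError",
    "EmptyLayoutError",
    "generate_fiber_layout",
    "sample_transmissivity",
    "hex_lattice_points",
]

DEFAULT_CORE_RADIUS_FRACTION = 0.35  # core_radius = 0.35 * pitch keeps visible cladding gaps


class GeometryError(ValueError):
    """Bundle geometry incompatible with the canvas."""


class EmptyLayoutError(ValueError):
    """No valid core survives the requested geometry."""


@dataclasses.dataclass
class FiberLayout:
    """Core arrangement of one MCF instance.

    Parameters
    ----------
    core_centers : (n, 2) float array of (row, col) positions in pixels.
    core_radius : core radius in pixels (> 0).
    pitch : nominal core-to-core spacing in pixels.
    bundle_center : (row, col) of the bundle disk center in pixels.
    bundle_radius : radius of the disk containing all core centers.
    canvas_shape : (rows, cols) of the image canvas holding the bundle.
    """

    core_centers: np.ndarray
    core_radius: float
    pitch: float
    bundle_center: tuple[float, float]
    bundle_radius: float
    canvas_shape: tuple[int, int]
    layout_id: str = "layout"

    def __post_init__(self) -> None:
        self.core_centers = np.asarray(self.core_centers, dtype=float).reshape(-1, 2)

    @property
    def n_cores(self) -> int:
        return int(self.core_centers.shape[0])

    def validate(self) -> None:
        """Assert the layout invariants; raise GeometryError on violation."""
        if self.n_cores < 1:
            raise EmptyLayoutError("layout contains no cores")
        if not (self.core_radius > 0):
            raise GeometryError("core_radius must be positive")
        d = np.linalg.norm(self.core_centers - np.asarray(self.bundle_center), axis=1)
        if np.any(d > self.bundle_radius + 1e-9):
            raise GeometryError("a core center lies outside the bundle disk")
        cy, cx = self.bundle_center
        rows, cols = self.canvas_shape
        if (cy - self.bundle_radius < -1e-9 or cx - self.bundle_radius < -1e-9
                or cy + self.bundle_radius > rows - 1 + 1e-9
                or cx + self.bundle_radius > cols - 1 + 1e-9):
            raise GeometryError("bundle disk does not fit inside the canvas")
        if self.n_cores > 1:
            tree = cKDTree(self.core_centers)
            dmin, _ = tree.query(self.core_centers, k=2)
            if np.min(dmin[:, 1]) < 2 * self.core_radius - 1e-9:
                raise GeometryError("cores overlap: min pairwise distance < 2 * core_radius")

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path, gains: np.ndarray | None = None) -> None:
        """Persist as ``<stem>.csv`` (core_id,row,col,gain) + ``<stem>.json`` header."""
        path = Path(path)
        stem = path.with_suffix("")
        g = np.ones(self.n_cores) if gains is None else np.asarray(gains, dtype=float)
        if g.shape[0] != self.n_cores:
            raise ValueError("gain vector length does not match core count")
        with open(stem.with_suffix(".csv"), "w") as fh:
            fh.write("core_id,row,col,gain\n")
            for i, ((r, c), gi) in enumerate(zip(self.core_centers, g)):
                fh.write(f"{i},{float(r)!r},{float(c)!r},{float(gi)!r}\n")
        header = {
            "layout_id": self.layout_id,
            "core_radius": self.core_radius,
            "pitch": self.pitch,
            "bundle_center": list(self.bundle_center),
            "bundle_radius": self.bundle_radius,
            "canvas_shape": list(self.canvas_shape),
        }
        stem.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["FiberLayout", np.ndarray]:
        """Load a layout saved by :meth:`save`; returns ``(layout, gains)``."""
        stem = Path(path).with_suffix("")
        header = json.loads(stem.with_suffix(".json").read_text())
        rows = []
        gains = []
        with open(stem.with_suffix(".csv")) as fh:
            next(fh)
            for line in fh:
                _, r, c, g = line.strip().split(",")
                rows.append((float(r), float(c)))
                gains.append(float(g))
        layout = cls(
            core_centers=np.asarray(rows, dtype=float),
            core_radius=float(header["core_radius"]),
            pitch=float(header["pitch"]),
            bundle_center=tuple(header["bundle_center"]),
            bundle_radius=float(header["bundle_radius"]),
            canvas_shape=tuple(int(v) for v in header["canvas_shape"]),
            layout_id=str(header.get("layout_id", "layout")),
        )
        return layout, np.asarray(gains, dtype=float)


@dataclasses.dataclass
class TransmissivityMap:
    """Per-core intensity gains in [0, 1] plus a homogeneity flag."""

    gains: np.ndarray
    mode: str  # "homogeneous" | "inhomogeneous"

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float).ravel()
        if self.mode not in ("homogeneous", "inhomogeneous"):
            raise ValueError(f"unknown transmissivity mode {self.mode!r}")
        if self.gains.size < 1:
            raise ValueError("empty gain vector")
        if np.any(~np.isfinite(self.gains)) or np.any(self.gains < 0) or np.any(self.gains > 1):
            raise ValueError("gains must be finite and within [0, 1]")
        if self.mode == "homogeneous" and not np.allclose(self.gains, self.gains[0]):
            raise ValueError("homogeneous mode requires identical gains")

    @property
    def n_cores(self) -> int:
        return int(self.gains.size)


def hex_lattice_points(
    center: tuple[float, float], pitch: float, radius: float
) -> np.ndarray:
    """Points of a hexagonal lattice (one vertex at ``center``) inside a disk.

    Rows are spaced ``pitch * sqrt(3)/2`` apart; odd rows are offset by half a
    pitch.  Points with distance <= radius (inclusive) are returned in
    deterministic (row, col) order.
    """
    row_step = pitch * np.sqrt(3.0) / 2.0
    n_rows = int(np.floor(radius / row_step))
    n_cols = int(np.floor(radius / pitch)) + 1
    pts = []
    cy, cx = center
    for i in range(-n_rows, n_rows + 1):
        off = 0.5 * pitch if (i % 2) else 0.0
        for j in range(-n_cols - 1, n_cols + 2):
            r = cy + i * row_step
            c = cx + j * pitch + off
            if (r - cy) ** 2 + (c - cx) ** 2 <= radius**2 + 1e-9:
                pts.append((r, c))
    out = np.asarray(pts, dtype=float)
    if out.size:
        out = out[np.lexsort((out[:, 1], out[:, 0]))]
    return out.reshape(-1, 2)


def generate_fiber_layout(
    canvas_shape: tuple[int, int],
    pitch_px: float,
    jitter_std_px: float = 0.0,
    bundle_radius_px: float | None = None,
    seed: int = 0,
    core_radius_px: float | None = None,
    bundle_center: tuple[float, float] | None = None,
) -> FiberLayout:
    """Generate a jittered hexagonal core layout clipped to the bundle disk.

    Each lattice point inside the disk is perturbed by isotropic zero-mean
    Gaussian jitter of the given standard deviation (per coordinate).  Cores
    pushed outside the disk, and cores violating the non-overlap invariant
    (pairwise distance < 2 * core_radius), are removed deterministically.
    """
    rows, cols = canvas_shape
    if bundle_radius_px is None:
        bundle_radius_px = 0.45 * min(rows, cols)
    if core_radius_px is None:
        core_radius_px = DEFAULT_CORE_RADIUS_FRACTION * pitch_px
    if jitter_std_px < 0:
        raise ValueError("jitter_std_px must be >= 0")
    if pitch_px <= 2 * core_radius_px - 1e-12:
        raise GeometryError("pitch must exceed twice the core radius")
    if bundle_center is None:
        bundle_center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    cy, cx = bundle_center
    if (cy - bundle_radius_px < 0 or cx - bundle_radius_px < 0
            or cy + bundle_radius_px > rows - 1 or cx + bundle_radius_px > cols - 1):
        raise GeometryError(
            f"bundle (center {bundle_center}, radius {bundle_radius_px}) exceeds canvas {canvas_shape}"
        )

    pts = hex_lattice_points(bundle_center, pitch_px, bundle_radius_px)
    if pts.shape[0] == 0:
        raise EmptyLayoutError("no lattice point falls inside the bundle disk")

    rng = np.random.default_rng(seed)
    if jitter_std_px > 0:
        pts = pts + rng.normal(0.0, jitter_std_px, size=pts.shape)
        inside = np.linalg.norm(pts - np.asarray(bundle_center), axis=1) <= bundle_radius_px
        pts = pts[inside]

    # enforce non-overlap: greedy keep in (row, col) order
    if pts.shape[0] > 1:
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]
        tree = cKDTree(pts)
        conflict = tree.query_pairs(2 * core_radius_px - 1e-12, output_type="ndarray")
        removed = np.zeros(pts.shape[0], dtype=bool)
        if conflict.size:
            # pairs are index pairs (i < j in sorted order): drop the later core
            for i, j in conflict[np.lexsort((conflict[:, 1], conflict[:, 0]))]:
                if not removed[i] and not removed[j]:
                    removed[max(i, j)] = True
        pts = pts[~removed]

    if pts.shape[0] == 0:
        raise EmptyLayoutError("no core survives jitter/overlap removal")

    layout = FiberLayout(
        core_centers=pts,
        core_radius=float(core_radius_px),
        pitch=float(pitch_px),
        bundle_center=tuple(map(float, bundle_center)),
        bundle_radius=float(bundle_radius_px),
        canvas_shape=(int(rows), int(cols)),
        layout_id=f"hex-p{pitch_px:g}-j{jitter_std_px:g}-s{seed}",
    )
    layout.validate()
    return layout


def sample_transmissivity(
    layout: FiberLayout,
    mean: float = 0.8,
    std: float = 0.15,
    clip_low: float = 0.0,
    seed: int = 0,
) -> TransmissivityMap:
    """Draw per-core gains from a normal distribution clipped to [clip_low, 1].

    ``std = 0`` yields a homogeneous map with all gains equal to ``mean``.
    """
    if not (0 < mean <= 1):
        raise ValueError("mean must be in (0, 1]")
    if std < 0:
        raise ValueError("std must be >= 0")
    if not (0 <= clip_low < mean):
        raise ValueError("clip_low must satisfy 0 <= clip_low < mean")
    n = layout.n_cores
    if std == 0:
        return TransmissivityMap(gains=np.full(n, mean), mode="homogeneous")
    rng = np.random.default_rng(seed)
    gains = np.clip(rng.normal(mean, std, size=n), clip_low, 1.0)
    return TransmissivityMap(gains=gains, mode="inhomogeneous")
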