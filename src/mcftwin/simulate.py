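"""Forward model of the digital twin: scene -> honeycomb-pixelated MCF frame.

Each core integrates the scene over a Gaussian sampling aperture centered on
the core, the per-core transmissivity scales that value, and the frame is
re-rendered as a sum of Gaussian core spots.  The composition reproduces the
honeycomb artifact that limits the raw resolution to the core pitch.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from skimage.transform import resize

from .geometry import FiberLayout, TransmissivityMap
from .reference import render_spots

__all__ = [
    "MCFImage",
    "SimulateConfig",
    "sample_core_values",
    "apply_transmissivity",
    "render_mcf_image",
    "simulate",
]


@dataclasses.dataclass
class MCFImage:
    """A honeycomb endoscopic frame plus provenance metadata."""

    pixels: np.ndarray
    provenance: str  # "simulated" | "measured"
    layout_id: str = ""
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.provenance not in ("simulated", "measured"):
            raise ValueError("provenance must be 'simulated' or 'measured'")


@dataclasses.dataclass
class SimulateConfig:
    """Knobs of the forward model.

    sampling_sigma_px : Gaussian aperture each core uses to average the
        scene; default 1.0 x core radius (a collection aperture comparable
        to the core size, which enforces the pitch-limited resolution of
        the honeycomb image).
    spot_sigma_px : rendering spot width; default 0.4 x core radius
        (identical kernel to the reference rendering).
    noise_sigma : optional additive Gaussian camera noise after rendering.
    """

    sampling_sigma_px: float | None = None
    spot_sigma_px: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    clip: bool = True

    def resolved(self, layout: FiberLayout) -> "SimulateConfig":
        return dataclasses.replace(
            self,
            sampling_sigma_px=self.sampling_sigma_px or 1.0 * layout.core_radius,
            spot_sigma_px=self.spot_sigma_px or 0.4 * layout.core_radius,
        )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _to_canvas(scene: np.ndarray, canvas_shape: tuple[int, int]) -> np.ndarray:
    scene = np.asarray(scene, dtype=float)
    if scene.shape != tuple(canvas_shape):
        scene = resize(scene, canvas_shape, order=1, anti_aliasing=False,
                       preserve_range=True, mode="edge")
    return scene


def sample_core_values(
    scene: np.ndarray,
    layout: FiberLayout,
    sampling_sigma_px: float | None = None,
) -> np.ndarray:
    """Gaussian-weighted average of the scene at each core center.

    Weights are normalized to sum 1 over the sampling window, so a uniform
    scene maps to that uniform value exactly and a linear ramp maps to the
    ramp evaluated at the core center (up to window truncation).
    """
    if sampling_sigma_px is None:
        sampling_sigma_px = 1.0 * layout.core_radius
    if sampling_sigma_px <= 0:
        raise ValueError("sampling sigma must be positive")
    scene = _to_canvas(scene, layout.canvas_shape)
    rows, cols = scene.shape
    half = int(np.ceil(4 * sampling_sigma_px))
    inv2s2 = 1.0 / (2.0 * sampling_sigma_px**2)
    values = np.empty(layout.n_cores)
    for k, (r, c) in enumerate(layout.core_centers):
        r0, r1 = max(0, int(np.floor(r)) - half), min(rows, int(np.ceil(r)) + half + 1)
        c0, c1 = max(0, int(np.floor(c)) - half), min(cols, int(np.ceil(c)) + half + 1)
        rr = np.arange(r0, r1, dtype=float)[:, None] - r
        cc = np.arange(c0, c1, dtype=float)[None, :] - c
        w = np.exp(-(rr * rr + cc * cc) * inv2s2)
        values[k] = float((w * scene[r0:r1, c0:c1]).sum() / w.sum())
    return values


def apply_transmissivity(core_values: np.ndarray, tmap: TransmissivityMap) -> np.ndarray:
    """Elementwise product of core values and per-core gains."""
    core_values = np.asarray(core_values, dtype=float).ravel()
    if core_values.size != tmap.n_cores:
        raise ValueError(
            f"core value length {core_values.size} != gain length {tmap.n_cores}"
        )
    return core_values * tmap.gains


def render_mcf_image(
    core_values: np.ndarray,
    layout: FiberLayout,
    spot_sigma_px: float | None = None,
    clip: bool = True,
    mask_bundle: bool = True,
) -> MCFImage:
    """Render core values as Gaussian spots; zero outside the bundle disk."""
    if spot_sigma_px is None:
        spot_sigma_px = 0.4 * layout.core_radius
    img = render_spots(layout.core_centers, core_values, layout.canvas_shape,
                       spot_sigma_px, clip=clip)
    if mask_bundle:
        rr = np.arange(layout.canvas_shape[0], dtype=float)[:, None] - layout.bundle_center[0]
        cc = np.arange(layout.canvas_shape[1], dtype=float)[None, :] - layout.bundle_center[1]
        img = np.where(rr * rr + cc * cc <= layout.bundle_radius**2, img, 0.0)
    return MCFImage(pixels=img, provenance="simulated", layout_id=layout.layout_id)


def simulate(
    scene: np.ndarray,
    layout: FiberLayout,
    tmap: TransmissivityMap,
    config: SimulateConfig | None = None,
) -> MCFImage:
    """Full forward pass: sample -> apply transmissivity -> render (+ noise)."""
    cfg = (config or SimulateConfig()).resolved(layout)
    values = sample_core_values(scene, layout, cfg.sampling_sigma_px)
    values = apply_transmissivity(values, tmap)
    mcf = render_mcf_image(values, layout, cfg.spot_sigma_px, clip=cfg.clip)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        noisy = mcf.pixels + rng.normal(0.0, cfg.noise_sigma, size=mcf.pixels.shape)
        mcf.pixels = np.clip(noisy, 0.0, 1.0) if cfg.clip else noisy
    mcf.meta = {
        "layout_id": layout.layout_id,
        "tmap_mode": tmap.mode,
        "seed": cfg.seed,
        "config_hash": cfg.hash(),
    }
    return mcf
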