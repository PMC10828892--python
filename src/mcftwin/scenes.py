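"""Procedural ground-truth scenes and paired-dataset construction.

Band-limited random textures stand in for a natural-image pre-training
corpus; soft elliptical blob scenes emulate a distinct tissue-like family for
transfer-learning experiments; binary three-bar targets probe resolution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import FiberLayout, TransmissivityMap, sample_transmissivity
from .imageio import write_image
from .metrics import BarSpec
from .reference import render_reference
from .simulate import SimulateConfig, simulate

__all__ = [
    "generate_texture_scene",
    "generate_bar_target",
    "generate_blob_scene",
    "build_dataset",
    "PairedDataset",
    "make_scene",
]

# autocorrelation of Gaussian-filtered white noise is Gaussian with std sigma*sqrt(2);
# its half-width at half-maximum is sigma*sqrt(2)*sqrt(2 ln 2)
_HWHM_FACTOR = np.sqrt(2.0) * np.sqrt(2.0 * np.log(2.0))


def generate_texture_scene(size: int, correlation_length_px: float = 6.0,
                           seed: int = 0) -> np.ndarray:
    """Band-limited random field rescaled to [0, 1].

    ``correlation_length_px`` is the half-width at half-maximum of the
    field's autocorrelation.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if correlation_length_px <= 0:
        raise ValueError("correlation length must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    sigma = correlation_length_px / _HWHM_FACTOR
    field = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    lo, hi = field.min(), field.max()
    return (field - lo) / (hi - lo)


def generate_bar_target(
    size: int,
    periods_px_list: list[int],
    orientation: str = "vertical",
    margin: int = 4,
    origin: tuple[int, int] | None = None,
    background: float = 0.0,
) -> tuple[np.ndarray, list[BarSpec]]:
    """USAF-style binary three-bar groups, one group per listed period.

    Each group holds 3 bright bars of width period/2 separated by period/2
    gaps; bar length is 2.5 periods.  Groups are stacked along the bar axis
    with a margin.  ``origin`` places the first group at a given (row, col)
    instead of the margin corner (e.g. to center it in a fiber bundle).
    ``background`` fills the surround (mid-gray isolates bar modulation from
    the group's own envelope when measuring contrast after blurring).
    Returns the image (binary when background is 0) and the BarSpec list.
    """
    img = np.full((size, size), float(background))
    specs: list[BarSpec] = []
    cursor = margin
    o_r, o_c = origin if origin is not None else (None, None)
    for period in periods_px_list:
        if period < 2:
            raise ValueError("bar period must be >= 2 px")
        w = period // 2
        group_extent = 3 * w + 2 * (period - w)  # three bars + two gaps
        length = int(round(2.5 * period))
        if orientation == "vertical":
            r0, r1 = (o_r, o_r + length) if o_r is not None else (cursor, cursor + length)
            c0 = o_c if o_c is not None else margin
            if r1 > size - margin or c0 + group_extent > size - margin:
                raise ValueError(f"period {period} group does not fit canvas {size}")
            img[r0:r1, c0:c0 + group_extent] = 0.0
            centers = []
            c = c0
            for _ in range(3):
                img[r0:r1, c:c + w] = 1.0
                centers.append(c + (w - 1) / 2.0)
                c += period
            specs.append(BarSpec(period_px=float(period), orientation="vertical",
                                 row_range=(r0, r1), col_range=(c0, c0 + group_extent),
                                 bar_centers=tuple(centers)))
            cursor = r1 + margin
        elif orientation == "horizontal":
            c0, c1 = (o_c, o_c + length) if o_c is not None else (cursor, cursor + length)
            r0 = o_r if o_r is not None else margin
            if c1 > size - margin or r0 + group_extent > size - margin:
                raise ValueError(f"period {period} group does not fit canvas {size}")
            img[r0:r0 + group_extent, c0:c1] = 0.0
            centers = []
            r = r0
            for _ in range(3):
                img[r:r + w, c0:c1] = 1.0
                centers.append(r + (w - 1) / 2.0)
                r += period
            specs.append(BarSpec(period_px=float(period), orientation="horizontal",
                                 row_range=(r0, r0 + group_extent), col_range=(c0, c1),
                                 bar_centers=tuple(centers)))
            cursor = c1 + margin
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
    return img, specs


def generate_blob_scene(
    size: int,
    n_blobs: int = 6,
    radius_range: tuple[float, float] = (5.0, 12.0),
    seed: int = 0,
    background: float = 0.08,
) -> np.ndarray:
    """Soft-edged elliptical blobs on a dim background, values in [0, 1]."""
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    img = np.full((size, size), background)
    rr = np.arange(size, dtype=float)[:, None]
    cc = np.arange(size, dtype=float)[None, :]
    for _ in range(n_blobs):
        r0 = rng.uniform(0.2 * size, 0.8 * size)
        c0 = rng.uniform(0.2 * size, 0.8 * size)
        a = rng.uniform(*radius_range)
        b = a * rng.uniform(0.5, 1.0)
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(0.6, 1.0)
        dr, dc = rr - r0, cc - c0
        u = dr * np.cos(theta) + dc * np.sin(theta)
        v = -dr * np.sin(theta) + dc * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        img += amp * np.exp(-(q**2))  # flat top, soft edge
    return np.clip(img, 0.0, 1.0)


def make_scene(family: str, size: int, seed: int) -> np.ndarray:
    """Dispatch a scene family by name ('texture' | 'blobs')."""
    if family == "texture":
        return generate_texture_scene(size, correlation_length_px=max(3.0, size / 16), seed=seed)
    if family == "blobs":
        return generate_blob_scene(size, n_blobs=5, seed=seed)
    raise ValueError(f"unknown scene family {family!r}")


# ---------------------------------------------------------------- datasets

TMAP_POLICIES = ("fixed-homogeneous", "fixed-inhomogeneous", "redraw-per-sample")


@dataclasses.dataclass
class PairedDataset:
    """Manifest-backed collection of (scene, MCF image, reference) triples."""

    manifest_path: Path
    manifest: dict

    @classmethod
    def load(cls, manifest_path: str | Path) -> "PairedDataset":
        p = Path(manifest_path)
        return cls(manifest_path=p, manifest=json.loads(p.read_text()))

    def entries(self, split: str | None = None) -> list[dict]:
        es = self.manifest["entries"]
        return [e for e in es if split is None or e["split"] == split]

    def to_arrays(self, split: str) -> dict:
        """Load a split into arrays: scenes (targets), mcf inputs, references.

        Under the redraw-per-sample policy each entry carries its own
        reference (matching its drawn transmissivity); fixed policies share
        the dataset-level reference.
        """
        from .imageio import read_image

        root = self.manifest_path.parent
        ref = read_image(root / self.manifest["reference"])
        scenes, mcfs, refs = [], [], []
        for e in self.entries(split):
            scenes.append(read_image(root / e["scene"]))
            mcfs.append(read_image(root / e["mcf"]))
            refs.append(read_image(root / e["reference"]) if "reference" in e else ref)
        return {"scenes": np.asarray(scenes), "mcf": np.asarray(mcfs),
                "reference": ref, "references": np.asarray(refs)}


def _tmap_for_sample(policy: str, layout: FiberLayout, base_seed: int,
                     sample_index: int, mean: float, std: float) -> tuple[TransmissivityMap, int]:
    if policy == "fixed-homogeneous":
        seed = base_seed
        tmap = sample_transmissivity(layout, mean=mean, std=0.0, seed=seed)
    elif policy == "fixed-inhomogeneous":
        seed = base_seed
        tmap = sample_transmissivity(layout, mean=mean, std=std, seed=seed)
    elif policy == "redraw-per-sample":
        seed = (base_seed * 1000003 + sample_index + 1) % (2**31)
        tmap = sample_transmissivity(layout, mean=mean, std=std, seed=seed)
    else:
        raise ValueError(f"unknown tmap policy {policy!r}; one of {TMAP_POLICIES}")
    return tmap, seed


def build_dataset(
    out_dir: str | Path,
    layout: FiberLayout,
    tmap_policy: str = "redraw-per-sample",
    n_train: int = 5000,
    n_val: int = 100,
    n_test: int = 400,
    scene_family: str = "texture",
    seed: int = 0,
    scene_scale: int = 2,
    tmap_mean: float = 0.8,
    tmap_std: float = 0.15,
    sim_config: SimulateConfig | None = None,
) -> PairedDataset:
    """Simulate a paired (scene, MCF) dataset and write it with a manifest.

    Scenes are generated at ``scene_scale`` x the layout canvas (the
    reconstruction target resolution) and down-sampled inside the simulator.
    The split sizes default to the 5000/100/400 pre-training design; desk
    runs pass smaller counts.  The reference frame uses the brightest-core
    normalization convention and its SHA-256 is recorded for provenance.
    """
    out = Path(out_dir)
    (out / "scenes").mkdir(parents=True, exist_ok=True)
    (out / "mcf").mkdir(parents=True, exist_ok=True)
    scene_size = layout.canvas_shape[0] * scene_scale

    ref_tmap = sample_transmissivity(layout, mean=tmap_mean, std=tmap_std, seed=seed)
    reference = render_reference(layout, ref_tmap)
    write_image(out / "reference.tiff", reference)
    ref_sha = hashlib.sha256((out / "reference.tiff").read_bytes()).hexdigest()
    layout.save(out / "layout.csv", gains=ref_tmap.gains)

    entries = []
    idx = 0
    try:
        for si, (split, count) in enumerate((("train", n_train), ("val", n_val),
                                             ("test", n_test))):
            for j in range(count):
                # per-split seeding so e.g. a test-only dataset with the same
                # root seed reproduces the same test scenes
                scene_seed = (seed * 7919 + si * 1000003 + j) % (2**31)
                scene = make_scene(scene_family, scene_size, scene_seed)
                tmap, tseed = _tmap_for_sample(tmap_policy, layout, seed, idx,
                                               tmap_mean, tmap_std)
                cfg = sim_config or SimulateConfig()
                mcf = simulate(scene, layout, tmap, cfg)
                spath = f"scenes/{split}_{idx:05d}.tiff"
                mpath = f"mcf/{split}_{idx:05d}.tiff"
                write_image(out / spath, scene)
                write_image(out / mpath, mcf.pixels)
                entry = {
                    "id": idx, "split": split, "scene": spath, "mcf": mpath,
                    "tmap_seed": tseed,
                    "tmap_hash": hashlib.sha256(tmap.gains.tobytes()).hexdigest()[:16],
                }
                if tmap_policy == "redraw-per-sample":
                    # the reference channel must show the drawn transmissivity
                    rpath = f"refs/{split}_{idx:05d}.tiff"
                    (out / "refs").mkdir(exist_ok=True)
                    write_image(out / rpath, render_reference(layout, tmap))
                    entry["reference"] = rpath
                entries.append(entry)
                idx += 1
    except OSError:
        for e in entries:  # partial-output cleanup
            (out / e["scene"]).unlink(missing_ok=True)
            (out / e["mcf"]).unlink(missing_ok=True)
        raise

    manifest = {
        "layout": "layout.csv",
        "layout_id": layout.layout_id,
        "reference": "reference.tiff",
        "reference_sha256": ref_sha,
        "tmap_policy": tmap_policy,
        "scene_family": scene_family,
        "seed": seed,
        "scene_scale": scene_scale,
        "splits": {"train": n_train, "val": n_val, "test": n_test},
        "entries": entries,
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return PairedDataset(manifest_path=mpath, manifest=manifest)
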