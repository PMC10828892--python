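"""Learned reconstruction: depixelation U-Net cascaded with a residual
super-resolution stage, optionally conditioned on the fiber reference image.

The cascade maps a honeycomb MCF frame (plus, when enabled, the reference
frame as a second input channel) to a depixelated image at input resolution
(stage 1) and then to an upscaled restoration bounded to [0, 1] (stage 2).
Pre-training runs on simulated pairs from the digital twin; transfer
learning continues optimization on a small measured-style dataset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .metrics import psnr, ssim
from .nn import (F32, Adam, AvgPool2, BoundedLinear01, Conv3x3, LeakyReLU,
                 UpsampleNearest2)

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "TrainedModel",
    "ArrayDataset",
    "Cascade",
    "build_cascade",
    "train",
    "fine_tune",
    "reconstruct",
]


@dataclasses.dataclass
class NetworkConfig:
    """Architecture of the reconstruction cascade.

    in_channels : 1 (MCF frame only) or 2 (MCF frame + reference).
    base_width : feature width of the first encoder level.
    depth : number of U-Net resolution levels (1 = no downsampling, 2 = one
        2x down/up pair).
    n_res_blocks : residual blocks in the super-resolution stage.
    upscale : integer output magnification, a power of 2 (1, 2, 4, ...).
    """

    in_channels: int = 1
    base_width: int = 4
    depth: int = 2
    n_res_blocks: int = 2
    upscale: int = 2
    use_reference_channel: bool = False

    def __post_init__(self) -> None:
        if self.use_reference_channel != (self.in_channels == 2):
            raise ValueError("use_reference_channel requires in_channels == 2 (and vice versa)")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        u = self.upscale
        if u < 1 or (u & (u - 1)) != 0:
            raise ValueError("upscale must be a power of 2 (>= 1)")
        if self.depth not in (1, 2):
            raise ValueError("depth must be 1 or 2")
        if self.base_width < 1 or self.n_res_blocks < 0:
            raise ValueError("invalid width / residual-block count")


@dataclasses.dataclass
class TrainConfig:
    loss: str = "l1"
    lr: float = 2e-3
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    checkpoint_every: int = 1
    fine_tune: bool = False
    lr_schedule: str = "cosine"  # "cosine" | "constant"

    def __post_init__(self) -> None:
        if self.lr < 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("hyperparameters must be positive (epochs >= 0)")
        if self.loss not in ("l1", "l2"):
            raise ValueError("loss must be 'l1' or 'l2'")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


class _UNet:
    """Small encoder/decoder with one optional 2x down/up pair and skip concat."""

    def __init__(self, in_ch: int, width: int, depth: int, rng: np.random.Generator):
        w = width
        self.depth = depth
        self.enc1a, self.enc1b = Conv3x3(in_ch, w, rng), Conv3x3(w, w, rng)
        if depth == 2:
            self.pool = AvgPool2()
            self.mid_a, self.mid_b = Conv3x3(w, 2 * w, rng), Conv3x3(2 * w, 2 * w, rng)
            self.up = UpsampleNearest2()
            self.up_conv = Conv3x3(2 * w, w, rng)
            self.dec_a = Conv3x3(2 * w, w, rng)  # after skip concat
        self.out_conv = Conv3x3(w, 1, rng, scale=0.1)
        self._relus = [LeakyReLU() for _ in range(6)]

    def layers(self):
        ls = [self.enc1a, self.enc1b, self.out_conv]
        if self.depth == 2:
            ls += [self.mid_a, self.mid_b, self.up_conv, self.dec_a]
        return ls

    def params(self):
        return [pg for l in self.layers() for pg in l.params()]

    def forward(self, x, train=True):
        r = self._relus
        e = r[0].forward(self.enc1a.forward(x, train), train)
        e = r[1].forward(self.enc1b.forward(e, train), train)
        if self.depth == 1:
            return self.out_conv.forward(e, train)
        self._e = e if train else None
        m = self.pool.forward(e, train)
        m = r[2].forward(self.mid_a.forward(m, train), train)
        m = r[3].forward(self.mid_b.forward(m, train), train)
        u = self.up.forward(m, train)
        u = r[4].forward(self.up_conv.forward(u, train), train)
        cat = np.concatenate([u, e], axis=1)
        d = r[5].forward(self.dec_a.forward(cat, train), train)
        return self.out_conv.forward(d, train)

    def backward(self, gy):
        r = self._relus
        g = self.out_conv.backward(gy)
        if self.depth == 1:
            g = self.enc1b.backward(r[1].backward(g))
            return self.enc1a.backward(r[0].backward(g))
        g = self.dec_a.backward(r[5].backward(g))
        w = self.up_conv.out_ch
        gu, ge_skip = g[:, :w], g[:, w:]
        g = self.up_conv.backward(r[4].backward(gu))
        g = self.up.backward(g)
        g = self.mid_b.backward(r[3].backward(g))
        g = self.mid_a.backward(r[2].backward(g))
        g = self.pool.backward(g)
        g = g + ge_skip
        g = self.enc1b.backward(r[1].backward(g))
        return self.enc1a.backward(r[0].backward(g))


class _ResBlock:
    def __init__(self, width: int, rng: np.random.Generator):
        self.c1, self.c2 = Conv3x3(width, width, rng), Conv3x3(width, width, rng, scale=0.1)
        self.relu = LeakyReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x, train=True):
        y = self.relu.forward(self.c1.forward(x, train), train)
        return x + self.c2.forward(y, train)

    def backward(self, gy):
        g = self.c2.backward(gy)
        g = self.c1.backward(self.relu.backward(g))
        return g + gy


class _PixelShuffle:
    """(B, r^2, H, W) -> (B, 1, rH, rW) sub-pixel rearrangement."""

    def __init__(self, r: int):
        self.r = r

    def forward(self, x, train=True):
        b, c, h, w = x.shape
        r = self.r
        y = x.reshape(b, r, r, h, w).transpose(0, 3, 1, 4, 2)
        return np.ascontiguousarray(y.reshape(b, 1, h * r, w * r))

    def backward(self, gy):
        b, _, hr, wr = gy.shape
        r = self.r
        h, w = hr // r, wr // r
        g = gy.reshape(b, h, r, w, r).transpose(0, 2, 4, 1, 3)
        return np.ascontiguousarray(g.reshape(b, r * r, h, w))


class _SRStage:
    """Residual super-resolution with a sub-pixel convolution tail.

    All convolutions run at base resolution; the tail conv emits upscale^2
    channels that a pixel shuffle rearranges into the magnified frame.
    """

    def __init__(self, width: int, n_blocks: int, upscale: int, rng: np.random.Generator):
        self.head = Conv3x3(1, width, rng)
        self.blocks = [_ResBlock(width, rng) for _ in range(n_blocks)]
        self.body_out = Conv3x3(width, width, rng, scale=0.1)
        self.upscale = upscale
        self.tail = Conv3x3(width, upscale * upscale, rng, scale=0.1)
        self.tail.b[...] = 0.5  # start at mid-gray so the [0,1] bound is not saturated
        self.shuffle = _PixelShuffle(upscale) if upscale > 1 else None
        self.out_act = BoundedLinear01()

    def params(self):
        ps = self.head.params() + self.body_out.params() + self.tail.params()
        for b in self.blocks:
            ps += b.params()
        return ps

    def forward(self, x, train=True):
        f = self.head.forward(x, train)
        y = f
        for b in self.blocks:
            y = b.forward(y, train)
        y = f + self.body_out.forward(y, train)
        y = self.tail.forward(y, train)
        if self.shuffle is not None:
            y = self.shuffle.forward(y, train)
        return self.out_act.forward(y, train)

    def backward(self, gy):
        g = self.out_act.backward(gy)
        if self.shuffle is not None:
            g = self.shuffle.backward(g)
        g = self.tail.backward(g)
        g_skip = g
        g = self.body_out.backward(g)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.head.backward(g + g_skip)


class Cascade:
    """Stage-1 depixelation network feeding a stage-2 super-resolution network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.unet = _UNet(config.in_channels, config.base_width, config.depth, rng)
        self.sr = _SRStage(config.base_width, config.n_res_blocks, config.upscale, rng)

    def params(self):
        return self.unet.params() + self.sr.params()

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=F32)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected input (B, {self.config.in_channels}, H, W), got {x.shape}"
            )
        return self.sr.forward(self.unet.forward(x, train), train)

    def backward(self, gy: np.ndarray) -> None:
        self.unet.backward(self.sr.backward(gy))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match architecture")
        for (p, _), w in zip(own, weights):
            p[...] = w


def build_cascade(config: NetworkConfig, seed: int = 0) -> Cascade:
    """Construct an untrained cascade with seed-deterministic initialization."""
    return Cascade(config, seed=seed)


@dataclasses.dataclass
class ArrayDataset:
    """In-memory aligned training data.

    ``*_x``: (N, C, H, W) network inputs (MCF frame [+ reference channel]);
    ``*_y``: (N, 1, H*u, W*u) target scenes.
    """

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    @staticmethod
    def stack_inputs(mcf: np.ndarray, reference: np.ndarray | None) -> np.ndarray:
        """(N, H, W) frames [+ one shared (H, W) reference] -> (N, C, H, W)."""
        mcf = np.asarray(mcf, dtype=F32)
        if mcf.ndim == 2:
            mcf = mcf[None]
        x = mcf[:, None]
        if reference is not None:
            ref = np.broadcast_to(np.asarray(reference, dtype=F32), mcf.shape)[:, None]
            x = np.concatenate([x, ref], axis=1)
        return np.ascontiguousarray(x, dtype=F32)

    @classmethod
    def from_paired(cls, dataset, use_reference: bool, val_split: str = "val") -> "ArrayDataset":
        tr = dataset.to_arrays("train")
        va = dataset.to_arrays(val_split)
        return cls(
            train_x=cls.stack_inputs(tr["mcf"], tr["references"] if use_reference else None),
            train_y=np.asarray(tr["scenes"], dtype=F32)[:, None],
            val_x=cls.stack_inputs(va["mcf"], va["references"] if use_reference else None),
            val_y=np.asarray(va["scenes"], dtype=F32)[:, None],
            meta={"manifest": str(dataset.manifest_path)},
        )

    def hash(self) -> str:
        h = hashlib.sha256()
        for a in (self.train_x, self.train_y, self.val_x, self.val_y):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]


@dataclasses.dataclass
class TrainedModel:
    """Serialized cascade weights plus the configs and history that made them."""

    weights: list
    net_config: NetworkConfig
    train_config: TrainConfig
    history: dict
    dataset_hash: str = ""
    no_improvement: bool = False

    def to_model(self) -> Cascade:
        model = Cascade(self.net_config, seed=0)
        model.set_weights([np.asarray(w, dtype=F32) for w in self.weights])
        return model

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        meta = {
            "net_config": dataclasses.asdict(self.net_config),
            "train_config": dataclasses.asdict(self.train_config),
            "history": self.history,
            "dataset_hash": self.dataset_hash,
            "no_improvement": self.no_improvement,
        }
        with open(path, "wb") as fh:  # keep the exact filename (no implicit .npz)
            np.savez(fh, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
        return cls(
            weights=weights,
            net_config=NetworkConfig(**meta["net_config"]),
            train_config=TrainConfig(**meta["train_config"]),
            history=meta["history"],
            dataset_hash=meta["dataset_hash"],
            no_improvement=meta.get("no_improvement", False),
        )


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    diff = pred - target
    n = diff.size
    if kind == "l1":
        return float(np.abs(diff).mean()), np.sign(diff).astype(F32) / n
    return float((diff * diff).mean()), (2.0 * diff / n).astype(F32)


def _validate(model: Cascade, val_x, val_y, batch: int = 8) -> tuple[float, float]:
    ps, ss = [], []
    for i in range(0, len(val_x), batch):
        out = model.forward(val_x[i:i + batch], train=False)
        for o, t in zip(out, val_y[i:i + batch]):
            p = psnr(o[0], t[0])
            ps.append(min(p, 100.0))
            ss.append(ssim(o[0].astype(float), t[0].astype(float)))
    return float(np.mean(ps)), float(np.mean(ss))


def train(model: Cascade, dataset: ArrayDataset, train_config: TrainConfig) -> TrainedModel:
    """Optimize the cascade on aligned pairs; keep the best-validation weights.

    Deterministic for a fixed seed (shuffling and initialization both flow
    from explicit generators).  Raises on empty data, shape mismatch or a
    non-finite loss.
    """
    cfg = train_config
    x, y = dataset.train_x, dataset.train_y
    if len(x) == 0:
        raise ValueError("empty training set")
    if x.shape[0] != y.shape[0]:
        raise ValueError("input/target count mismatch")
    u = model.config.upscale
    if y.shape[2] != x.shape[2] * u or y.shape[3] != x.shape[3] * u:
        raise ValueError(
            f"target shape {y.shape[2:]} incompatible with input {x.shape[2:]} x upscale {u}"
        )
    history: dict = {"train_loss": [], "val_psnr": [], "val_ssim": []}
    if cfg.epochs == 0:
        return TrainedModel(model.get_weights(), model.config, cfg, history,
                            dataset_hash=dataset.hash())

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)
    best_psnr, best_weights = -np.inf, model.get_weights()
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
        idx = rng.permutation(len(x))
        losses = []
        for i in range(0, len(idx), cfg.batch_size):
            sel = idx[i:i + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward(x[sel], train=True)
            loss, grad = _loss_and_grad(pred, y[sel], cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        vp, vs = _validate(model, dataset.val_x, dataset.val_y)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_psnr"].append(vp)
        history["val_ssim"].append(vs)
        if vp > best_psnr and (epoch + 1) % cfg.checkpoint_every == 0 or epoch == cfg.epochs - 1:
            if vp > best_psnr:
                best_psnr, best_weights = vp, model.get_weights()
    model.set_weights(best_weights)
    return TrainedModel(best_weights, model.config, cfg, history,
                        dataset_hash=dataset.hash())


def fine_tune(trained_model: TrainedModel, small_dataset: ArrayDataset,
              train_config: TrainConfig) -> TrainedModel:
    """Transfer learning: continue optimization from pre-trained weights.

    The validation metric on the small domain is compared before and after;
    if fine-tuning did not improve it, the result carries a
    ``no_improvement`` flag (the better weights are still the checkpointed
    best-validation ones).
    """
    cfg = dataclasses.replace(train_config, fine_tune=True)
    model = trained_model.to_model()
    pre_psnr, _ = _validate(model, small_dataset.val_x, small_dataset.val_y)
    result = train(model, small_dataset, cfg)
    post = result.history["val_psnr"]
    post_psnr = max(post) if post else pre_psnr
    result.no_improvement = bool(post_psnr < pre_psnr)
    if result.no_improvement:  # keep the stronger starting weights
        result = dataclasses.replace(result, weights=trained_model.weights)
    result.history["pre_finetune_val_psnr"] = pre_psnr
    return result


def reconstruct(trained_model: TrainedModel, mcf_image: np.ndarray,
                reference: np.ndarray | None = None,
                return_info: bool = False):
    """Single forward pass: MCF frame (+ reference iff configured) -> ReconImage."""
    cfg = trained_model.net_config
    mcf = np.asarray(mcf_image, dtype=F32)
    if cfg.use_reference_channel and reference is None:
        raise ValueError("this model requires a reference image")
    if not cfg.use_reference_channel and reference is not None:
        raise ValueError("this model does not take a reference image")
    if reference is not None and np.asarray(reference).shape != mcf.shape:
        raise ValueError("reference shape must match the MCF frame")
    x = ArrayDataset.stack_inputs(mcf[None], reference)
    model = trained_model.to_model()
    t0 = time.perf_counter()
    out = model.forward(x, train=False)[0, 0].astype(float)
    dt = time.perf_counter() - t0
    if return_info:
        return out, {"seconds_per_frame": dt, "fps": (1.0 / dt if dt > 0 else float("inf"))}
    return out
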