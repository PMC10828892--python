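"""Desk-scale replicas of the two headline experiments.

``hallucination_experiment`` quantifies the failure mode where a
reconstruction network trained on a homogeneous-transmissivity fiber
hallucinates structure when the real fiber is inhomogeneous, and how a
reference-conditioned network trained with per-sample re-drawn
transmissivity maps recovers.  ``transfer_experiment`` pre-trains on the
texture family and fine-tunes on a small blob-scene set, measuring the
benefit of transfer learning on limited data.

Both run on a single CPU in minutes; problem sizes are the package's
desk-scale defaults (64 x 64 frames, ~150-core layout, 200/20/40 splits).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .geometry import generate_fiber_layout
from .metrics import psnr
from .network import (ArrayDataset, NetworkConfig, TrainConfig, TrainedModel,
                      build_cascade, fine_tune, reconstruct, train)
from .scenes import PairedDataset, build_dataset

__all__ = ["hallucination_experiment", "transfer_experiment", "desk_layout"]


def desk_layout(seed: int = 0, canvas: int = 64, pitch_px: float = 4.5,
                jitter_frac: float = 0.1):
    """~150-core jittered hexagonal layout on a 64 x 64 canvas."""
    return generate_fiber_layout(
        (canvas, canvas), pitch_px, jitter_std_px=jitter_frac * pitch_px,
        bundle_radius_px=0.45 * canvas, seed=seed,
    )


def _test_psnrs(trained: TrainedModel, dataset: PairedDataset, split: str = "test"):
    arrs = dataset.to_arrays(split)
    use_ref = trained.net_config.use_reference_channel
    vals = []
    for mcf, scene, ref in zip(arrs["mcf"], arrs["scenes"], arrs["references"]):
        out = reconstruct(trained, mcf, ref if use_ref else None)
        vals.append(min(psnr(out, scene), 100.0))
    return float(np.mean(vals))


def hallucination_experiment(
    work_dir: str | Path,
    seed: int = 0,
    n_train: int = 200,
    n_val: int = 20,
    n_test: int = 40,
    epochs: int = 12,
    base_width: int = 4,
    lr: float = 3e-3,
) -> dict:
    """Train no-reference (homogeneous data) and reference-conditioned
    (redraw-per-sample data) cascades; test both under the fiber's true
    inhomogeneous transmissivity.

    Returns mean test PSNRs:
    ``noref_hom`` (matched conditions), ``noref_inhom`` (hallucination
    regime) and ``ref_inhom`` (reference-based correction).
    """
    work = Path(work_dir)
    layout = desk_layout(seed)

    ds_hom = build_dataset(work / "hom", layout, "fixed-homogeneous",
                           n_train, n_val, n_test, "texture", seed=seed)
    ds_redraw = build_dataset(work / "redraw", layout, "redraw-per-sample",
                              n_train, n_val, n_test, "texture", seed=seed)
    # same scenes as ds_hom (same seed/counts), but the fiber's true gains
    ds_inhom = build_dataset(work / "inhom", layout, "fixed-inhomogeneous",
                             n_train=0, n_val=0, n_test=n_test,
                             scene_family="texture", seed=seed)

    tc = TrainConfig(lr=lr, epochs=epochs, batch_size=8, seed=seed)
    noref = train(
        build_cascade(NetworkConfig(in_channels=1, base_width=base_width), seed=seed),
        ArrayDataset.from_paired(ds_hom, use_reference=False), tc)
    refnet = train(
        build_cascade(NetworkConfig(in_channels=2, use_reference_channel=True,
                                    base_width=base_width), seed=seed),
        ArrayDataset.from_paired(ds_redraw, use_reference=True), tc)

    return {
        "noref_hom": _test_psnrs(noref, ds_hom),
        "noref_inhom": _test_psnrs(noref, ds_inhom),
        "ref_inhom": _test_psnrs(refnet, ds_inhom),
        "n_cores": layout.n_cores,
        "seed": seed,
    }


def transfer_experiment(
    work_dir: str | Path,
    seed: int = 0,
    n_pretrain: int = 200,
    n_finetune_pairs: int = 50,
    n_test: int = 40,
    pretrain_epochs: int = 12,
    finetune_epochs: int = 20,
    base_width: int = 4,
) -> dict:
    """Pre-train on textures, fine-tune on 50 blob-scene pairs, test on
    held-out blob scenes; returns mean test PSNR before and after transfer."""
    work = Path(work_dir)
    layout = desk_layout(seed)

    ds_tex = build_dataset(work / "tex", layout, "fixed-inhomogeneous",
                           n_pretrain, 20, 0, "texture", seed=seed)
    ds_blob = build_dataset(work / "blob", layout, "fixed-inhomogeneous",
                            n_finetune_pairs, 10, n_test, "blobs", seed=seed + 1)

    pre = train(
        build_cascade(NetworkConfig(in_channels=2, use_reference_channel=True,
                                    base_width=base_width), seed=seed),
        ArrayDataset.from_paired(ds_tex, use_reference=True),
        TrainConfig(lr=3e-3, epochs=pretrain_epochs, batch_size=8, seed=seed))
    tuned = fine_tune(
        pre, ArrayDataset.from_paired(ds_blob, use_reference=True),
        TrainConfig(lr=1e-3, epochs=finetune_epochs, batch_size=8, seed=seed))

    return {
        "pretrained_blob_psnr": _test_psnrs(pre, ds_blob),
        "finetuned_blob_psnr": _test_psnrs(tuned, ds_blob),
        "no_improvement_flag": tuned.no_improvement,
        "seed": seed,
    }
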