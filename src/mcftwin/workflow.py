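"""JSON-configured workflow runner with provenance and deterministic seeding.

A run config names the stages to execute (generate, simulate, pretrain,
finetune, evaluate) with their parameters; all randomness fans out from one
root seed.  Each run writes a directory with the config copy, a plain-text
log, a JSON event stream, metrics CSVs and a machine-readable report of
stage statuses and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from pathlib import Path

import numpy as np

from .classical import classical_reconstruct
from .geometry import generate_fiber_layout, sample_transmissivity
from .imageio import write_image
from .metrics import evaluate_set
from .network import (ArrayDataset, NetworkConfig, TrainConfig, TrainedModel,
                      build_cascade, fine_tune, train)
from .reference import render_reference
from .scenes import PairedDataset, build_dataset

__all__ = ["run_workflow", "validate_config", "ConfigError", "SCHEMA"]

STAGE_ORDER = ("generate", "simulate", "pretrain", "finetune", "evaluate")

# minimal declarative schema: stage -> {field: (type, required)}
SCHEMA: dict = {
    "seed": (int, True),
    "out_dir": (str, True),
    "stages": {
        "generate": {
            "canvas": (int, False), "pitch_px": (float, False),
            "jitter_std_px": (float, False), "bundle_radius_px": (float, False),
        },
        "simulate": {
            "tmap_policy": (str, False), "n_train": (int, False),
            "n_val": (int, False), "n_test": (int, False),
            "scene_family": (str, False),
        },
        "pretrain": {
            "use_reference": (bool, False), "base_width": (int, False),
            "epochs": (int, False), "lr": (float, False),
            "batch_size": (int, False), "upscale": (int, False),
        },
        "finetune": {
            "n_pairs": (int, False), "epochs": (int, False), "lr": (float, False),
            "scene_family": (str, False),
        },
        "evaluate": {"split": (str, False)},
    },
}


class ConfigError(ValueError):
    """Configuration does not validate against the schema."""


def validate_config(config: dict) -> None:
    for key, spec in SCHEMA.items():
        if key == "stages":
            continue
        typ, required = spec
        if required and key not in config:
            raise ConfigError(f"missing required field '{key}'")
        if key in config and not isinstance(config[key], typ):
            raise ConfigError(f"field '{key}': expected {typ.__name__}, got {type(config[key]).__name__}")
    stages = config.get("stages")
    if not isinstance(stages, dict) or not stages:
        raise ConfigError("field 'stages': must be a non-empty object")
    for name, params in stages.items():
        if name not in SCHEMA["stages"]:
            raise ConfigError(f"stages.{name}: unknown stage (one of {list(SCHEMA['stages'])})")
        if not isinstance(params, dict):
            raise ConfigError(f"stages.{name}: must be an object")
        for field, value in params.items():
            if field not in SCHEMA["stages"][name]:
                raise ConfigError(f"stages.{name}.{field}: unknown field")
            typ = SCHEMA["stages"][name][field][0]
            ok = isinstance(value, typ) or (typ is float and isinstance(value, int))
            if not ok:
                raise ConfigError(
                    f"stages.{name}.{field}: expected {typ.__name__}, got {type(value).__name__}"
                )


def _stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_workflow(config_path: str | Path | dict) -> dict:
    """Execute the configured stages in canonical order; return the run report."""
    if isinstance(config_path, dict):
        config = config_path
    else:
        config = json.loads(Path(config_path).read_text())
    validate_config(config)

    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True))
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    log_lines: list[str] = []
    events: list[dict] = []

    def log(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}"
        log_lines.append(line)
        events.append({"t": time.time(), "msg": msg})

    root_seed = int(config["seed"])
    report: dict = {"config_hash": config_hash, "stages": {}, "outputs": {}}
    state: dict = {}
    failed = False

    for stage in STAGE_ORDER:
        if stage not in config["stages"]:
            continue
        if failed:
            report["stages"][stage] = {"status": "skipped"}
            continue
        params = config["stages"][stage]
        seed = _stage_seed(root_seed, stage)
        log(f"stage {stage} start (seed {seed})")
        try:
            _run_stage(stage, params, seed, out, state, report)
            report["stages"][stage] = {"status": "completed", "seed": seed}
            log(f"stage {stage} done")
        except Exception as exc:  # noqa: BLE001 — report and skip downstream
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            log(f"stage {stage} FAILED: {exc}")
            log(traceback.format_exc())
            failed = True

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    (out / "events.jsonl").write_text("\n".join(json.dumps(e) for e in events) + "\n")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _run_stage(stage: str, params: dict, seed: int, out: Path,
               state: dict, report: dict) -> None:
    if stage == "generate":
        canvas = params.get("canvas", 64)
        layout = generate_fiber_layout(
            (canvas, canvas),
            pitch_px=params.get("pitch_px", 5.0),
            jitter_std_px=params.get("jitter_std_px", 0.5),
            bundle_radius_px=params.get("bundle_radius_px", 0.45 * canvas),
            seed=seed,
        )
        tmap = sample_transmissivity(layout, seed=seed)
        layout.save(out / "layout.csv", gains=tmap.gains)
        ref = render_reference(layout, tmap)
        write_image(out / "reference.tiff", ref)
        state.update(layout=layout, tmap=tmap, reference=ref)
        report["outputs"]["layout"] = _sha(out / "layout.csv")
        report["outputs"]["reference"] = _sha(out / "reference.tiff")

    elif stage == "simulate":
        layout = state["layout"]
        ds = build_dataset(
            out / "data",
            layout,
            tmap_policy=params.get("tmap_policy", "redraw-per-sample"),
            n_train=params.get("n_train", 40),
            n_val=params.get("n_val", 8),
            n_test=params.get("n_test", 8),
            scene_family=params.get("scene_family", "texture"),
            seed=seed,
        )
        state["dataset"] = ds
        report["outputs"]["manifest"] = _sha(ds.manifest_path)

    elif stage == "pretrain":
        ds = state["dataset"]
        use_ref = params.get("use_reference", True)
        net = NetworkConfig(
            in_channels=2 if use_ref else 1,
            use_reference_channel=use_ref,
            base_width=params.get("base_width", 4),
            upscale=params.get("upscale", 2),
        )
        tc = TrainConfig(lr=params.get("lr", 2e-3), epochs=params.get("epochs", 3),
                         batch_size=params.get("batch_size", 8), seed=seed)
        data = ArrayDataset.from_paired(ds, use_reference=use_ref)
        model = build_cascade(net, seed=seed)
        trained = train(model, data, tc)
        trained.save(out / "model.npz")
        state["trained"] = trained
        _history_csv(trained, out / "pretrain_metrics.csv")
        report["outputs"]["model"] = _sha(out / "model.npz")

    elif stage == "finetune":
        trained = state["trained"]
        layout = state["layout"]
        ds = build_dataset(
            out / "data_ft", layout, tmap_policy="fixed-inhomogeneous",
            n_train=params.get("n_pairs", 50), n_val=8, n_test=8,
            scene_family=params.get("scene_family", "blobs"), seed=seed + 1,
        )
        use_ref = trained.net_config.use_reference_channel
        data = ArrayDataset.from_paired(ds, use_reference=use_ref)
        tc = TrainConfig(lr=params.get("lr", 5e-4), epochs=params.get("epochs", 3),
                         batch_size=8, seed=seed, fine_tune=True)
        tuned = fine_tune(trained, data, tc)
        tuned.save(out / "model_ft.npz")
        state["trained_ft"] = tuned
        state["dataset_ft"] = ds
        _history_csv(tuned, out / "finetune_metrics.csv")
        report["outputs"]["model_ft"] = _sha(out / "model_ft.npz")

    elif stage == "evaluate":
        from .network import reconstruct as net_reconstruct

        split = params.get("split", "test")
        trained = state.get("trained_ft") or state["trained"]
        ds = state.get("dataset_ft") or state["dataset"]
        arrs = ds.to_arrays(split)
        use_ref = trained.net_config.use_reference_channel
        pairs = [
            {"id": i,
             "input_image": net_reconstruct(trained, m, r if use_ref else None),
             "target_image": s}
            for i, (m, s, r) in enumerate(
                zip(arrs["mcf"], arrs["scenes"], arrs["references"]))
        ]
        table = evaluate_set(
            pairs,
            out_csv=out / "evaluate_metrics.csv",
            plot_path=out / "evaluate_hist.png",
            method_name="network",
        )
        report["outputs"]["evaluate_metrics"] = _sha(out / "evaluate_metrics.csv")
        report["outputs"]["mean_test_psnr_db"] = float(
            table[table.image_id == "mean"].psnr_db.iloc[0])
    else:  # pragma: no cover
        raise ConfigError(f"unknown stage {stage}")


def _history_csv(trained: TrainedModel, path: Path) -> None:
    import pandas as pd

    h = trained.history
    n = len(h.get("train_loss", []))
    pd.DataFrame({
        "epoch": np.arange(1, n + 1),
        "train_loss": h.get("train_loss", []),
        "val_psnr": h.get("val_psnr", []),
        "val_ssim": h.get("val_ssim", []),
    }).to_csv(path, index=False)
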