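"""End-to-end experiment orchestration.

simulate -> tile -> train -> select -> predict -> evaluate -> class metrics
-> report, for every (architecture, tile size) cell of the configured sweep.
Every stage is a thin call into the library modules; artifacts land under a
run directory and are listed in ``run_manifest.json``.  All randomness
derives from the single global seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .augment import AugmentParams
from .evaluation import ConfusionMatrix, confusion_matrix, summary_metrics
from .inference import DEFAULT_FRACTIONS, predict_scene
from .landscape import class_landscape_metrics, f1_metric_regression
from .models import ModelConfig, build_model
from .scenes import (LabeledScene, SceneSpec, generate_scene, perturb_scene,
                     save_scene, three_class_spec, savanna_spec,
                     empirical_class_proportions)
from .tiling import spatial_split, tile_scene, save_tiles
from .training import TrainConfig, select_best_epoch, train
from .weights import DEFAULT_WEIGHT_EXPONENTS, compute_class_weights

__all__ = ["PipelineConfig", "run_experiment", "temporal_transfer_eval",
           "desk_config", "load_run"]

_PRESET_SPECS = {"three_class": three_class_spec, "savanna": savanna_spec}


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    scene_preset: str = "three_class"
    scene_sizes: dict = field(default_factory=lambda: {
        "train": [(256, 256), (256, 256), (256, 256)],
        "validation": [(128, 128)], "test": [(128, 128)]})
    tile_sizes: tuple = (64,)
    architectures: tuple = ("unet",)
    depth: int = 2
    base_width: int = 8
    max_epochs: int = 30
    patience: int = 40
    learning_rate: float = 1e-2
    weight_exponent: float | None = None   # None -> per-architecture default
    batch_size: int | None = 2
    augment: bool = False
    smoothing_span: float = 0.3
    offset_fractions: tuple = DEFAULT_FRACTIONS
    exclude_background_from_mean: bool = False

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("tile_sizes", "architectures", "offset_fractions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "scene_sizes" in raw:
            raw["scene_sizes"] = {k: [tuple(s) for s in v]
                                  for k, v in raw["scene_sizes"].items()}
        return cls(**raw)

    def to_yaml(self, path):
        data = asdict(self)
        data["tile_sizes"] = list(self.tile_sizes)
        data["architectures"] = list(self.architectures)
        data["offset_fractions"] = list(self.offset_fractions)
        data["scene_sizes"] = {k: [list(s) for s in v]
                               for k, v in self.scene_sizes.items()}
        Path(path).write_text(yaml.safe_dump(data))


def desk_config(out_dir, seed: int = 0, **overrides) -> PipelineConfig:
    """The shipped desk-scale preset: 3 separable classes, one small U-Net."""
    return PipelineConfig(out_dir=str(out_dir), seed=seed, **overrides)


def _derived_seed(seed: int, *salts) -> int:
    """Stable sub-seed derivation (process-independent, < 2^31)."""
    h = np.uint64(seed)
    for s in salts:
        h = (h * np.uint64(1000003) + np.uint64(zlib.crc32(repr(s).encode()))) % np.uint64(2 ** 31)
    return int(h)


def _simulate_scenes(config: PipelineConfig):
    make_spec = _PRESET_SPECS[config.scene_preset]
    scenes, scheme = {}, {}
    for role, sizes in config.scene_sizes.items():
        scheme[role] = []
        for i, (h, w) in enumerate(sizes):
            sid = f"{role}_{i}"
            spec = make_spec(h, w)
            scene = generate_scene(spec, seed=_derived_seed(config.seed, role, i))
            scene.scene_id = sid
            scenes[sid] = scene
            scheme[role].append(sid)
    return scenes, scheme


def run_experiment(config: PipelineConfig) -> dict:
    """Run the full sweep; returns a results dict (also saved as JSON)."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    artifacts = [str(run_dir / "config.yaml")]

    stage = "simulate"
    try:
        scenes, scheme = _simulate_scenes(config)
        split = spatial_split(list(scenes), scheme)
        scene_dir = run_dir / "scenes"
        for sid, scene in scenes.items():
            save_scene(scene, scene_dir, sid)
            artifacts += [str(scene_dir / f"{sid}_{k}.png") for k in ("image", "mask")]
            artifacts.append(str(scene_dir / f"{sid}_classes.csv"))

        train_scenes = [scenes[s] for s in split.scenes("train")]
        val_scenes = [scenes[s] for s in split.scenes("validation")]
        test_scenes = [scenes[s] for s in split.scenes("test")]
        class_table = train_scenes[0].class_table
        n_classes = len(class_table)
        big_mask = np.concatenate([s.mask.ravel() for s in train_scenes])
        proportions = empirical_class_proportions(big_mask, class_table)

        results = {"run_dir": str(run_dir), "cells": {}}
        for arch in config.architectures:
            for tile_size in config.tile_sizes:
                stage = f"train[{arch},{tile_size}]"
                cell_dir = run_dir / f"{arch}_t{tile_size}"
                cell_dir.mkdir(exist_ok=True)
                tiles = []
                for scene in train_scenes:
                    tiles.extend(tile_scene(scene, tile_size))
                manifest = save_tiles(tiles, cell_dir / "tiles", role="train")
                artifacts.append(str(manifest))

                x_exp = (config.weight_exponent
                         if config.weight_exponent is not None
                         else DEFAULT_WEIGHT_EXPONENTS[arch])
                weights = compute_class_weights(proportions, x_exp)
                model = build_model(ModelConfig(
                    arch, n_classes=n_classes, depth=config.depth,
                    base_width=config.base_width,
                    seed=_derived_seed(config.seed, arch, tile_size)))
                tcfg = TrainConfig(
                    tile_size=tile_size, batch_size=config.batch_size,
                    max_epochs=config.max_epochs, patience=config.patience,
                    learning_rate=config.learning_rate, weight_exponent=x_exp,
                    seed=_derived_seed(config.seed, arch, tile_size, "train"),
                    augment=AugmentParams() if config.augment else None)
                log = train(model, tiles, val_scenes, weights, tcfg,
                            run_dir=cell_dir / "checkpoints")
                log.save_csv(cell_dir / "training_log.csv")
                artifacts.append(str(cell_dir / "training_log.csv"))

                stage = f"select[{arch},{tile_size}]"
                if len(log.records) >= 3:
                    best_epoch = select_best_epoch(log, config.smoothing_span)
                else:  # too short to smooth: raw argmax, earliest on ties
                    best_epoch = int(log.epochs[int(np.argmax(log.val_mious))])
                ckpt = log.checkpoint_for(best_epoch)
                state = dict(np.load(ckpt)) if isinstance(ckpt, (str, Path)) else ckpt
                model.load_state_dict(state)

                stage = f"predict[{arch},{tile_size}]"
                total_cm = np.zeros((n_classes, n_classes), dtype=np.int64)
                predictions = {}
                for scene in test_scenes:
                    pred = predict_scene(model, scene, tile_size,
                                         fractions=config.offset_fractions)
                    predictions[scene.scene_id] = pred
                    total_cm += confusion_matrix(scene.mask, pred, n_classes).counts
                    out_png = cell_dir / f"pred_{scene.scene_id}.png"
                    iio.imwrite(out_png, pred.astype(np.uint8))
                    artifacts.append(str(out_png))

                stage = f"evaluate[{arch},{tile_size}]"
                report = summary_metrics(
                    ConfusionMatrix(total_cm),
                    exclude_background=config.exclude_background_from_mean)
                report.save(cell_dir / "metrics.json")
                report.save(cell_dir / "metrics.csv")
                artifacts += [str(cell_dir / "metrics.json"), str(cell_dir / "metrics.csv")]

                stage = f"class-metrics[{arch},{tile_size}]"
                train_mask = np.concatenate([s.mask for s in train_scenes], axis=1) \
                    if len({s.mask.shape[0] for s in train_scenes}) == 1 \
                    else train_scenes[0].mask
                lm = class_landscape_metrics(train_mask, class_table,
                                             gsd_cm=train_scenes[0].gsd_cm,
                                             background_id=class_table[0][0])
                lm_lines = ["class_id,name,n_patches,mean_patch_area_ha,"
                            "total_area_ha,mean_compactness"]
                for m in lm:
                    lm_lines.append(f"{m.class_id},{m.name},{m.n_patches},"
                                    f"{m.mean_patch_area_ha},{m.total_class_area_ha},"
                                    f"{m.mean_compactness}")
                (cell_dir / "landscape_metrics.csv").write_text("\n".join(lm_lines) + "\n")
                artifacts.append(str(cell_dir / "landscape_metrics.csv"))

                regressions = {}
                veg = [m for m in lm if not m.is_background and m.n_patches > 0]
                if len(veg) >= 3:
                    f1_by_id = {i: float(report.f1[i]) for i in range(n_classes)}
                    for metric_name in ("mean_patch_area_ha", "total_class_area_ha",
                                        "mean_compactness"):
                        xs = [getattr(m, metric_name) for m in veg]
                        ys = [f1_by_id[m.class_id] for m in veg]
                        try:
                            slope, intercept, p, df = f1_metric_regression(xs, ys)
                            regressions[metric_name] = {
                                "slope": slope, "intercept": intercept,
                                "p_value": p, "df": df}
                        except ValueError as exc:
                            regressions[metric_name] = {"error": str(exc)}

                results["cells"][f"{arch}_t{tile_size}"] = {
                    "architecture": arch, "tile_size": tile_size,
                    "best_epoch": best_epoch,
                    "epochs_trained": int(log.epochs[-1]),
                    "mean_f1": report.mean_f1,
                    "overall_accuracy": report.overall_accuracy,
                    "kappa": report.kappa, "miou": report.miou,
                    "per_class_f1": [float(v) for v in report.f1],
                    "regressions": regressions,
                    "cell_dir": str(cell_dir),
                }
    except Exception as exc:
        (run_dir / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    summary_path = run_dir / "summary.json"
    summary_path.write_text(json.dumps(results["cells"], indent=2))
    artifacts.append(str(summary_path))
    (run_dir / "run_manifest.json").write_text(json.dumps(sorted(artifacts), indent=2))
    results["summary_path"] = str(summary_path)
    results["scenes"] = scenes
    results["split"] = split
    results["models"] = {}  # filled lazily by callers that keep models
    results["last_model"] = model
    results["config"] = config
    return results


def load_run(run_dir) -> dict:
    """Reconstruct a results dict from a completed run directory.

    Loads the stored scenes and the selected checkpoint of the last sweep
    cell, so ``temporal_transfer_eval`` and further evaluation can run
    without retraining.
    """
    from .scenes import load_scene

    run_dir = Path(run_dir)
    config = PipelineConfig.from_yaml(run_dir / "config.yaml")
    cells = json.loads((run_dir / "summary.json").read_text())
    scenes, scheme = {}, {}
    for role, sizes in config.scene_sizes.items():
        scheme[role] = []
        for i in range(len(sizes)):
            sid = f"{role}_{i}"
            scenes[sid] = load_scene(run_dir / "scenes", sid)
            scheme[role].append(sid)
    split = spatial_split(list(scenes), scheme)
    last_key = list(cells)[-1]
    cell = cells[last_key]
    n_classes = len(scenes[scheme["train"][0]].class_table)
    model = build_model(ModelConfig(
        cell["architecture"], n_classes=n_classes, depth=config.depth,
        base_width=config.base_width,
        seed=_derived_seed(config.seed, cell["architecture"], cell["tile_size"])))
    ckpt = Path(cell["cell_dir"]) / "checkpoints" / f"epoch_{cell['best_epoch']:04d}.npz"
    model.load_state_dict(dict(np.load(ckpt)))
    return {"run_dir": str(run_dir), "cells": cells, "scenes": scenes,
            "split": split, "last_model": model, "config": config}


def temporal_transfer_eval(results: dict, strengths) -> list:
    """Evaluate the selected model on perturbed test scenes.

    Returns one row per perturbation strength with the mean F1 of the final
    predictions, emulating re-surveying the same plots in a later season.
    """
    strengths = list(strengths)
    if not strengths:
        raise ValueError("empty perturbation ladder")
    model = results.get("last_model")
    if model is None:
        raise ValueError("results carry no trained model checkpoint")
    config: PipelineConfig = results["config"]
    split = results["split"]
    scenes = results["scenes"]
    test_scenes = [scenes[s] for s in split.scenes("test")]
    n_classes = len(test_scenes[0].class_table)
    tile_size = config.tile_sizes[-1]
    table = []
    for strength in strengths:
        total = np.zeros((n_classes, n_classes), dtype=np.int64)
        for scene in test_scenes:
            shifted = perturb_scene(scene, strength,
                                    seed=_derived_seed(config.seed, "perturb"))
            pred = predict_scene(model, shifted, tile_size,
                                 fractions=config.offset_fractions)
            total += confusion_matrix(scene.mask, pred, n_classes).counts
        report = summary_metrics(ConfusionMatrix(total),
                                 exclude_background=config.exclude_background_from_mean)
        table.append({"strength": float(strength), "mean_f1": report.mean_f1,
                      "overall_accuracy": report.overall_accuracy})
    run_dir = Path(results["run_dir"])
    lines = ["strength,mean_f1,overall_accuracy"]
    lines += [f"{r['strength']},{r['mean_f1']:.6f},{r['overall_accuracy']:.6f}"
              for r in table]
    (run_dir / "temporal_transfer.csv").write_text("\n".join(lines) + "\n")
    return table
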