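"""Configuration, seeding and orchestration of the end-to-end flow:
phantom -> unmix -> segment -> {grade, quantify, stain} -> reports.

A single global seed is fanned out to per-stage seeds (stage-name CRC mixed
into the global seed) so stages are independently reproducible. Every run
writes a manifest (config hash, stage timings, artifact registry, warnings)
sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import grading, io, phantom, quantify, segmodel, vstain
from .preproc import UnmixMatrix, compose_rgb, stitch, tile, unmix
from .quantify import QuantConfig
from .segmodel import SegConfig
from .vstain import VStainConfig

log = logging.getLogger("srshisto")

STAGES = ("phantom", "unmix", "segment", "grade", "quantify", "stain")
_DEPS = {"phantom": (), "unmix": ("phantom",), "segment": ("unmix",),
         "grade": ("segment",), "quantify": ("unmix", "segment"),
         "stain": ("unmix", "segment")}


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifact."""


class ConfigError(ValueError):
    """Configuration failed validation."""


def _pipeline_defaults() -> dict:
    return {
        "seed": 0,
        "out_dir": "srshisto_run",
        "log_level": "INFO",
        "phantom": {"height": 256, "width": 256, "region_smoothness": 16.0,
                    "noise_sd": 4.0, "separable": False},
        "preproc": {"unmix_coeffs": [[1.0, 0.40], [0.55, 1.0]]},
        "segmodel": {"backbone_scale": "toy", "epochs": 10, "lr": 1e-4,
                     "weight_decay": 0.01, "loss_weights": [1.0, 1.0],
                     "train_crop": 64, "resize_edge": 64, "source_patch": 64,
                     "batch": 4, "train_lr": 2e-3},
        "segmetrics": {"tolerance": 6.0},
        "grading": {"threshold_pct": 20.0},
        "quantify": {"tile_size": 64, "px_per_um": 2.8986,
                     "min_component_px": 20, "n_tiles_per_class": 1000},
        "vstain": {"lambda_adv": 1.0, "lambda_cyc": 10.0, "lambda_idt": 0.5,
                   "adam_beta1": 0.5, "adam_beta2": 0.999, "lr": 2e-4,
                   "alpha_floor": 0.3, "image_size": 64,
                   "epochs_pretrain": 2, "epochs_finetune": 2, "batch": 2},
    }


@dataclass
class PipelineConfig:
    raw: dict

    def section(self, name: str) -> dict:
        return self.raw[name]

    @property
    def seed(self) -> int:
        return self.raw["seed"]

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _merge(defaults: dict, override: dict, path=""):
    out = dict(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{path}{key} must be a mapping")
            out[key] = _merge(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def validate_config(source=None) -> PipelineConfig:
    """Schema-check a YAML file / dict and fill defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offender.
    """
    if source is None:
        override = {}
    elif isinstance(source, dict):
        override = source
    else:
        override = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(_pipeline_defaults(), override)
    errors = []
    if not 0 <= cfg["grading"]["threshold_pct"] <= 100:
        errors.append("grading.threshold_pct must lie in [0, 100]")
    if cfg["segmetrics"]["tolerance"] < 0:
        errors.append("segmetrics.tolerance must be nonnegative")
    if cfg["quantify"]["px_per_um"] <= 0:
        errors.append("quantify.px_per_um must be positive")
    for sec, key in (("segmodel", "lr"), ("vstain", "lr")):
        if cfg[sec][key] <= 0:
            errors.append(f"{sec}.{key} must be positive")
    for key in ("lambda_adv", "lambda_cyc", "lambda_idt"):
        if cfg["vstain"][key] < 0:
            errors.append(f"vstain.{key} must be nonnegative")
    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(raw=cfg)


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list
    timings_s: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(asdict(self), indent=2))
        os.replace(tmp, path)


def _predict_slide(state, image, crop):
    """Tile a slide to the inference size, predict, stitch labels and probs."""
    tiles, grid = tile(image, crop)
    lab_tiles, prob_tiles = [], []
    for t in tiles:
        probs, labels = segmodel.predict(state, t)
        lab_tiles.append(labels)
        prob_tiles.append(probs)
    return stitch(prob_tiles, grid), stitch(lab_tiles, grid)


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> RunManifest:
    """Execute the requested stages in dependency order."""
    stages = [s for s in STAGES if s in set(stages)]
    if not stages:
        raise ConfigError("no valid stages requested")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.raw["log_level"])
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed,
                           stages=stages)
    ctx: dict = {}
    matrix = UnmixMatrix(np.array(cfg.section("preproc")["unmix_coeffs"]))

    def _need(stage, key, loader):
        if key in ctx:
            return ctx[key]
        try:
            ctx[key] = loader()
            return ctx[key]
        except FileNotFoundError as e:
            missing = [d for d in _DEPS[stage] if d not in stages]
            raise DependencyError(
                f"stage '{stage}' needs output of upstream stage(s) "
                f"{missing or list(_DEPS[stage])}: {e}") from e

    for stage in stages:
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        if stage == "phantom":
            ph = cfg.section("phantom")
            if ph["separable"]:
                spec = phantom.separable_phantom_spec(
                    ph["height"], ph["width"], seed=seed, noise_sd=ph["noise_sd"],
                    region_smoothness=ph["region_smoothness"])
            else:
                spec = phantom.PhantomSpec(
                    height=ph["height"], width=ph["width"], seed=seed,
                    region_smoothness=ph["region_smoothness"],
                    class_specs=phantom.default_class_specs(ph["noise_sd"]))
            sample = phantom.generate(spec, matrix)
            ctx["sample"] = sample
            io.write_frame(sample.frame, out / "frame.tif")
            io.write_label_png(sample.truth_labels, out / "truth_labels.png")
            io.write_mask_png(sample.truth_nuclei, out / "truth_nuclei.png")
            io.write_maps(sample.truth_maps, out / "truth_maps.tif")
            if sample.n_skipped_nuclei:
                manifest.warnings.append(
                    {"stage": stage, "skipped_nuclei": sample.n_skipped_nuclei})
            manifest.artifacts[stage] = ["frame.tif", "truth_labels.png",
                                         "truth_nuclei.png", "truth_maps.tif"]
        elif stage == "unmix":
            frame = (ctx["sample"].frame if "sample" in ctx else
                     _need(stage, "frame", lambda: io.read_frame(out / "frame.tif")))
            maps = unmix(frame, matrix)
            ctx["maps"] = maps
            io.write_maps(maps, out / "maps.tif")
            io.write_rgb_png(compose_rgb(maps), out / "composite.png")
            manifest.artifacts[stage] = ["maps.tif", "composite.png"]
        elif stage == "segment":
            maps = _need(stage, "maps", lambda: io.read_maps(out / "maps.tif"))
            truth = (ctx["sample"].truth_labels if "sample" in ctx else
                     _need(stage, "truth", lambda: io.read_label_png(out / "truth_labels.png")))
            sc = cfg.section("segmodel")
            seg_cfg = SegConfig(backbone_scale=sc["backbone_scale"],
                                epochs=sc["epochs"], lr=sc["train_lr"],
                                weight_decay=sc["weight_decay"],
                                loss_weights=tuple(sc["loss_weights"]),
                                train_crop=sc["train_crop"],
                                resize_edge=sc["resize_edge"],
                                source_patch=sc["source_patch"],
                                batch=sc["batch"], seed=seed)
            image = quantify.maps_to_image(maps)
            img_tiles, _ = tile(image, seg_cfg.train_crop)
            lab_tiles, _ = tile(truth, seg_cfg.train_crop)
            state = segmodel.train(list(zip(img_tiles, lab_tiles)), seg_cfg)
            probs, labels = _predict_slide(state, image, seg_cfg.train_crop)
            ctx["probs"], ctx["labels"] = probs, labels
            segmodel.save_state(state, out / "seg_model.npz")
            io.write_label_png(labels, out / "pred_labels.png")
            np.savez_compressed(out / "pred_probs.npz", probs=probs.astype(np.float32))
            manifest.artifacts[stage] = ["seg_model.npz", "pred_labels.png",
                                         "pred_probs.npz"]
            manifest.timings_s["segment_val_miou"] = state.val_miou
        elif stage == "grade":
            labels = _need(stage, "labels",
                           lambda: io.read_label_png(out / "pred_labels.png"))
            result = grading.slide_grade(
                labels, cfg.section("grading")["threshold_pct"])
            (out / "grade.json").write_text(json.dumps(result.to_dict(), indent=2))
            manifest.artifacts[stage] = ["grade.json"]
        elif stage == "quantify":
            maps = _need(stage, "maps", lambda: io.read_maps(out / "maps.tif"))
            labels = _need(stage, "labels",
                           lambda: io.read_label_png(out / "pred_labels.png"))
            nuclei = (ctx["sample"].truth_nuclei if "sample" in ctx else
                      _need(stage, "nuclei",
                            lambda: io.read_mask_png(out / "truth_nuclei.png")))
            qc = cfg.section("quantify")
            quant_cfg = QuantConfig(tile_size=qc["tile_size"],
                                    px_per_um=qc["px_per_um"],
                                    min_component_px=qc["min_component_px"],
                                    n_tiles_per_class=qc["n_tiles_per_class"],
                                    seed=seed)
            table = quantify.profile_slide(maps, labels, nuclei, quant_cfg)
            table.to_csv(out / "quant.csv", index=False)
            manifest.warnings.append({"stage": stage,
                                      "nuclei_source": "phantom truth mask"})
            manifest.artifacts[stage] = ["quant.csv"]
        elif stage == "stain":
            maps = _need(stage, "maps", lambda: io.read_maps(out / "maps.tif"))
            probs = (ctx.get("probs") if "probs" in ctx else
                     _need(stage, "probs",
                           lambda: np.load(out / "pred_probs.npz")["probs"].astype(np.float64)))
            sample = ctx.get("sample")
            if sample is None:
                raise DependencyError("stage 'stain' needs the phantom stage "
                                      "in the same run (training domains)")
            vs = cfg.section("vstain")
            v_cfg = VStainConfig(
                lambda_adv=vs["lambda_adv"], lambda_cyc=vs["lambda_cyc"],
                lambda_idt=vs["lambda_idt"], adam_beta1=vs["adam_beta1"],
                adam_beta2=vs["adam_beta2"], lr=vs["lr"],
                alpha_floor=vs["alpha_floor"], image_size=vs["image_size"],
                epochs_pretrain=vs["epochs_pretrain"],
                epochs_finetune=vs["epochs_finetune"], batch=vs["batch"],
                seed=seed)
            rgb = compose_rgb(unmix(sample.frame, matrix)).astype(np.float64) / 255.0
            he = phantom.render_he_like(sample.truth_labels, sample.truth_nuclei,
                                        seed=seed)
            size = v_cfg.image_size
            srs_tiles, _ = tile(rgb, size)
            he_tiles, _ = tile(he, size)
            prob_tiles, _ = tile(probs, size)
            state = vstain.train_two_stage(srs_tiles, he_tiles, srs_tiles,
                                           he_tiles, prob_tiles, v_cfg)
            srvh = vstain.virtual_stain(rgb, probs, state, v_cfg)
            io.write_rgb_png(srvh, out / "srvh.png")
            manifest.artifacts[stage] = ["srvh.png"]
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
    manifest.write(out / "manifest.json")
    return manifest
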