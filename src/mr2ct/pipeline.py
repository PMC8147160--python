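"""Config-driven end-to-end runs with provenance records.

A run executes the stages of the MR-to-pseudo-CT workflow in order —
simulate (or ingest) -> segment -> normalize -> register -> extract-pairs ->
train -> convert -> evaluate — writing every artifact under one output
directory.  Each executed stage appends a provenance record (inputs, the
stage config, the seed, a config hash and output checksums) so any stage
can be re-run in isolation, and a rerun with an identical config reproduces
identical deterministic artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .cnn import ModelSpec, TrainConfig, TrainedModel, predict_volume
from .evaluate import compare_volumes, tissue_stats
from .fcm import FcmConfig, segment_tissues
from .pairs import (DEFAULT_COUNTS, DEFAULT_TRAINING_SLICES,
                    DEFAULT_VALIDATION_SLICES, TemplateLayout,
                    build_all_templates, crop_patches, extract_pairs)
from .registration import MattesConfig, OptimizerSettings, rigid_register, resample
from .shading import BulkIntensities, normalize_mri
from .simulate import BiasSpec, PhantomConfig, make_torso_phantom, save_phantom
from .volume import (TissueLabelMap, Volume, read_labels, read_volume,
                     write_labels, write_volume)

log = logging.getLogger("mr2ct.pipeline")

STAGES = ("simulate", "segment", "normalize", "register", "extract_pairs",
          "train", "convert", "evaluate")


@dataclass
class RunConfig:
    out_dir: str = "mr2ct_run"
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    inputs: dict[str, str] = field(default_factory=dict)   # mri/ct paths
    simulate: dict = field(default_factory=dict)           # PhantomConfig kwargs
    fcm: dict = field(default_factory=dict)                # FcmConfig kwargs
    bulk: dict[int, float] | None = None
    smoothing_width: int = 10
    registration: dict = field(default_factory=dict)       # MattesConfig kwargs
    pair_slices: list[int] = field(default_factory=lambda: list(DEFAULT_TRAINING_SLICES))
    validation_slices: list[int] = field(default_factory=lambda: list(DEFAULT_VALIDATION_SLICES))
    pair_counts: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    model: dict = field(default_factory=dict)              # ModelSpec kwargs
    training: dict = field(default_factory=dict)           # TrainConfig kwargs
    patches_per_template: int = 500
    stride: int = 18

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        # JSON/YAML map keys arrive as strings; tissue codes are ints
        if cfg.bulk is not None:
            cfg.bulk = {int(k): float(v) for k, v in cfg.bulk.items()}
        cfg.pair_counts = {int(k): int(v) for k, v in cfg.pair_counts.items()}
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        cfg.stages = stages
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(out: Path, stage: str, cfg_fragment: dict, inputs: list[str],
            outputs: list[Path], seed: int, t0: float) -> dict:
    rec = {
        "stage": stage,
        "inputs": inputs,
        "config": cfg_fragment,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_fragment, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 3),
        "outputs": {str(p): _sha256(p) for p in outputs if p.is_file()},
    }
    (out / f"{stage}.provenance.json").write_text(json.dumps(rec, indent=2))
    return rec


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the artifact manifest.

    A stage failure raises after the manifest written so far is flushed to
    ``manifest.json`` (partial-manifest contract).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"out_dir": str(out), "seed": cfg.seed, "stages": {}}
    paths: dict[str, Path] = {}

    def flush() -> None:
        (out / "manifest.json").write_text(json.dumps(
            {**manifest, "stages": {k: {kk: str(vv) for kk, vv in v.items()}
                                    for k, v in manifest["stages"].items()}},
            indent=2, default=str))

    try:
        for stage in STAGES:
            if not cfg.stages.get(stage, False):
                continue
            t0 = time.time()
            log.info("stage %s started", stage)
            outputs = _STAGE_FUNCS[stage](cfg, out, paths)
            manifest["stages"][stage] = outputs
            _record(out, stage, _stage_cfg(cfg, stage),
                    [str(p) for p in paths.values()],
                    [Path(p) for p in outputs.values()
                     if isinstance(p, (str, Path)) and Path(p).exists()],
                    cfg.seed, t0)
            log.info("stage %s finished in %.1fs", stage, time.time() - t0)
            flush()
    except Exception:
        flush()
        log.exception("pipeline halted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest


def _stage_cfg(cfg: RunConfig, stage: str) -> dict:
    return {
        "simulate": cfg.simulate, "segment": cfg.fcm,
        "normalize": {"bulk": cfg.bulk, "width": cfg.smoothing_width},
        "register": cfg.registration,
        "extract_pairs": {"slices": cfg.pair_slices,
                          "validation_slices": cfg.validation_slices,
                          "counts": cfg.pair_counts},
        "train": {"model": cfg.model, "training": cfg.training,
                  "patches_per_template": cfg.patches_per_template},
        "convert": {"stride": cfg.stride},
        "evaluate": {},
    }[stage]


# --- stage implementations -------------------------------------------------


def _stage_simulate(cfg: RunConfig, out: Path, paths: dict) -> dict:
    sim = dict(cfg.simulate)
    if "bias" in sim and isinstance(sim["bias"], dict):
        sim["bias"] = BiasSpec(**sim["bias"])
    sim.setdefault("seed", cfg.seed)
    truth = make_torso_phantom(PhantomConfig(**sim))
    manifest = save_phantom(truth, out / "phantom")
    paths["mri"] = Path(manifest["files"]["mri"])
    paths["ct"] = Path(manifest["files"]["ct"])
    return dict(manifest["files"])


def _stage_segment(cfg: RunConfig, out: Path, paths: dict) -> dict:
    mri = _get_mri(cfg, paths)
    fcm = FcmConfig(**{**cfg.fcm, "seed": cfg.fcm.get("seed", cfg.seed)})
    labels = segment_tissues(mri, fcm)
    p = out / "labels.nii.gz"
    write_labels(labels, p)
    paths["labels"] = p
    return {"labels": str(p)}


def _stage_normalize(cfg: RunConfig, out: Path, paths: dict) -> dict:
    mri = _get_mri(cfg, paths)
    labels = read_labels(paths["labels"]) if "labels" in paths else None
    bulk = BulkIntensities(cfg.bulk) if cfg.bulk else None
    corrected, shading, labels = normalize_mri(
        mri, bulk=bulk, width=cfg.smoothing_width, labels=labels)
    pc, ps = out / "corrected.nii.gz", out / "shading.nii.gz"
    write_volume(corrected, pc)
    write_volume(shading.map, ps)
    paths["corrected"] = pc
    return {"corrected": str(pc), "shading": str(ps)}


def _stage_register(cfg: RunConfig, out: Path, paths: dict) -> dict:
    fixed = read_volume(paths["corrected"]) if "corrected" in paths else _get_mri(cfg, paths)
    moving = _get_ct(cfg, paths)
    mcfg = MattesConfig(**{**cfg.registration, "seed": cfg.registration.get("seed", cfg.seed)})
    result = rigid_register(fixed, moving, mcfg)
    pt, pr = out / "transform.json", out / "ct_registered.nii.gz"
    pt.write_text(json.dumps({**result.transform.to_dict(), "mi": result.mi,
                              "converged": result.converged}, indent=2))
    registered = resample(moving, result.transform, fixed)
    write_volume(registered, pr)
    paths["ct_registered"] = pr
    return {"transform": str(pt), "ct_registered": str(pr)}


def _stage_extract_pairs(cfg: RunConfig, out: Path, paths: dict) -> dict:
    mri = read_volume(paths["corrected"]) if "corrected" in paths else _get_mri(cfg, paths)
    ct = (read_volume(paths["ct_registered"]) if "ct_registered" in paths
          else _get_ct(cfg, paths))
    labels = read_labels(paths["labels"])
    outputs = {}
    for role, slices in [("training", cfg.pair_slices),
                         ("validation", cfg.validation_slices)]:
        pairs = extract_pairs(mri, ct, labels, slices=slices,
                              counts=cfg.pair_counts, role=role)
        p = out / f"pairs_{role}.csv"
        pairs.to_csv(p)
        paths[f"pairs_{role}"] = p
        outputs[f"pairs_{role}"] = str(p)
    return outputs


def _stage_train(cfg: RunConfig, out: Path, paths: dict) -> dict:
    from .pairs import IntensityPairSet

    train_pairs = IntensityPairSet.from_csv(paths["pairs_training"])
    val_pairs = IntensityPairSet.from_csv(paths["pairs_validation"])
    train_patches = crop_patches(build_all_templates(train_pairs),
                                 cfg.patches_per_template, seed=cfg.seed)
    val_patches = crop_patches(build_all_templates(val_pairs),
                               max(cfg.patches_per_template // 5, 1),
                               seed=cfg.seed + 1)
    model = TrainedModel.build(ModelSpec(**cfg.model), seed=cfg.seed)
    tcfg = TrainConfig(**{**cfg.training, "seed": cfg.training.get("seed", cfg.seed)})
    model.train(train_patches, val_patches, tcfg)
    model_dir = out / "model"
    model.save(model_dir)
    paths["model"] = model_dir
    return {"model": str(model_dir),
            "final_val_rmse_hu": model.loss_history[-1].get("val_rmse_hu")}


def _stage_convert(cfg: RunConfig, out: Path, paths: dict) -> dict:
    mri = read_volume(paths["corrected"]) if "corrected" in paths else _get_mri(cfg, paths)
    model = TrainedModel.load(paths["model"])
    pct = predict_volume(model, mri, stride=cfg.stride)
    p = out / "pseudo_ct.nii.gz"
    write_volume(pct, p)
    paths["pseudo_ct"] = p
    return {"pseudo_ct": str(p)}


def _stage_evaluate(cfg: RunConfig, out: Path, paths: dict) -> dict:
    labels = read_labels(paths["labels"])
    outputs = {}
    mri = _get_mri(cfg, paths)
    stats = {"uncorrected_mri": tissue_stats(mri, labels).table}
    if "corrected" in paths:
        stats["corrected_mri"] = tissue_stats(read_volume(paths["corrected"]),
                                              labels).table
    if "pseudo_ct" in paths:
        ct = (read_volume(paths["ct_registered"]) if "ct_registered" in paths
              else _get_ct(cfg, paths))
        report = compare_volumes(read_volume(paths["pseudo_ct"]), ct, labels)
        p = out / "pseudo_vs_real_ct.csv"
        report.to_frame().to_csv(p, index=False)
        outputs["pseudo_vs_real_ct"] = str(p)
    p = out / "tissue_stats.json"
    p.write_text(json.dumps({k: v.to_dict(orient="records")
                             for k, v in stats.items()}, indent=2))
    outputs["tissue_stats"] = str(p)
    return outputs


def _get_mri(cfg: RunConfig, paths: dict) -> Volume:
    if "mri" in paths:
        return read_volume(paths["mri"])
    if "mri" in cfg.inputs:
        paths["mri"] = Path(cfg.inputs["mri"])
        return read_volume(paths["mri"])
    raise FileNotFoundError("no MRI input: enable the simulate stage or set inputs.mri")


def _get_ct(cfg: RunConfig, paths: dict) -> Volume:
    if "ct" in paths:
        return read_volume(paths["ct"])
    if "ct" in cfg.inputs:
        paths["ct"] = Path(cfg.inputs["ct"])
        return read_volume(paths["ct"])
    raise FileNotFoundError("no CT input: enable the simulate stage or set inputs.ct")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "normalize": _stage_normalize,
    "register": _stage_register,
    "extract_pairs": _stage_extract_pairs,
    "train": _stage_train,
    "convert": _stage_convert,
    "evaluate": _stage_evaluate,
}
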