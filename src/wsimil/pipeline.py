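"""Experiment orchestration: simulate → tile → train-features → extract →
{mil | misl} → evaluate, with per-stage manifests, seeds, and caching.

The six patch-size variants mirror the experiment grid of the analysis:
``multires`` (concatenated 256/512/1024 features per leaf), native ``1024``
and ``512`` (whole-patch block averaging into the encoder), ``1024to256``
and ``512to256`` (bilinear resize to 256 px first), and plain ``256``.
Tasks are ``mil2y`` (2-year relapse), ``mil5y`` (5-year relapse), and
``misl`` (survival regression).

Every stage writes ``<stage>.manifest.json`` with the hash of its effective
configuration and of its upstream manifest; a stage re-runs only when that
hash changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import mil as mil_mod
from . import misl as misl_mod
from . import survstats
from .bags import InstanceBag
from .features import EncoderConfig, IdentityEncoder, pairing_accuracy, sample_pairs
from .synthetic import CohortSpec, SyntheticPatient, generate_cohort, generate_tissue_image
from .tiling import (
    build_multires_instances,
    manifest_frame,
    patch_image,
    records_from_frame,
    resize_to_256,
    tile_wsi,
)

logger = logging.getLogger(__name__)

PATCH_VARIANTS = ("multires", "1024", "1024to256", "512", "512to256", "256")
TASKS = ("mil2y", "mil5y", "misl")
HORIZONS = {"mil2y": 730, "mil5y": 1826}


@dataclass
class ExperimentConfig:
    patch_variant: str = "multires"
    task: str = "misl"
    seed: int = 0
    n_patients: int = 30
    image_size_px: int = 1024
    folds: int | None = None  # default: 5 for MIL, 3 for MISL
    tstep: float = 30.0
    encoder: dict = field(default_factory=dict)  # EncoderConfig overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    model: dict = field(default_factory=dict)  # MIL/MISL estimator overrides

    def __post_init__(self) -> None:
        if self.patch_variant not in PATCH_VARIANTS:
            raise ValueError(f"patch_variant must be one of {PATCH_VARIANTS}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    @property
    def n_folds(self) -> int:
        if self.folds is not None:
            return self.folds
        return 3 if self.task == "misl" else 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_fresh(run_dir: Path, stage: str, key: str) -> bool:
    mpath = run_dir / f"{stage}.manifest.json"
    if not mpath.exists():
        return False
    try:
        return json.loads(mpath.read_text()).get("key") == key
    except json.JSONDecodeError:
        return False


def _write_manifest(run_dir: Path, stage: str, key: str, extra: dict | None = None) -> None:
    payload = {"stage": stage, "key": key}
    if extra:
        payload.update(extra)
    (run_dir / f"{stage}.manifest.json").write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: ExperimentConfig, run_dir: Path) -> str:
    key = _hash({"seed": config.seed, "n": config.n_patients,
                 "size": config.image_size_px, "cohort": config.cohort})
    if _stage_fresh(run_dir, "simulate", key):
        logger.info("simulate: cached")
        return key
    spec = CohortSpec(n_patients=config.n_patients,
                      image_size_px=config.image_size_px,
                      rng_seed=config.seed, **config.cohort)
    patients, frame = generate_cohort(spec)
    img_dir = run_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for p in patients:
        img, mask = generate_tissue_image(spec, p)
        Image.fromarray(img).save(img_dir / f"{p.patient_id}.png")
        Image.fromarray(mask).save(img_dir / f"{p.patient_id}.mask.png")
    frame.to_csv(run_dir / "survival.csv", index=False)
    _write_manifest(run_dir, "simulate", key, {"n_patients": config.n_patients})
    return key


def _load_slide(run_dir: Path, patient_id: str) -> tuple[np.ndarray, np.ndarray]:
    img = np.asarray(Image.open(run_dir / "images" / f"{patient_id}.png"))
    mask = np.asarray(Image.open(run_dir / "images" / f"{patient_id}.mask.png"))
    return img, mask


def stage_tile(config: ExperimentConfig, run_dir: Path, upstream: str) -> str:
    key = _hash({"upstream": upstream, "threshold": 0.5})
    if _stage_fresh(run_dir, "tile", key):
        logger.info("tile: cached")
        return key
    survival = pd.read_csv(run_dir / "survival.csv")
    records = []
    for pid in survival["patient_id"]:
        img, mask = _load_slide(run_dir, pid)
        records.extend(tile_wsi(img, mask, wsi_id=pid))
    manifest_frame(records).to_csv(run_dir / "patches.csv", index=False)
    _write_manifest(run_dir, "tile", key, {"n_patches": len(records)})
    return key


def _encoder_config(config: ExperimentConfig) -> EncoderConfig:
    return EncoderConfig(seed=config.seed, **config.encoder)


def stage_train_features(config: ExperimentConfig, run_dir: Path, upstream: str) -> str:
    enc_cfg = _encoder_config(config)
    key = _hash({"upstream": upstream, "encoder": dataclasses.asdict(enc_cfg)})
    if _stage_fresh(run_dir, "train_features", key):
        logger.info("train-features: cached")
        return key
    manifest = pd.read_csv(run_dir / "patches.csv", keep_default_na=False)
    records = {r.patch_id: r for r in records_from_frame(manifest)}
    pairs = sample_pairs(manifest, enc_cfg.n_pairs_per_wsi, seed=config.seed)
    if not pairs:
        raise RuntimeError("train-features: no patch pairs available")
    wsi_ids = sorted({p.wsi_id for p in pairs})
    wsi_index = {w: i for i, w in enumerate(wsi_ids)}
    slides = {w: _load_slide(run_dir, w)[0] for w in wsi_ids}

    def img_of(pid: str) -> np.ndarray:
        rec = records[pid]
        return patch_image(slides[rec.wsi_id], rec)

    X_train = np.stack([img_of(p.train_patch_id) for p in pairs])
    X_val = np.stack([img_of(p.val_patch_id) for p in pairs])
    y = np.array([wsi_index[p.wsi_id] for p in pairs])
    encoder = IdentityEncoder(enc_cfg).fit(X_train, y)
    acc = pairing_accuracy(encoder, X_val, y)
    with open(run_dir / "encoder.pkl", "wb") as fh:
        pickle.dump(encoder, fh)
    _write_manifest(run_dir, "train_features", key,
                    {"pairing_accuracy": acc, "n_pairs": len(pairs)})
    return key


def stage_extract(config: ExperimentConfig, run_dir: Path, upstream: str) -> str:
    key = _hash({"upstream": upstream, "variant": config.patch_variant})
    if _stage_fresh(run_dir, "extract", key):
        logger.info("extract: cached")
        return key
    with open(run_dir / "encoder.pkl", "rb") as fh:
        encoder: IdentityEncoder = pickle.load(fh)
    manifest = pd.read_csv(run_dir / "patches.csv", keep_default_na=False)
    records = records_from_frame(manifest)
    variant = config.patch_variant
    if variant == "multires":
        wanted = {256: "native", 512: "resize", 1024: "resize"}
    elif variant in ("256", "512", "1024"):
        wanted = {int(variant): "native"}
    else:  # 1024to256 / 512to256
        wanted = {int(variant.split("to")[0]): "resize"}

    slides: dict[str, np.ndarray] = {}
    feats: dict[str, np.ndarray] = {}
    batch_ids, batch_imgs = [], []

    def flush() -> None:
        if not batch_imgs:
            return
        X = np.stack(batch_imgs)
        F = encoder.transform(X)
        for pid, f in zip(batch_ids, F):
            feats[pid] = f
        batch_ids.clear()
        batch_imgs.clear()

    by_size: dict[int, list] = {}
    for rec in records:
        if rec.level_px in wanted:
            by_size.setdefault(rec.level_px, []).append(rec)
    for level, recs in sorted(by_size.items()):
        mode = wanted[level]
        for rec in recs:
            if rec.wsi_id not in slides:
                slides[rec.wsi_id] = _load_slide(run_dir, rec.wsi_id)[0]
            img = patch_image(slides[rec.wsi_id], rec)
            if mode == "resize" and level != 256:
                img = resize_to_256(img)
            batch_ids.append(rec.patch_id)
            batch_imgs.append(img)
            if len(batch_imgs) >= 64:
                flush()
        flush()
    arr_ids = sorted(feats)
    np.savez(run_dir / "features.npz",
             features=np.stack([feats[i] for i in arr_ids]))
    pd.DataFrame({"patch_id": arr_ids}).to_csv(run_dir / "features.csv", index=False)
    _write_manifest(run_dir, "extract", key, {"n_features": len(arr_ids)})
    return key


def build_bags(config: ExperimentConfig, run_dir: Path) -> list[InstanceBag]:
    """Assemble per-patient instance bags for the configured patch variant."""
    manifest = pd.read_csv(run_dir / "patches.csv", keep_default_na=False)
    records = records_from_frame(manifest)
    arr = np.load(run_dir / "features.npz")["features"]
    ids = pd.read_csv(run_dir / "features.csv")["patch_id"].astype(str).tolist()
    feats = {pid: arr[i] for i, pid in enumerate(ids)}
    survival = pd.read_csv(run_dir / "survival.csv").set_index("patient_id")

    variant = config.patch_variant
    per_patient: dict[str, tuple[list, list]] = {}
    if variant == "multires":
        for inst in build_multires_instances(records, feats):
            wsi = inst.leaf_patch_id.split(":")[0]
            xs, cs = per_patient.setdefault(wsi, ([], []))
            xs.append(inst.feature)
            cs.append(inst.cluster)
    else:
        level = int(variant.split("to")[0]) if "to" in variant else int(variant)
        for rec in records:
            if rec.level_px != level:
                continue
            xs, cs = per_patient.setdefault(rec.wsi_id, ([], []))
            xs.append(feats[rec.patch_id])
            cs.append(rec.cluster)

    bags = []
    for pid in survival.index:
        if pid not in per_patient:
            logger.warning("patient %s has no retained patches; skipped", pid)
            continue
        xs, cs = per_patient[pid]
        bags.append(InstanceBag(
            patient_id=pid, instances=np.asarray(xs), cluster_labels=cs,
            time_days=float(survival.loc[pid, "time_days"]),
            event=int(survival.loc[pid, "event"]),
        ))
    return bags


def stage_model(config: ExperimentConfig, run_dir: Path, upstream: str) -> str:
    key = _hash({"upstream": upstream, "task": config.task,
                 "folds": config.n_folds, "model": config.model,
                 "tstep": config.tstep})
    if _stage_fresh(run_dir, config.task, key):
        logger.info("%s: cached", config.task)
        return key
    bags = build_bags(config, run_dir)
    if config.task == "misl":
        risk_df, fold_df = misl_mod.train_misl(
            bags, k=config.n_folds, seed=config.seed,
            tstep=config.tstep, **config.model)
        risk_df.to_csv(run_dir / "risks.csv", index=False)
        fold_df.to_csv(run_dir / "folds.csv", index=False)
    else:
        horizon = HORIZONS[config.task]
        pred_df, fold_df = mil_mod.train_mil(
            bags, horizon_days=horizon, k=config.n_folds,
            seed=config.seed, **config.model)
        pred_df.to_csv(run_dir / "predictions.csv", index=False)
        fold_df.to_csv(run_dir / "folds.csv", index=False)
    _write_manifest(run_dir, config.task, key)
    return key


def stage_evaluate(config: ExperimentConfig, run_dir: Path, upstream: str) -> str:
    key = _hash({"upstream": upstream, "eval": 1})
    if _stage_fresh(run_dir, "evaluate", key):
        logger.info("evaluate: cached")
        return key
    results: dict = {"task": config.task, "patch_variant": config.patch_variant,
                     "seed": config.seed}
    if config.task == "misl":
        risk_df = pd.read_csv(run_dir / "risks.csv")
        results["c_index"] = misl_mod.concordance_index(
            risk_df["risk"], risk_df["time_days"], risk_df["event"])
        try:
            cut = survstats.best_cutoff(
                risk_df["risk"].to_numpy(), risk_df["time_days"].to_numpy(),
                risk_df["event"].to_numpy())
            results["cutoff"] = cut["cutoff"]
            results["logrank_p"] = cut["p"]
        except ValueError as exc:
            results["cutoff_error"] = str(exc)
    else:
        pred_df = pd.read_csv(run_dir / "predictions.csv")
        metrics = mil_mod.evaluate_classification(pred_df["p"], pred_df["label"])
        results.update(metrics)
        hi = pred_df["p"] >= 0.5
        surv = pd.read_csv(run_dir / "survival.csv").set_index("patient_id")
        sub = surv.loc[pred_df["patient_id"]]
        if hi.any() and (~hi).any():
            lr = survstats.logrank_one_sided(
                sub.loc[hi.to_numpy(), "time_days"], sub.loc[hi.to_numpy(), "event"],
                sub.loc[(~hi).to_numpy(), "time_days"], sub.loc[(~hi).to_numpy(), "event"])
            results["logrank_p"] = lr["p"]
    (run_dir / "results.json").write_text(json.dumps(results, indent=2, default=float))
    _write_manifest(run_dir, "evaluate", key)
    return key


def run_experiment(config: ExperimentConfig, run_dir: str | Path) -> dict:
    """Execute the full pipeline for one configuration; returns results."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    key = stage_simulate(config, run_dir)
    key = stage_tile(config, run_dir, key)
    key = stage_train_features(config, run_dir, key)
    key = stage_extract(config, run_dir, key)
    key = stage_model(config, run_dir, key)
    stage_evaluate(config, run_dir, key)
    return json.loads((run_dir / "results.json").read_text())
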