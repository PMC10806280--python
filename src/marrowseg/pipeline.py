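"""End-to-end orchestration: phantoms → training → segmentation → QC → BMFF.

A run writes, under its output directory:

* ``phantoms/``   validation fat/water volumes and truth masks (NIfTI),
* ``model/``      checkpoint (npz) and per-step training log (CSV),
* ``segmentations/`` predicted masks (NIfTI),
* ``qc.csv``      per-subject status (OK/Small/Empty) and flags,
* ``ffmaps/``     fat-fraction maps (NIfTI),
* ``bmff.csv``    per-subject mean BMFF records,
* ``summary.json``  held-out Dice, centre error, QC counts, BMFF summary.

Every output carries a ``.provenance.json`` sidecar (config hash, seed,
package version), and a rerun with the same config reproduces all numeric
outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as onp
import pandas as pd
import yaml

from . import __version__
from .fat_fraction import compute_ff, extract_bmff, smooth_volume
from .nn.baseline import BaselineConfig, BaselineUNet
from .nn.roi_unet import NetworkConfig, RoiAttentionUNet
from .phantom import PhantomConfig, generate_dataset
from .qc import QcStatus, compute_region_stats, run_qc
from .train import TrainConfig, evaluate, save_checkpoint, train
from .volumes import LabelMask, RegionLabel, write_mask, write_volume

logger = logging.getLogger("marrowseg.pipeline")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "runs/demo"
    region: str = "diaphysis"
    shape: tuple[int, int, int] = (24, 24, 24)
    n_train: int = 12
    n_val: int = 4
    true_ff_percent: float = 80.0
    noise_sd: float = 5.0
    model: str = "roi_attention"  # or "unet"
    epochs: int = 8
    batch_size: int = 2
    learning_rate: float = 1e-3
    inject_empty_failure: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: Path, cfg_hash: str, seed: int) -> None:
    side = Path(str(path) + ".provenance.json")
    side.write_text(
        json.dumps(
            {"config_hash": cfg_hash, "seed": seed, "package_version": __version__},
            indent=2,
        )
    )


def _build_model(cfg: RunConfig):
    if cfg.model == "roi_attention":
        return RoiAttentionUNet(NetworkConfig.test_scale())
    if cfg.model == "unet":
        return BaselineUNet(BaselineConfig.test_scale())
    raise ValueError(f"unknown model '{cfg.model}' (expected 'roi_attention' or 'unet')")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written to JSON)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    h = _config_hash(cfg)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    region = RegionLabel(cfg.region)
    stage = "phantom"
    try:
        phantom_cfg = PhantomConfig.test_scale(
            region, shape=cfg.shape, true_ff_percent=cfg.true_ff_percent, noise_sd=cfg.noise_sd
        )
        train_set = generate_dataset(cfg.n_train, phantom_cfg, seed=cfg.seed)
        val_set = generate_dataset(cfg.n_val, phantom_cfg, seed=cfg.seed + 10_000)
        pdir = out / "phantoms"
        pdir.mkdir(exist_ok=True)
        for i, s in enumerate(val_set):
            for name, writer, obj in (
                (f"val{i:02d}_fat.nii.gz", write_volume, s.fat),
                (f"val{i:02d}_water.nii.gz", write_volume, s.water),
                (f"val{i:02d}_truth.nii.gz", write_mask, s.truth_mask),
            ):
                writer(obj, pdir / name)
                write_provenance(pdir / name, h, cfg.seed)
        logger.info("generated %d train / %d validation phantoms", cfg.n_train, cfg.n_val)

        stage = "train"
        model = _build_model(cfg)
        params, log = train(
            model,
            train_set,
            TrainConfig(
                epochs=cfg.epochs,
                batch_size=cfg.batch_size,
                learning_rate=cfg.learning_rate,
                seed=cfg.seed,
            ),
        )
        mdir = out / "model"
        mdir.mkdir(exist_ok=True)
        save_checkpoint(params, mdir / "checkpoint.npz")
        pd.DataFrame(log).to_csv(mdir / "training_log.csv", index=False)
        write_provenance(mdir / "checkpoint.npz", h, cfg.seed)
        write_provenance(mdir / "training_log.csv", h, cfg.seed)
        logger.info("trained %s for %d epochs (final loss %.4f)", cfg.model, cfg.epochs, log[-1]["L_total"])

        stage = "segment"
        sdir = out / "segmentations"
        sdir.mkdir(exist_ok=True)
        predicted: list[tuple[str, LabelMask]] = []
        for i, s in enumerate(val_set):
            res = model.predict(params, s.fat)
            mask = res.mask if hasattr(res, "mask") else res
            predicted.append((f"val{i:02d}", mask))
            write_mask(mask, sdir / f"val{i:02d}_mask.nii.gz")
            write_provenance(sdir / f"val{i:02d}_mask.nii.gz", h, cfg.seed)
        report = evaluate(model, params, val_set)

        stage = "qc"
        stats = compute_region_stats([s.truth_mask for s in train_set], region)
        qc_inputs = list(predicted)
        if cfg.inject_empty_failure:
            empty = LabelMask(onp.zeros(cfg.shape, dtype=onp.uint8), phantom_cfg.spacing)
            qc_inputs.append(("injected_failure", empty))
        qc_rows = []
        cleaned_masks: dict[str, LabelMask] = {}
        for subject, mask in qc_inputs:
            cleaned, result = run_qc(mask, stats)
            cleaned_masks[subject] = cleaned
            qc_rows.append(
                {
                    "subject": subject,
                    "region": region.value,
                    "status": result.status.value,
                    "volume_voxels": result.volume,
                    "com_outlier": result.com_outlier,
                    "notes": result.notes,
                }
            )
        qc_df = pd.DataFrame(qc_rows)
        qc_df.to_csv(out / "qc.csv", index=False)
        write_provenance(out / "qc.csv", h, cfg.seed)

        stage = "ffmap"
        fdir = out / "ffmaps"
        fdir.mkdir(exist_ok=True)
        ff_maps = {}
        for i, s in enumerate(val_set):
            ff = compute_ff(smooth_volume(s.fat), smooth_volume(s.water))
            ff_maps[f"val{i:02d}"] = ff
            from .volumes import Volume3D

            write_volume(Volume3D(ff.data, ff.spacing), fdir / f"val{i:02d}_ff.nii.gz")
            write_provenance(fdir / f"val{i:02d}_ff.nii.gz", h, cfg.seed)

        stage = "bmff"
        bmff_rows = []
        for subject, mask in predicted:
            status = next(r["status"] for r in qc_rows if r["subject"] == subject)
            if status != QcStatus.OK.value:
                continue  # Small or Empty outputs are excluded from BMFF analysis
            rec = extract_bmff(ff_maps[subject], cleaned_masks[subject], region)
            bmff_rows.append(
                {
                    "subject": subject,
                    "region": rec.region.value,
                    "mean_ff": rec.mean_ff,
                    "voxels_used": rec.voxels_used,
                    "eroded": rec.eroded,
                }
            )
        bmff_df = pd.DataFrame(bmff_rows)
        bmff_df.to_csv(out / "bmff.csv", index=False)
        write_provenance(out / "bmff.csv", h, cfg.seed)

        stage = "summary"
        status_counts = {s.value: 0 for s in QcStatus}
        for r in qc_rows:
            status_counts[r["status"]] += 1
        summary = {
            "config": cfg.to_dict(),
            "config_hash": h,
            "package_version": __version__,
            "dice": {
                "per_sample": report.per_sample_dice,
                "mean": report.mean_dice,
            },
            "centre_error_normalized": {
                "per_sample": report.per_sample_centre_error,
                "mean": report.mean_centre_error,
            },
            "qc_counts": status_counts,
            "bmff": {
                "n_subjects": len(bmff_rows),
                "mean_ff": float(bmff_df["mean_ff"].mean()) if bmff_rows else None,
                "true_ff_percent": cfg.true_ff_percent,
            },
            "final_train_loss": log[-1]["L_total"],
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        write_provenance(out / "summary.json", h, cfg.seed)
        return summary
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
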