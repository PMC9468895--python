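"""End-to-end pipeline: phantom cohort → split → train → segment → TUR → ROC → staging.

One master seed drives everything: per-stage seeds are derived as the first
four bytes of ``blake2b("turstage:<master>:<stage name>")`` reduced modulo
2^31, so each stage is reproducible in isolation and two runs with the same
configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import __version__ as _version
from .annotations import DatasetSplit, split_dataset
from .errors import EmptySegmentationError, PipelineStageError
from .metrics import DscRecord, dsc, summarize
from .phantom import SEQUENCES, default_params, sample_cohort, write_cohort
from .segmentation import UnetConfig, build_unet, predict_mask, save_checkpoint, train
from .staging import (
    FusionRule,
    TurRecord,
    classify,
    compute_tur,
    evaluate,
    fuse,
    roc_curve,
)

log = logging.getLogger("turstage")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2b(f"turstage:{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_ia: int = Field(22, ge=0)
    n_ib: int = Field(13, ge=0)
    image_size: int = Field(64, ge=32)
    noise_sd: float = Field(6.0, ge=0)
    distractor_prob: float = Field(0.0, ge=0, le=1)


class UnetSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    depth: int = Field(3, ge=2)
    base_channels: int = Field(8, ge=1)
    learning_rate: float = 0.0003
    max_epochs: int = Field(60, ge=1)
    patience: int = Field(10, ge=0)
    batch_size: int = Field(4, ge=1)
    augment_flip: bool = False
    per_sequence: bool = True

    @field_validator("learning_rate")
    @classmethod
    def _lr_positive(cls, v):
        if v <= 0:
            raise ValueError("learning_rate must be > 0")
        return v


class SplitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ratios: tuple[float, float, float] = (6, 1, 3)


class FusionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["single", "k_of_n"] = "k_of_n"
    k: int = Field(2, ge=1)
    sequences: tuple[str, ...] = SEQUENCES

    @field_validator("sequences")
    @classmethod
    def _known(cls, v):
        bad = [s for s in v if s not in SEQUENCES]
        if bad:
            raise ValueError(f"unknown sequences {bad}")
        return v


class PipelineConfig(BaseModel):
    """Validated configuration of one full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = Field(0, ge=0)
    phantom: PhantomSection = PhantomSection()
    unet: UnetSection = UnetSection()
    split: SplitSection = SplitSection()
    fusion: FusionSection = FusionSection()

    @model_validator(mode="after")
    def _image_size_divisible(self):
        if self.phantom.image_size % (1 << self.unet.depth) != 0:
            raise ValueError(
                f"image_size {self.phantom.image_size} not divisible by "
                f"2^depth = {1 << self.unet.depth}"
            )
        return self

    def fusion_rule(self) -> FusionRule:
        if self.fusion.mode == "single":
            return FusionRule(self.fusion.sequences[:1], 1)
        return FusionRule(self.fusion.sequences, self.fusion.k)


def validate_config(document: dict | str | Path | None) -> PipelineConfig:
    """Parse and validate a JSON/YAML pipeline configuration document.

    Unknown keys are rejected; an empty document yields the all-defaults
    configuration.
    """
    if document is None:
        document = {}
    if isinstance(document, Path) or (
        isinstance(document, str) and "\n" not in document and Path(document).exists()
    ):
        document = yaml.safe_load(Path(document).read_text()) or {}
    elif isinstance(document, str):
        document = yaml.safe_load(document) or {}
    return PipelineConfig(**document)


@dataclass(frozen=True)
class RunRecord:
    config: dict
    version: str
    timings: dict[str, float]
    artifacts: dict[str, str]


def run_pipeline(config: PipelineConfig, out_dir: Path) -> RunRecord:
    """Execute the full staging pipeline and persist every intermediate.

    Stages: phantom cohort generation → patient-level split → per-sequence
    U-net training → test-set segmentation → DSC table → TUR table →
    per-sequence ROC with Youden criteria → fused staging report with
    cohort accuracy/sensitivity/specificity.  Any stage failure raises
    :class:`PipelineStageError` carrying the stage name; artifacts written
    so far (and the run record) are left on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    record = RunRecord(config.model_dump(), _version, timings, artifacts)

    def _persist():
        (out_dir / "run_record.json").write_text(json.dumps(record.__dict__, indent=1))

    stage = "phantom"
    try:
        t0 = time.perf_counter()
        params = default_params(config.phantom.image_size, config.phantom.noise_sd,
                                config.phantom.distractor_prob)
        cases = sample_cohort(config.phantom.n_ia, config.phantom.n_ib, params,
                              seed=derive_seed(config.seed, "phantom"))
        manifest = write_cohort(cases, out_dir / "cohort")
        artifacts["manifest"] = str(manifest)
        timings[stage] = time.perf_counter() - t0
        log.info("phantom: %d cases -> %s", len(cases), manifest)

        stage = "split"
        t0 = time.perf_counter()
        split = split_dataset([c.patient_id for c in cases], config.split.ratios,
                              seed=derive_seed(config.seed, "split"))
        (out_dir / "split.json").write_text(split.to_json())
        artifacts["split"] = str(out_dir / "split.json")
        timings[stage] = time.perf_counter() - t0
        log.info("split: %d/%d/%d patients",
                 len(split.train), len(split.validation), len(split.test))

        stage = "train"
        t0 = time.perf_counter()
        by_id = {c.patient_id: c for c in cases}
        models = _train_models(config, split, by_id, out_dir)
        timings[stage] = time.perf_counter() - t0

        stage = "segment"
        t0 = time.perf_counter()
        dsc_records, tur_records = _segment_cohort(split, by_id, models)
        timings[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        part = {pid: split.partition_of(pid) for pid in by_id}
        dsc_df = pd.DataFrame([r.__dict__ for r in dsc_records])
        dsc_df.insert(1, "partition", dsc_df["patient_id"].map(part))
        dsc_df.to_csv(out_dir / "dsc.csv", index=False)
        summarize(dsc_records).to_csv(out_dir / "dsc_summary.csv", index=False)
        artifacts["dsc"] = str(out_dir / "dsc.csv")
        tur_df = pd.DataFrame([r.__dict__ for r in tur_records])
        tur_df.insert(1, "partition", tur_df["patient_id"].map(part))
        tur_df.to_csv(out_dir / "tur.csv", index=False)
        artifacts["tur"] = str(out_dir / "tur.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "roc"
        t0 = time.perf_counter()
        criteria: dict[str, float] = {}
        roc_summary: dict[str, dict] = {}
        for seq in config.fusion.sequences:
            seq_records = [r for r in tur_records
                           if r.sequence == seq and np.isfinite(r.tur)
                           and part[r.patient_id] == "test"]
            roc = roc_curve(seq_records)
            criteria[seq] = roc.criterion
            roc_summary[seq] = {
                "auc": roc.auc, "criterion": roc.criterion,
                "sensitivity": roc.sens_at_criterion,
                "specificity": roc.spec_at_criterion,
            }
            pd.DataFrame({"threshold": roc.thresholds,
                          "sensitivity": roc.sensitivity,
                          "specificity": roc.specificity,
                          }).to_csv(out_dir / f"roc_{seq}.csv", index=False)
        (out_dir / "roc_summary.json").write_text(json.dumps(roc_summary, indent=1))
        artifacts["roc_summary"] = str(out_dir / "roc_summary.json")
        timings[stage] = time.perf_counter() - t0

        stage = "staging"
        t0 = time.perf_counter()
        report_rows = []
        rule = config.fusion_rule()
        for pid in sorted(by_id):  # report covers the whole cohort
            votes = {}
            for seq in rule.sequences:
                rec = next(r for r in tur_records
                           if r.patient_id == pid and r.sequence == seq)
                votes[seq] = (classify(rec.tur, criteria[seq])
                              if np.isfinite(rec.tur) else "IA")
            call = fuse(votes, rule)
            row = {"patient_id": pid, "partition": part[pid],
                   "true_stage": by_id[pid].stage,
                   **{f"vote_{s}": votes[s] for s in rule.sequences},
                   "fused_stage": call}
            report_rows.append(row)
        report = pd.DataFrame(report_rows)
        report.to_csv(out_dir / "staging_report.csv", index=False)
        artifacts["staging_report"] = str(out_dir / "staging_report.csv")
        test_rows = report[report["partition"] == "test"]
        perf = evaluate(list(test_rows["fused_stage"]), list(test_rows["true_stage"]))
        (out_dir / "performance.json").write_text(json.dumps(perf.__dict__, indent=1))
        artifacts["performance"] = str(out_dir / "performance.json")
        timings[stage] = time.perf_counter() - t0
        log.info("staging: accuracy %.3f sensitivity %.3f specificity %.3f",
                 perf.accuracy, perf.sensitivity, perf.specificity)
    except Exception as err:
        _persist()
        raise PipelineStageError(stage, str(err)) from err
    _persist()
    return record


def _train_models(config: PipelineConfig, split: DatasetSplit, by_id, out_dir: Path):
    """One U-net per sequence kind (or one joint model when per_sequence=False)."""
    u = config.unet
    models = {}
    groups = [(s,) for s in SEQUENCES] if u.per_sequence else [SEQUENCES]
    for seqs in groups:
        name = seqs[0] if u.per_sequence else "joint"
        cfg = UnetConfig(
            depth=u.depth, base_channels=u.base_channels,
            in_size=config.phantom.image_size, learning_rate=u.learning_rate,
            max_epochs=u.max_epochs, patience=u.patience, batch_size=u.batch_size,
            seed=derive_seed(config.seed, f"train:{name}"),
            per_sequence=u.per_sequence, augment_flip=u.augment_flip,
        )
        def pairs(ids):
            return [(by_id[i].slices[s].image.pixels, by_id[i].slices[s].mask)
                    for i in ids for s in seqs]
        model = build_unet(cfg)
        model, hist = train(model, pairs(split.train), pairs(split.validation), cfg)
        save_checkpoint(model, out_dir / "models" / name)
        log.info("train[%s]: stopped at epoch %d (best %d, val loss %.4f)",
                 name, hist.stopped_epoch, hist.best_epoch,
                 hist.val_loss[hist.best_epoch - 1])
        for s in seqs:
            models[s] = model
    return models


def _segment_cohort(split, by_id, models):
    dsc_records: list[DscRecord] = []
    tur_records: list[TurRecord] = []
    for pid in sorted(by_id):
        case = by_id[pid]
        for seq in SEQUENCES:
            s = case.slices[seq]
            pred = predict_mask(models[seq], s.image.pixels)
            for structure in ("uterus", "tumor"):
                dsc_records.append(
                    DscRecord(pid, seq, structure, dsc(s.mask, pred, structure)))
            try:
                tur = compute_tur(pred)
            except EmptySegmentationError:
                log.warning("empty predicted segmentation for %s/%s; TUR recorded NaN",
                            pid, seq)
                tur = float("nan")
            tur_records.append(
                TurRecord(pid, seq, tur, case.stage) if np.isfinite(tur)
                else _nan_tur_record(pid, seq, case.stage))
    return dsc_records, tur_records


def _nan_tur_record(pid: str, seq: str, stage: str) -> TurRecord:
    rec = TurRecord.__new__(TurRecord)
    object.__setattr__(rec, "patient_id", pid)
    object.__setattr__(rec, "sequence", seq)
    object.__setattr__(rec, "tur", float("nan"))
    object.__setattr__(rec, "true_stage", stage)
    return rec
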