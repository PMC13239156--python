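"""End-to-end orchestration: stream -> windows -> balance -> train -> report.

The default stage order is leakage-safe: the stratified train/test split
happens on whole windows before anything is fitted, the standard scaler is
fitted on training windows only, and SMOTE balancing is applied to the
training partition only, so no synthetic window (and no test statistic) can
influence what the model sees at test time.  ``paper_order=True`` instead
reproduces the literal workflow of scaling the full dataset and balancing
before the split.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .accel_io import (
    AccelStream,
    LabelCodec,
    apply_scaler,
    clean_labels,
    fit_scaler,
    read_accel_csv,
    save_metadata,
    split_train_test,
)
from .classifier import LSTMClassifier, ModelConfig, TrainHistory, build_model
from .metrics import EvalReport, classification_report, confusion_matrix
from .smote import SmoteConfig, balance
from .windowing import WindowDataset, build_dataset
from .simulate import preset_table1, simulate_stream

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one experiment.

    Either ``input_csvs`` (paths to accelerometer CSV files, windowed
    independently so a window never spans two sources) or ``sim_*`` fields
    (simulator preset) define the input.  One master ``seed`` derives the
    per-stage seeds deterministically.
    """

    input_csvs: list[str] = field(default_factory=list)
    # simulator input (used when input_csvs is empty)
    sim_duration_s: float = 1800.0
    sim_min_share: float | None = 0.004
    sim_scheduled: bool = True
    # windowing: cut window_samples-long windows, optionally subsample to
    # model_timesteps equally spaced steps (the 5 s preset uses 125 -> 10)
    window_samples: int = 10
    model_timesteps: int = 10
    rate_hz: float = 25.0
    drop_labels: list[str] | None = None
    test_fraction: float = 0.20
    use_smote: bool = True
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    paper_order: bool = False
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("simulate", "split", "smote", "model")
        return {name: int(s) & 0x7FFFFFFF for name, s in zip(names, state)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "smote" in raw:
            raw["smote"] = SmoteConfig(**raw["smote"])
        if "model" in raw:
            model = raw["model"]
            if "recurrent_units" in model:
                model["recurrent_units"] = tuple(model["recurrent_units"])
            raw["model"] = ModelConfig(**model)
        return cls(**raw)

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_seeds"] = self.stage_seeds()
        return d


@dataclass
class PipelineResult:
    report: EvalReport
    history: TrainHistory
    model: LSTMClassifier
    train: WindowDataset
    test: WindowDataset
    counts_before_balance: dict[str, int]
    counts_after_balance: dict[str, int]
    manifest: dict


def _load_streams(cfg: PipelineConfig) -> list[AccelStream]:
    if cfg.input_csvs:
        return [read_accel_csv(p, rate_hz=cfg.rate_hz) for p in cfg.input_csvs]
    sim_cfg = preset_table1(
        cfg.sim_duration_s,
        seed=cfg.stage_seeds()["simulate"],
        min_share=cfg.sim_min_share,
        scheduled=cfg.sim_scheduled,
    )
    return [simulate_stream(sim_cfg)]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute read -> clean -> window -> encode -> split -> scale -> balance
    -> train -> evaluate and return the evaluation report plus artifacts.

    In the default order the scaler is fitted on training windows and SMOTE
    is applied to the training partition only; with ``paper_order=True`` the
    scaler is fitted on all windows and balancing precedes the split.
    """
    seeds = cfg.stage_seeds()
    stage = "read"
    try:
        streams = _load_streams(cfg)
        logger.info("read: %d stream(s), %s samples",
                    len(streams), sum(len(s) for s in streams))

        stage = "clean"
        streams = [clean_labels(s, cfg.drop_labels) for s in streams]
        codec = LabelCodec.from_labels(
            lab for s in streams for lab in s.label_inventory()
        )
        logger.info("clean: %d behaviour classes %s", codec.num_classes, codec.names)

        stage = "window"
        dataset = build_dataset(
            streams, cfg.window_samples, codec,
            model_timesteps=cfg.model_timesteps, rate_hz=cfg.rate_hz,
        )
        logger.info("window: %d homogeneous windows of T=%d", len(dataset), dataset.T)

        if cfg.paper_order:
            stage = "scale"
            scaler = fit_scaler(dataset.X)
            dataset.X = apply_scaler(dataset.X, scaler)
            dataset.scaler = scaler
            stage = "balance"
            counts_before = dict(zip(codec.names, dataset.class_counts().tolist()))
            if cfg.use_smote:
                smote_cfg = dataclasses.replace(cfg.smote, seed=seeds["smote"])
                dataset = balance(dataset, smote_cfg)
            stage = "split"
            train, test = split_train_test(dataset, cfg.test_fraction, seed=seeds["split"])
        else:
            stage = "split"
            train, test = split_train_test(dataset, cfg.test_fraction, seed=seeds["split"])
            stage = "scale"
            scaler = fit_scaler(train.X)
            train.X = apply_scaler(train.X, scaler)
            test.X = apply_scaler(test.X, scaler)
            train.scaler = test.scaler = scaler
            stage = "balance"
            counts_before = dict(zip(codec.names, train.class_counts().tolist()))
            if cfg.use_smote:
                smote_cfg = dataclasses.replace(cfg.smote, seed=seeds["smote"])
                train = balance(train, smote_cfg)
        counts_after = dict(zip(codec.names, train.class_counts().tolist()))
        logger.info("balance: %s -> %s", counts_before, counts_after)
        logger.info("split: %d train / %d test windows", len(train), len(test))

        stage = "train"
        model_cfg = dataclasses.replace(cfg.model, seed=seeds["model"])
        model = build_model(model_cfg, train.T, codec.num_classes)
        history = model.fit(train.X, train.y)

        stage = "evaluate"
        y_pred = model.predict(test.X)
        cm = confusion_matrix(test.y, y_pred, codec.num_classes)
        report = classification_report(cm, class_names=codec.names)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    manifest = {"config": cfg.to_manifest(), "stages": {
        "n_streams": len(streams),
        "n_windows": int(len(dataset)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "counts_before_balance": counts_before,
        "counts_after_balance": counts_after,
        "stopped_epoch": history.stopped_epoch,
    }}
    result = PipelineResult(
        report=report, history=history, model=model, train=train, test=test,
        counts_before_balance=counts_before, counts_after_balance=counts_after,
        manifest=manifest,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.save(outdir / "model.npz")
        save_metadata(outdir / "metadata.json", codec, scaler)
        report.save_json(outdir / "report.json")
        (outdir / "report.txt").write_text(report.to_text() + "\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
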