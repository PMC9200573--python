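"""End-to-end orchestration: simulate/load -> preprocess -> featurize -> train -> evaluate.

A single :class:`PipelineConfig` (YAML-serializable, with nested per-stage
parameter blocks) fully determines every artifact: a master seed is expanded
into independent substreams for data generation and the train/test split, and
all floating-point output is written with fixed formatting, so a rerun with
the same config is byte-identical.

Artifacts written into the output directory:

* ``config.yaml``      — snapshot of the effective configuration
* ``features.csv``     — one row per image: label, ten co-occurrence
  statistics, wavelet subband energy shares
* ``model.json``       — the trained stump ensemble
* ``metrics.json``     — accuracy/sensitivity/specificity/AUC on the held-out
  split, plus confusion counts
* ``roc.csv``          — (threshold, fpr, tpr) sweep
* ``run.log``          — per-stage parameters, shapes and timings
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import classifier, evaluation, glcm_features, preprocessing, synthetic_data
from . import wavelet_features

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "featurize_only", "build_feature_table"]

logger = logging.getLogger("thyrotex")

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one serializable record."""

    # input: synthetic generation (default) or an on-disk manifest
    synthetic: synthetic_data.SyntheticConfig = field(
        default_factory=lambda: synthetic_data.default_config(200)
    )
    input_manifest: str | None = None
    # preprocessing
    wiener_window: int = 3
    gabor_frequencies: tuple[float, ...] = preprocessing.DEFAULT_FREQUENCIES
    gabor_orientations: tuple[float, ...] = preprocessing.DEFAULT_ORIENTATIONS
    gabor_combine: str = "max"
    # co-occurrence features
    glcm_levels: int = 32
    glcm_delta: int = 1
    # wavelet features
    wavelet: str = "db2"
    wavelet_levels: int = 1
    # boosting and evaluation
    rounds: int = 50
    test_fraction: float = 0.3
    seed: int = 0
    output_dir: str = "runs/latest"

    def validate(self) -> None:
        if self.input_manifest is None:
            self.synthetic.validate()
        bank = self.gabor_bank()
        bank.validate()
        if self.glcm_levels < 2:
            raise ValueError("glcm_levels must be >= 2")
        if self.glcm_delta < 1:
            raise ValueError("glcm_delta must be >= 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")

    def gabor_bank(self) -> preprocessing.GaborBank:
        return preprocessing.GaborBank(
            frequencies=tuple(self.gabor_frequencies),
            orientations=tuple(self.gabor_orientations),
            combine=self.gabor_combine,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = synthetic_data.SyntheticConfig.from_dict(d["synthetic"])
        for key in ("gabor_frequencies", "gabor_orientations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:16]


def _plain(obj: Any) -> Any:
    """Recursively convert tuples/numpy scalars for YAML/JSON round-trips."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class RunRecord:
    config_hash: str
    timings: dict[str, float]
    artifacts: dict[str, str]
    log_path: str
    report: evaluation.MetricReport | None = None


def _derive_seeds(seed: int) -> tuple[int, int]:
    """(data seed, split seed) from the master seed, both below 2^31."""
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def build_feature_table(
    image_set: synthetic_data.LabeledImageSet, config: PipelineConfig
) -> pd.DataFrame:
    """Preprocess every image and extract the combined feature vector.

    Columns: ``label``, the ten co-occurrence statistics, then the wavelet
    energy shares ``E_LL_l1 ...``.
    """
    bank = config.gabor_bank()
    wnames = wavelet_features.wavelet_feature_names(config.wavelet_levels)
    rows = []
    for img in image_set.images:
        enhanced = preprocessing.hwgf_preprocess(
            img, wiener_window=config.wiener_window, bank=bank
        )
        tex = glcm_features.extract_fglcm(
            enhanced, levels=config.glcm_levels, delta=config.glcm_delta
        )
        awt = wavelet_features.extract_awt(
            enhanced, wavelet=config.wavelet, levels=config.wavelet_levels
        )
        rows.append(np.concatenate([tex.as_array(), awt.as_array()]))
    columns = list(glcm_features.FEATURE_NAMES) + wnames
    table = pd.DataFrame(rows, columns=columns)
    table.insert(0, "label", image_set.labels)
    return table


def _load_or_generate(config: PipelineConfig) -> synthetic_data.LabeledImageSet:
    if config.input_manifest is not None:
        return synthetic_data.load_dataset(config.input_manifest)
    data_seed, _ = _derive_seeds(config.seed)
    cfg = dataclasses.replace(config.synthetic, seed=data_seed)
    return synthetic_data.generate_dataset(cfg)


def _setup_logging(out: Path) -> Path:
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return log_path


class StageError(RuntimeError):
    """An error in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def featurize_only(config: PipelineConfig) -> Path:
    """Run input + preprocessing + feature extraction; return the CSV path."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        image_set = _load_or_generate(config)
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("input", exc) from exc
    try:
        table = build_feature_table(image_set, config)
    except Exception as exc:  # noqa: BLE001
        raise StageError("featurize", exc) from exc
    path = out / "features.csv"
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    config.to_yaml(out / "config.yaml")
    return path


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute the full pipeline; see the module docstring for artifacts."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = _setup_logging(out)
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}
    _, split_seed = _derive_seeds(config.seed)

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s: failed: %s", name, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False

        return _Timer()

    with stage("input"):
        image_set = _load_or_generate(config)
        logger.info(
            "input: %d images of shape %s, %d malignant",
            len(image_set),
            image_set.images[0].shape,
            int(np.sum(image_set.labels)),
        )

    with stage("featurize"):
        table = build_feature_table(image_set, config)
        features_path = out / "features.csv"
        table.to_csv(features_path, index=False, float_format=_FLOAT_FMT)
        artifacts["features"] = str(features_path)
        logger.info("featurize: table %s -> %s", table.shape, features_path)

    with stage("train"):
        X = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        train_idx, test_idx = classifier.stratified_split(
            X, y, test_fraction=config.test_fraction, seed=split_seed
        )
        train = classifier.TrainingSet(
            X[train_idx], y[train_idx],
            feature_names=tuple(table.columns[1:]),
        )
        model = classifier.train_adaboost(train, rounds=config.rounds, seed=config.seed)
        model_path = out / "model.json"
        classifier.save_model(model, model_path)
        artifacts["model"] = str(model_path)
        logger.info(
            "train: %d/%d split, %d boosting rounds retained",
            train_idx.size, test_idx.size, model.rounds,
        )

    with stage("evaluate"):
        report, curve = evaluation.evaluate_pipeline(model, X[test_idx], y[test_idx])
        counts = evaluation.confusion(
            classifier.predict(model, X[test_idx])[0], y[test_idx]
        )
        metrics_path = out / "metrics.json"
        payload = {
            "accuracy": report.accuracy,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "auc": report.auc,
            "confusion": {"tp": counts.tp, "tn": counts.tn,
                          "fp": counts.fp, "fn": counts.fn},
            "n_test": int(test_idx.size),
            "undefined": sorted(report.undefined),
        }
        with open(metrics_path, "w") as fh:
            json.dump(_plain(payload), fh, indent=2, sort_keys=True)
        roc_path = out / "roc.csv"
        pd.DataFrame(
            {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
        ).to_csv(roc_path, index=False, float_format=_FLOAT_FMT)
        artifacts["metrics"] = str(metrics_path)
        artifacts["roc"] = str(roc_path)
        logger.info("evaluate: %s", report.as_percent())

    config.to_yaml(out / "config.yaml")
    artifacts["config"] = str(out / "config.yaml")
    record = RunRecord(
        config_hash=config.config_hash(),
        timings=timings,
        artifacts=artifacts,
        log_path=str(log_path),
        report=report,
    )
    for h in list(logger.handlers):
        h.close()
        logger.removeHandler(h)
    return record
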