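"""Config-driven orchestration of the full study.

One :class:`PipelineConfig` holds every tunable the analysis depends on —
gray levels, pair distance, angles, the IQR fence multiplier, fold count,
SVM C, seeds — so a single YAML file pins a reproducible run. ``run_pipeline``
executes generate/ingest -> extract -> clean -> summarize -> classify and
writes all tables, reports and plots into a run directory together with a
manifest of content hashes; rerunning the same config reproduces the metric
files bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import image_io, synthetic, texture
from .feature_table import COMPARISONS, clean_records, plot_comparison, summarize_comparison
from .classification import plot_best_confusion, plot_roc_folds, run_comparison

log = logging.getLogger("shgtex")


class ValidationError(ValueError):
    """Raised when a manifest or config fails validation."""


@dataclass
class PipelineConfig:
    """Every setting of the end-to-end analysis, YAML-serializable."""

    mode: str = "synthetic"  # "synthetic" | "manifest"
    out_dir: str = "run"
    manifest_path: str | None = None  # for mode="manifest"
    image_root: str | None = None
    seed: int = 0
    field_size: tuple[int, int] = (512, 512)
    glcm_levels: int = 64
    glcm_distance: int = 1
    angles: tuple[int, ...] = texture.ANGLES
    iqr_k: float = 3.0
    cv_k: int = 9
    c_param: float = 1.0
    grouping: str = "datapoint"
    channels: tuple[str, ...] = ("SHG", "TPF")
    comparisons: tuple[str, ...] = tuple(sorted(COMPARISONS))
    make_plots: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "manifest"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        bad = [a for a in self.angles if a not in texture.ANGLES]
        if bad:
            raise ValidationError(f"unsupported angles {bad}")
        if self.cv_k < 2:
            raise ValidationError("cv_k must be >= 2")
        if self.mode == "manifest" and not self.manifest_path:
            raise ValidationError("manifest mode requires manifest_path")
        unknown = [c for c in self.comparisons if c not in COMPARISONS]
        if unknown:
            raise ValidationError(f"unknown comparisons {unknown}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        for name in ("field_size", "angles", "channels", "comparisons"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def validate_manifest(manifest_path: str | Path, root: str | Path | None = None):
    """Validate a dataset manifest: files exist, labels legal, no duplicates.

    Returns the validated DataFrame; raises :class:`ValidationError` listing
    every offending row otherwise.
    """
    manifest_path = Path(manifest_path)
    root = Path(root) if root is not None else manifest_path.parent
    df = image_io.read_manifest(manifest_path)
    problems = []
    for i, row in df.iterrows():
        if not (root / row["file"]).exists():
            problems.append(f"row {i}: missing file {row['file']}")
        if row["channel"] not in image_io.CHANNELS:
            problems.append(f"row {i}: bad channel {row['channel']!r}")
        if row["group"] not in image_io.GROUPS:
            problems.append(f"row {i}: bad group {row['group']!r}")
        if row["diagnosis"] not in image_io.DIAGNOSES:
            problems.append(f"row {i}: bad diagnosis {row['diagnosis']!r}")
    dup = df.duplicated(subset=["file", "channel"], keep=False)
    for i in df.index[dup]:
        problems.append(f"row {i}: duplicate (file, channel) entry {df.loc[i, 'file']}")
    if problems:
        raise ValidationError("manifest validation failed:\n" + "\n".join(problems))
    return df


def extract_features(images, config: PipelineConfig) -> pd.DataFrame:
    """Per-angle GLCM feature extraction over a list of LabeledImages."""
    records = []
    for img in images:
        if img.levels == 256 and config.glcm_levels != 256:
            img = img.quantized(config.glcm_levels)
        records.extend(
            texture.features_per_angle(img, config.glcm_distance, config.angles)
        )
    return pd.DataFrame.from_records(records)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full study; returns the run directory.

    Any stage failure aborts with a stage-named error; partial outputs are
    kept next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        stage = "ingest"
        t0 = time.perf_counter()
        if config.mode == "synthetic":
            dataset = synthetic.generate_study(
                synthetic.default_study_classes(),
                seed=config.seed,
                out_dir=out / "images",
                size_px=config.field_size,
            )
            images = dataset.images
        else:
            manifest = validate_manifest(config.manifest_path, config.image_root)
            root = config.image_root or Path(config.manifest_path).parent
            images = image_io.load_labeled_images(manifest, root)
        timings[stage] = time.perf_counter() - t0
        log.info("ingest: %d images", len(images))

        stage = "extract"
        t0 = time.perf_counter()
        features = extract_features(images, config)
        features.to_csv(out / "features.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        log.info("extract: %d datapoints", len(features))

        stage = "clean"
        t0 = time.perf_counter()
        cleaned, removal_log = clean_records(features, iqr_k=config.iqr_k)
        cleaned.to_csv(out / "features_clean.csv", index=False)
        removal_log.to_csv(out / "removal_log.csv", index=False)
        timings[stage] = time.perf_counter() - t0
        log.info("clean: removed %d of %d records", len(removal_log), len(features))

        stage = "summarize"
        t0 = time.perf_counter()
        summary_rows = []
        for channel in config.channels:
            for comparison in config.comparisons:
                gc = summarize_comparison(cleaned, comparison, channel)
                t = gc.table.assign(comparison=comparison, channel=channel)
                summary_rows.append(t)
                if config.make_plots:
                    plot_comparison(gc, out / f"summary_{comparison}_{channel}.png")
        summary = pd.concat(summary_rows, ignore_index=True)
        summary.to_csv(out / "group_summaries.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        table_rows = []
        for channel in config.channels:
            for comparison in config.comparisons:
                report = run_comparison(
                    cleaned,
                    comparison,
                    channel=channel,
                    k=config.cv_k,
                    seed=config.seed,
                    c_param=config.c_param,
                    grouping=config.grouping,
                )
                report.save_json(out / f"report_{comparison}_{channel}.json")
                if config.make_plots:
                    plot_roc_folds(report, out / f"roc_{comparison}_{channel}.png")
                    plot_best_confusion(
                        report, out / f"confusion_{comparison}_{channel}.png"
                    )
                table_rows.append(
                    {
                        "model": comparison,
                        "channel": channel,
                        "n_datapoints": report.n_datapoints,
                        "best_fold_accuracy": report.best_fold_accuracy,
                        "average_accuracy": report.average_accuracy,
                        "mean_auc": report.mean_auc,
                    }
                )
        pd.DataFrame(table_rows).to_csv(out / "model_accuracies.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        import shgtex

        run_manifest = {
            "package_version": shgtex.__version__,
            "seed": config.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "files": {
                p.name: _sha256(p)
                for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            },
        }
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
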