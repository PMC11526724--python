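"""CSV interchange for feature tables, run configuration and the end-to-end
pipeline.

Feature tables travel as plain CSV with a header row: ``sample_id``, ``label``
(0/1), optional ``source`` (real/synthetic, defaults to real) and one column
per feature.  :func:`run_pipeline` chains the workflow stages -- simulate or
load images, preprocess, extract features, select, augment, evaluate,
interpret -- writing one artifact per stage plus a machine-readable run log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import augment_to_ratio
from .datatypes import RESERVED_COLUMNS, SOURCE_REAL, FeatureTable
from .errors import ValidationError
from .evaluate import ir_sweep_experiment
from .features import ExtractionConfig, extract_all
from .interpret import BootstrapTestConfig, run_all_feature_tests
from .preprocess import PreprocessConfig, remove_hair, resize_image, segment_fallback
from .quality import quality_report
from .selection import BootstrapConfig, ensemble_select
from .simulate import SyntheticLesionSpec, generate_lesion_image


def read_feature_table(path) -> FeatureTable:
    """Read a feature-table CSV; validates label/sample_id columns."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValidationError("label: column missing from CSV")
    if "sample_id" not in df.columns:
        raise ValidationError("sample_id: column missing from CSV")
    labels = df["label"]
    bad = set(labels.unique()) - {0, 1}
    if bad:
        raise ValidationError(f"label: non-binary values {sorted(bad)!r}")
    source = df["source"] if "source" in df.columns else None
    features = df.drop(columns=[c for c in RESERVED_COLUMNS if c in df.columns])
    return FeatureTable(features, labels.to_numpy(), source,
                        sample_ids=df["sample_id"].tolist())


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV; full float precision for round-trips."""
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Flat, typed configuration of one end-to-end run.

    ``n_images``/``melanoma_frac`` drive the synthetic image stage (ignored
    when ``features_csv`` is given, in which case the pipeline starts at the
    selection stage).  Every random operation's seed derives from ``seed``.
    """

    out_dir: str = "dermaug_run"
    seed: int = 0
    # stage 1-2: images (synthetic unless features_csv given)
    features_csv: str | None = None
    n_images: int = 60
    melanoma_frac: float = 0.2
    image_size: int = 96
    ng: int = 32
    # stage 3: ensemble FS
    fs_m: int = 20
    k_final: int = 35
    top_t: int | None = None
    # stage 4: augmentation
    method: str = "smote"
    ratios: tuple[float, ...] = (0.5, 1.0)
    # stage 5: evaluation
    models: tuple[str, ...] = ("lasso",)
    repeats: int = 3
    cv_k: int = 3
    # stage 6: interpretability
    bootstrap_m: int = 1000
    alpha: float = 0.05
    version: str = "0.1.0"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (I/O paths excluded)."""
        fields = {k: v for k, v in asdict(self).items()
                  if k not in ("out_dir", "features_csv")}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Append-only, machine-readable record of the pipeline stages."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, "time": time.time(), **info})

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2, default=str))


def _simulate_table(config: RunConfig, log: RunLog) -> FeatureTable:
    """Stages 1-2: synthetic images -> preprocess -> feature catalogue."""
    rng = np.random.default_rng(config.seed)
    n_mel = max(1, round(config.n_images * config.melanoma_frac))
    rows, labels, ids = [], [], []
    pp = PreprocessConfig(target_size=config.image_size)
    for i in range(config.n_images):
        label = 1 if i < n_mel else 0
        spec = SyntheticLesionSpec(
            image_size=config.image_size,
            eccentricity=float(rng.uniform(1.0, 1.8)),
            asymmetry_coeff=float(rng.uniform(0.2, 0.5)) if label else
            float(rng.uniform(0.0, 0.15)),
            border_waviness=(float(rng.uniform(2, 5)), 8.0) if label else (1.0, 4.0),
            variegation_spots=int(rng.integers(3, 7)) if label else
            int(rng.integers(0, 2)),
            texture_noise_sigma=float(rng.uniform(4, 9)),
            n_hairs=int(rng.integers(0, 4)),
            class_label=label,
            seed=int(rng.integers(0, 2**31)),
        )
        sample = generate_lesion_image(spec)
        image = resize_image(sample.image, config.image_size)
        clean, _ = remove_hair(image, pp)
        mask = segment_fallback(clean)
        rows.append(extract_all(clean, mask, ExtractionConfig(Ng=config.ng)))
        labels.append(label)
        ids.append(f"img_{i:04d}")
    log.record("extract", rows_out=len(rows), n_features=len(rows[0]))
    return FeatureTable(pd.DataFrame(rows), labels, sample_ids=ids)


def run_pipeline(config: RunConfig) -> tuple[dict, RunLog]:
    """Execute the workflow stages in order; returns (artifact paths, log).

    Image stages are skipped when ``config.features_csv`` is supplied.
    Artifacts: features.csv, selected.json, augmented.csv, report.json,
    results.json, interpret.json, run_log.json -- each JSON embeds the config
    hash and master seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    stamp = {"config_hash": config.config_hash(), "seed": config.seed,
             "version": config.version}
    artifacts: dict[str, str] = {}

    def dump(name: str, payload: dict) -> None:
        path = out / name
        path.write_text(json.dumps({**stamp, **payload}, indent=2, default=str,
                                   sort_keys=True))
        artifacts[name] = str(path)

    # stages 1-2
    if config.features_csv:
        table = read_feature_table(config.features_csv)
        log.record("extract", skipped=True, reason="tabular entry point",
                   rows_in=len(table))
    else:
        table = _simulate_table(config, log)
    features_path = out / "features.csv"
    write_feature_table(table, features_path)
    artifacts["features.csv"] = str(features_path)

    # stage 3: ensemble feature selection
    k_final = min(config.k_final, len(table.feature_names))
    selected, ranking = ensemble_select(
        table.features.to_numpy(dtype=float), table.labels.to_numpy(),
        BootstrapConfig(M=config.fs_m, seed=config.seed),
        top_t=config.top_t, k_final=k_final,
        feature_names=table.feature_names)
    dump("selected.json", {
        "selected": selected,
        "ranking": ranking.ranking,
        "votes": {n: int(v) for n, v in zip(ranking.feature_names, ranking.votes)},
    })
    log.record("select", features_in=len(table.feature_names),
               features_out=len(selected))
    reduced = table.select_features(selected)

    # stage 4: augmentation at the largest requested ratio + quality report
    r_max = max(config.ratios)
    augmented = augment_to_ratio(reduced, method=config.method, r=r_max,
                                 seed=config.seed)
    augmented_path = out / "augmented.csv"
    write_feature_table(augmented, augmented_path)
    artifacts["augmented.csv"] = str(augmented_path)
    n_syn = int((augmented.source == "synthetic").sum())
    log.record("augment", rows_in=len(reduced), rows_out=len(augmented),
               n_synthetic=n_syn, achieved_ratio=(
                   (reduced.class_counts()[1] + n_syn) / reduced.class_counts()[0]))

    syn_mask = (augmented.source == "synthetic").to_numpy()
    real_min = reduced.features[reduced.labels == reduced.minority_label]
    if n_syn > 0:
        report = quality_report(real_min.to_numpy(dtype=float),
                                augmented.features.to_numpy(dtype=float)[syn_mask],
                                feature_names=selected)
        dump("report.json", report.to_dict())
        log.record("quality", mean_hd=report.mean_hd, pcd=report.pcd)

    # stage 5: repeated evaluation over the IR sweep
    result = ir_sweep_experiment(
        reduced, models=config.models, oversampler=config.method,
        r_values=config.ratios, repeats=config.repeats, cv_k=config.cv_k,
        seed=config.seed)
    dump("results.json", result.to_dict())
    log.record("evaluate", n_records=len(result.records))

    # stage 6: interpretability
    tests = run_all_feature_tests(
        reduced, BootstrapTestConfig(M=config.bootstrap_m, alpha=config.alpha,
                                     seed=config.seed))
    dump("interpret.json", {"tests": [
        {"feature": t.feature, "delta": t.delta, "ci": list(t.ci),
         "significant": t.significant} for t in tests]})
    log.record("interpret", n_features=len(tests),
               n_significant=sum(t.significant for t in tests))

    log_path = out / "run_log.json"
    log.write(log_path)
    artifacts["run_log.json"] = str(log_path)
    return artifacts, log
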