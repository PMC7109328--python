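"""End-to-end pipeline: simulate/load -> encode -> split -> train/evaluate -> embed.

Every stage writes its artifacts under the configured output directory and
the run finishes with a manifest recording inputs, seeds, software version
and a SHA-256 digest of every artifact.  Rerunning with the same config
reproduces the manifest byte for byte; all randomness flows from the
config's master seed through named derived sub-seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .datasets import (
    BalancedSplit,
    SamplePool,
    derive_seed,
    make_balanced_splits,
    reduce_redundancy,
)
from .embedding import TSNESettings, neighbor_label_purity, tsne_embed
from .features import FeatureMatrix, encode_dataset
from .models import ClassifierSpec, aggregate_reports, cross_validate, evaluate_holdout, fit_classifier
from .seq_io import Label, ProteinRecord, read_fasta, write_fasta
from .synthetic import SyntheticSpec, generate_dataset, write_labels_tsv

logger = logging.getLogger(__name__)

# sub-seed namespaces, so different stages never share a random stream
_NS_CV = 1000
_NS_EMBED = 9000


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    outdir: Path
    seed: int = 0
    source: str = "synthetic"  # or "fasta"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    positive_fasta: Optional[Path] = None
    negative_fasta: Optional[Path] = None
    redundancy: str = "none"  # none | builtin | cdhit
    redundancy_threshold: float = 0.6
    repeats: int = 10
    classifiers: tuple[str, ...] = (
        "random_forest",
        "c45_tree",
        "naive_bayes",
        "svm",
        "knn",
    )
    hyperparameters: dict[str, dict] = field(default_factory=dict)
    cv_folds: int = 10
    holdout: bool = True
    embedding: TSNESettings = field(default_factory=TSNESettings)
    embedding_standardize: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "synthetic" in raw and isinstance(raw["synthetic"], dict):
            syn = dict(raw["synthetic"])
            if "length_range" in syn:
                syn["length_range"] = tuple(syn["length_range"])
            syn.setdefault("seed", raw.get("seed", 0))
            raw["synthetic"] = SyntheticSpec(**syn)
        if "embedding" in raw and isinstance(raw["embedding"], dict):
            raw["embedding"] = TSNESettings(**raw["embedding"])
        if "classifiers" in raw:
            raw["classifiers"] = tuple(raw["classifiers"])
        for key in ("outdir", "positive_fasta", "negative_fasta"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        d = {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "source": self.source,
            "synthetic": asdict(self.synthetic),
            "positive_fasta": str(self.positive_fasta) if self.positive_fasta else None,
            "negative_fasta": str(self.negative_fasta) if self.negative_fasta else None,
            "redundancy": self.redundancy,
            "redundancy_threshold": self.redundancy_threshold,
            "repeats": self.repeats,
            "classifiers": list(self.classifiers),
            "hyperparameters": self.hyperparameters,
            "cv_folds": self.cv_folds,
            "holdout": self.holdout,
            "embedding": asdict(self.embedding),
            "embedding_standardize": self.embedding_standardize,
        }
        d["synthetic"]["length_range"] = list(d["synthetic"]["length_range"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_pool(config: RunConfig) -> SamplePool:
    if config.source == "synthetic":
        return generate_dataset(config.synthetic)
    if config.source == "fasta":
        if config.positive_fasta is None or config.negative_fasta is None:
            raise ValueError("fasta source requires positive_fasta and negative_fasta")
        positives = read_fasta(config.positive_fasta, Label.POSITIVE)
        negatives = read_fasta(config.negative_fasta, Label.NEGATIVE)
        return SamplePool(positives, negatives)
    raise ValueError(f"unknown data source {config.source!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def register(path: Path) -> None:
        artifacts[str(path.relative_to(outdir))] = _sha256(path)

    def stage(name: str):
        logger.info("stage %s: starting", name)
        return _StageTimer(name)

    # ---- data -------------------------------------------------------------
    try:
        with stage("data") as t:
            pool = _load_pool(config)
            pool_dir = outdir / "pool"
            pool_dir.mkdir(exist_ok=True)
            write_fasta(pool.positives, pool_dir / "positives.fasta")
            write_fasta(pool.negatives, pool_dir / "negatives.fasta")
            write_labels_tsv(pool, pool_dir / "labels.tsv")
            for f in ("positives.fasta", "negatives.fasta", "labels.tsv"):
                register(pool_dir / f)
        manifest["stages"]["data"] = {
            "source": config.source,
            "n_positive": pool.n_positive,
            "n_negative": pool.n_negative,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("data", exc) from exc

    # ---- redundancy reduction --------------------------------------------
    try:
        with stage("reduce"):
            if config.redundancy != "none":
                positives = reduce_redundancy(
                    pool.positives, config.redundancy_threshold, config.redundancy
                )
                negatives = reduce_redundancy(
                    pool.negatives, config.redundancy_threshold, config.redundancy
                )
                pool = SamplePool(positives, negatives)
            manifest["stages"]["reduce"] = {
                "method": config.redundancy,
                "threshold": config.redundancy_threshold,
                "n_positive": pool.n_positive,
                "n_negative": pool.n_negative,
            }
    except Exception as exc:
        raise StageError("reduce", exc) from exc

    # ---- splits -----------------------------------------------------------
    try:
        with stage("split"):
            splits = make_balanced_splits(pool, config.repeats, config.seed)
            split_dir = outdir / "splits"
            split_dir.mkdir(exist_ok=True)
            for s in splits:
                path = split_dir / f"split_{s.repetition:02d}.json"
                s.write_manifest(path)
                register(path)
            manifest["stages"]["split"] = {
                "repeats": config.repeats,
                "seed": config.seed,
                "sub_seeds": [s.seed for s in splits],
                "train_size": len(splits[0].train),
                "test_size": len(splits[0].test),
            }
    except Exception as exc:
        raise StageError("split", exc) from exc

    # ---- encode -----------------------------------------------------------
    try:
        with stage("encode"):
            # encode the whole pool once; split matrices are row subsets
            all_records = pool.positives + pool.negatives
            full = encode_dataset(all_records)
            row_of = {rid: i for i, rid in enumerate(full.ids)}

            def matrix_for(records: list[ProteinRecord]) -> FeatureMatrix:
                idx = [row_of[r.id] for r in records]
                return FeatureMatrix(
                    full.X[idx], [r.id for r in records], [r.label for r in records]
                )

            matrix_dir = outdir / "matrices"
            matrix_dir.mkdir(exist_ok=True)
            train_matrices = []
            for s in splits:
                m = matrix_for(s.train)
                train_matrices.append(m)
                path = matrix_dir / f"train_{s.repetition:02d}.csv"
                m.to_csv(path)
                register(path)
            manifest["stages"]["encode"] = {
                "n_sequences": len(full),
                "n_features": full.n_features,
            }
    except Exception as exc:
        raise StageError("encode", exc) from exc

    # ---- train / evaluate -------------------------------------------------
    try:
        with stage("train"):
            report_dir = outdir / "reports"
            report_dir.mkdir(exist_ok=True)
            summary: dict[str, Any] = {}
            for family in config.classifiers:
                cv_reports = []
                for s, train_m in zip(splits, train_matrices):
                    spec = ClassifierSpec(
                        family,
                        dict(config.hyperparameters.get(family, {})),
                        seed=derive_seed(config.seed, s.repetition),
                    )
                    cv_seed = derive_seed(config.seed, _NS_CV + s.repetition)
                    report = cross_validate(train_m, spec, config.cv_folds, cv_seed)
                    path = report_dir / f"split_{s.repetition:02d}_{family}.cv.json"
                    report.to_json(path)
                    register(path)
                    cv_reports.append(report)
                    if config.holdout and s.test:
                        model = fit_classifier(train_m, spec)
                        hold = evaluate_holdout(model, matrix_for(s.test))
                        hpath = (
                            report_dir / f"split_{s.repetition:02d}_{family}.holdout.json"
                        )
                        hold.to_json(hpath)
                        register(hpath)
                overall = aggregate_reports(cv_reports)
                apath = report_dir / f"aggregate_{family}.json"
                overall.to_json(apath)
                register(apath)
                summary[family] = {
                    "cv_acc": overall.metrics.acc,
                    "cv_sn": overall.metrics.sn,
                    "cv_sp": overall.metrics.sp,
                    "cv_mcc": overall.metrics.mcc,
                    "cv_auc": overall.auc,
                }
            manifest["stages"]["train"] = {
                "classifiers": list(config.classifiers),
                "folds": config.cv_folds,
                "summary": summary,
            }
    except Exception as exc:
        raise StageError("train", exc) from exc

    # ---- embed ------------------------------------------------------------
    try:
        with stage("embed"):
            embed_dir = outdir / "embedding"
            embed_dir.mkdir(exist_ok=True)
            embed_seed = derive_seed(config.seed, _NS_EMBED)
            result = tsne_embed(
                train_matrices[0],
                config.embedding,
                seed=embed_seed,
                standardize=config.embedding_standardize,
            )
            result.to_tsv(embed_dir / "embedding.tsv")
            result.write_settings_json(embed_dir / "embedding.settings.json")
            register(embed_dir / "embedding.tsv")
            register(embed_dir / "embedding.settings.json")
            manifest["stages"]["embed"] = {
                "seed": embed_seed,
                "kl_divergence": result.kl_divergence,
                "neighbor_purity_k10": neighbor_label_purity(result, k=10),
            }
    except Exception as exc:
        raise StageError("embed", exc) from exc

    manifest["artifacts"] = dict(sorted(artifacts.items()))
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d artifacts, manifest at %s", len(artifacts), manifest_path)
    return manifest


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        else:
            logger.error("stage %s: failed after %.2fs", self.name, dt)
        return False
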