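"""End-to-end experiment orchestration.

Runs the two evaluation protocols over a catalog (synthetic world or
disk manifest): split → supplement rare classes → fit each backend on
the rebalanced, augmented training stream → predict → score → ensemble.
The untrained-location protocol repeats this per location-blocked fold
and aggregates accuracy and macro F1 as mean ± population SD across
folds.

Every report embeds the fully resolved configuration (all seeds
explicit) and a config hash, so a report is reproducible from its own
metadata alone; reruns with identical config are byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import data_requirements as dr
from .catalog import Catalog, ClassRecallRow, class_counts, load_manifest
from .classify import (SoftmaxPixelClassifier, TrainConfig, ensemble_predict,
                       fit, make_backend, predict_top1)
from .metrics import MetricsReport, confusion, per_class_recall_table, report
from .sampling import supplement_to_minimum
from .splits import (SplitAssignment, location_kfold_plan, materialize_fold,
                     trained_location_split, verify_no_location_leakage)
from .synthetic import SyntheticWorld, SyntheticWorldConfig, generate_world

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "PipelineError",
    "run_trained_location",
    "run_untrained_location",
]

log = logging.getLogger("wildtrap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and config hash."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved settings for one experiment.

    Exactly one of ``world`` / ``manifest`` supplies the data.  The
    trained-location protocol uses ``test_fraction`` (default 0.10);
    the untrained-location protocol uses ``k`` contiguous location
    folds (default 5).  ``supplement_min`` is the per-class training
    floor reached by fixed augmented copies (0 disables; the original
    study used 100).
    """

    world: SyntheticWorldConfig | None = None
    manifest: str | None = None
    protocol: str = "trained_location"
    test_fraction: float = 0.10
    k: int = 5
    backends: tuple[str, ...] = ("pixel-logistic",)
    train: TrainConfig = TrainConfig()
    supplement_min: int = 0
    split_seed: int = 0
    recall_bin_edges: tuple[int, ...] = (500, 1000)

    def resolved(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ExperimentReport:
    """Results of one experiment (or of k folds for the untrained
    protocol, with across-fold mean ± population SD aggregates)."""

    protocol: str
    config: dict
    config_hash: str
    per_model: dict[str, MetricsReport]
    ensemble: MetricsReport
    recall_table: list[ClassRecallRow]
    data_requirements: list[dr.RecallBinSummary]
    fold_reports: list["ExperimentReport"] = field(default_factory=list)
    aggregate: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "config": self.config,
            "config_hash": self.config_hash,
            "per_model": {m: r.to_dict() for m, r in self.per_model.items()},
            "ensemble": self.ensemble.to_dict(),
            "recall_table": [
                {"species": r.class_label, "n_train": r.n_train, "n_test": r.n_test,
                 "recall_by_model": dict(r.recall_by_model)}
                for r in self.recall_table],
            "data_requirements": [dataclasses.asdict(s) for s in self.data_requirements],
            "fold_reports": [f.to_dict() for f in self.fold_reports],
            "aggregate": self.aggregate,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------

def _resolve_data(config: ExperimentConfig) -> tuple[Catalog, "dict[str, np.ndarray] | None", Path | None]:
    if (config.world is None) == (config.manifest is None):
        raise PipelineError("exactly one of world / manifest must be set")
    if config.world is not None:
        world: SyntheticWorld = generate_world(config.world)
        return world.catalog, world.images, None
    manifest = Path(config.manifest)
    return load_manifest(manifest), None, manifest.parent


def _loader(images: dict | None, root: Path | None):
    if images is not None:
        return lambda rec: images[rec.image_id]
    from PIL import Image

    def read(rec):
        return np.asarray(Image.open((root or Path(".")) / rec.path).convert("RGB"))

    return read


def _stage(name: str, config_hash: str):
    import contextlib

    @contextlib.contextmanager
    def ctx():
        log.info("stage=%s config=%s", name, config_hash)
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(
                f"stage {name!r} failed (config {config_hash}): {exc}") from exc

    return ctx()


def _evaluate_split(catalog: Catalog, images: dict | None, root: Path | None,
                    split: SplitAssignment, config: ExperimentConfig,
                    fold_tag: str = "") -> ExperimentReport:
    chash = config.config_hash()
    loader = _loader(images, root)

    assert not (split.train_ids & split.test_ids), "train/test overlap"
    train_cat = catalog.subset(split.train_ids)
    test_cat = catalog.subset(split.test_ids)
    if len(test_cat) == 0:
        raise PipelineError(f"stage 'split' produced an empty test set (config {chash})")

    extra_images: dict[str, np.ndarray] = {}
    if config.supplement_min > 0:
        with _stage("supplement", chash):
            train_cat, extra_images = supplement_to_minimum(
                train_cat, config.supplement_min, config.train.augmentation,
                seed=config.train.seed, loader=loader)

    def load_any(rec):
        return extra_images[rec.image_id] if rec.image_id in extra_images else loader(rec)

    train_records = list(train_cat.records)
    # runtime leakage guard: nothing outside the split's training side
    # (plus its own augmented copies) may feed the training stream
    allowed = set(split.train_ids) | set(extra_images)
    assert all(r.image_id in allowed for r in train_records)
    train_images = [load_any(r) for r in train_records]
    train_labels = [r.class_label for r in train_records]
    test_images = [loader(r) for r in test_cat.records]
    test_labels = [r.class_label for r in test_cat.records]

    per_model: dict[str, MetricsReport] = {}
    probas = []
    names = []
    label_order = None
    with _stage("fit-predict" + fold_tag, chash):
        for b_idx, backend_name in enumerate(config.backends):
            backend = make_backend(backend_name)
            inst_name = (backend_name if list(config.backends).count(backend_name) == 1
                         else f"{backend_name}-{b_idx}")
            backend.name = inst_name
            tc = replace(config.train,
                         seed=config.train.seed + 1000 * b_idx,
                         sampler=replace(config.train.sampler,
                                         seed=config.train.sampler.seed + 1000 * b_idx))
            fit(backend, train_images, train_labels, tc)
            if label_order is None:
                label_order = backend.class_labels
            p = backend.predict_proba(test_images)
            probas.append(p)
            names.append(inst_name)
            preds = [backend.class_labels[int(k)] for k in np.argmax(p, axis=1)]
            cm = confusion(test_labels, preds, catalog.classes)
            per_model[inst_name] = report(cm)

    with _stage("ensemble" + fold_tag, chash):
        if len(probas) >= 2:
            ens_preds = ensemble_predict(probas, label_order, names)
        else:
            ens_preds = [label_order[int(k)] for k in np.argmax(probas[0], axis=1)]
        ens_cm = confusion(test_labels, ens_preds, catalog.classes)
        ens_report = report(ens_cm)

    with _stage("recall-table" + fold_tag, chash):
        train_counts = class_counts(train_cat, include_augmented=False)
        for c in catalog.classes:
            train_counts.setdefault(c, 0)
        recall_rows = per_class_recall_table(ens_cm, train_counts, model_name="Ensemble")
        # merge the per-model recalls into the same rows
        merged = []
        for row in recall_rows:
            rbm = dict(row.recall_by_model)
            for inst_name in names:
                pm = per_model[inst_name].per_class.get(row.class_label)
                rbm[inst_name] = pm["recall"] if pm else 0.0
            merged.append(ClassRecallRow(row.class_label, row.n_train, row.n_test, rbm))
        summaries = dr.bin_recall(merged, "Ensemble", config.recall_bin_edges)

    return ExperimentReport(
        protocol=split.protocol, config=config.resolved(), config_hash=chash,
        per_model=per_model, ensemble=ens_report, recall_table=merged,
        data_requirements=summaries)


def run_trained_location(config: ExperimentConfig) -> ExperimentReport:
    """Trained-location protocol: one seeded random 90/10-style image
    split, every location seen during training."""
    chash = config.config_hash()
    with _stage("data", chash):
        catalog, images, root = _resolve_data(config)
    with _stage("split", chash):
        split = trained_location_split(catalog, config.test_fraction, config.split_seed)
    return _evaluate_split(catalog, images, root, split, config)


def run_untrained_location(config: ExperimentConfig) -> ExperimentReport:
    """Untrained-location protocol: k location-blocked folds, each
    trained and evaluated independently; aggregates are mean ±
    population SD across folds."""
    chash = config.config_hash()
    with _stage("data", chash):
        catalog, images, root = _resolve_data(config)
    with _stage("fold-plan", chash):
        plan = location_kfold_plan(catalog.locations, config.k)
    fold_reports = []
    for i in range(plan.k):
        split = materialize_fold(catalog, plan, i, seed=config.split_seed)
        if not verify_no_location_leakage(split, catalog):
            raise PipelineError(f"stage 'fold-{i}' leaked locations (config {chash})")
        fold_reports.append(_evaluate_split(catalog, images, root, split, config,
                                            fold_tag=f"-fold{i}"))

    model_names = list(fold_reports[0].per_model) + ["Ensemble"]
    aggregate = {}
    for name in model_names:
        accs = np.array([
            (f.ensemble if name == "Ensemble" else f.per_model[name]).top1_accuracy
            for f in fold_reports])
        f1s = np.array([
            (f.ensemble if name == "Ensemble" else f.per_model[name]).macro_f1
            for f in fold_reports])
        aggregate[name] = {
            "accuracy_mean": float(accs.mean()), "accuracy_sd": float(accs.std()),
            "macro_f1_mean": float(f1s.mean()), "macro_f1_sd": float(f1s.std()),
        }

    # headline report mirrors the aggregate of the last-listed ensemble
    pooled = ExperimentReport(
        protocol="untrained_location", config=config.resolved(), config_hash=chash,
        per_model=fold_reports[0].per_model, ensemble=fold_reports[0].ensemble,
        recall_table=[], data_requirements=[],
        fold_reports=fold_reports, aggregate=aggregate)
    return pooled
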