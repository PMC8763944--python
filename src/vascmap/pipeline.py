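"""Orchestration of the full workflow: simulate -> preprocess ->
bootstrap-label -> train -> predict -> evaluate.

Every stage writes its intermediates under the run directory, consumes
explicit seeds derived from the master seed, and is idempotent: with
existing outputs it is skipped unless forced. A run manifest records
the configuration hash, resolved seeds, library versions and per-stage
timing, which together suffice to reproduce a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bootstrap_labeler as bl
from . import cnn_segmenter as cnn
from . import evaluation, phantom, volio
from .classes import CLASS_NAMES, TISSUE_CLASSES
from .experiments import subject_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "split_cohort", "run_pipeline"]

STAGES = ("simulate", "preprocess", "bootstrap", "train", "predict", "evaluate")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    n_subjects: int = 2
    train_ratio: float = 0.5
    train_subjects: list[str] | None = None
    balance_on: str | None = None
    contour_fraction: float = 0.05
    run_bootstrap: bool = True
    seed: int = 0
    phantom: phantom.PhantomConfig = dataclasses.field(
        default_factory=phantom.PhantomConfig
    )
    unet: cnn.UNetConfig = dataclasses.field(default_factory=cnn.UNetConfig)
    training: cnn.TrainingConfig = dataclasses.field(
        default_factory=cnn.TrainingConfig
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            ph = dict(kwargs["phantom"])
            if "nidus" in ph:
                ph["nidus"] = phantom.NidusConfig(**ph["nidus"])
            if "grid_shape" in ph:
                ph["grid_shape"] = tuple(ph["grid_shape"])
            if "voxel_size" in ph:
                ph["voxel_size"] = tuple(ph["voxel_size"])
            if "n_vessel_trees" in ph:
                ph["n_vessel_trees"] = tuple(ph["n_vessel_trees"])
            if "vessel_radius_range" in ph:
                ph["vessel_radius_range"] = tuple(ph["vessel_radius_range"])
            if "confounders" in ph:
                ph["confounders"] = frozenset(ph["confounders"])
            if "target_prevalence" in ph:
                ph["target_prevalence"] = {
                    (k if isinstance(k, int) else int(k)): v
                    for k, v in ph["target_prevalence"].items()
                }
            kwargs["phantom"] = phantom.PhantomConfig(**ph)
        if "unet" in kwargs:
            kwargs["unet"] = cnn.UNetConfig(**kwargs["unet"])
        if "training" in kwargs:
            kwargs["training"] = cnn.TrainingConfig(**kwargs["training"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, (frozenset, set, tuple)):
                return sorted(map(enc, o)) if isinstance(o, (frozenset, set)) else list(o)
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
            return o

        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def split_cohort(
    manifest: pd.DataFrame,
    ratio: float | None = None,
    train_subjects: list[str] | None = None,
    balance_on: str | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint exhaustive train/validation split of a cohort manifest.

    Either an explicit training-subject list or a training ratio must
    be given. With ``balance_on`` set to a manifest column, the split
    is stratified on that column's truthiness so the flagged-subject
    proportion in each split stays within one subject of the cohort's.
    """
    subjects = list(manifest["subject"])
    if len(subjects) < 2:
        raise ValueError("split_cohort requires a manifest with >= 2 subjects")
    if train_subjects is not None:
        train = [s for s in subjects if s in set(train_subjects)]
        missing = set(train_subjects) - set(subjects)
        if missing:
            raise ValueError(f"unknown subjects in split: {sorted(missing)}")
        val = [s for s in subjects if s not in set(train_subjects)]
    else:
        if ratio is None:
            raise ValueError("provide either ratio or train_subjects")
        n_train = int(round(ratio * len(subjects)))
        if n_train < 1 or n_train >= len(subjects):
            raise ValueError(
                f"ratio {ratio} yields an empty split for {len(subjects)} subjects"
            )
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 10)))
        if balance_on is not None:
            flags = manifest[balance_on].astype(bool).to_numpy()
            strata = [np.flatnonzero(flags), np.flatnonzero(~flags)]
            train_idx: list[int] = []
            # proportional allocation per stratum, largest first
            quota = n_train
            for si, stratum in enumerate(sorted(strata, key=len, reverse=True)):
                if stratum.size == 0:
                    continue
                want = int(round(ratio * stratum.size))
                want = min(want, quota) if si < len(strata) - 1 else quota
                want = min(want, stratum.size)
                pick = rng.permutation(stratum)[:want]
                train_idx.extend(int(i) for i in pick)
                quota -= len(pick)
            train = [subjects[i] for i in sorted(train_idx)]
        else:
            perm = rng.permutation(len(subjects))
            train = [subjects[i] for i in sorted(perm[:n_train])]
        val = [s for s in subjects if s not in set(train)]
    if not train or not val:
        raise ValueError("split produced an empty train or validation set")
    if set(train) & set(val):
        raise ValueError("train and validation subject sets overlap")
    return train, val


def _subject_volumes(sub_dir: Path):
    tof = volio.read_volume(sub_dir / "tof.nii.gz", "tof")
    t1c = volio.read_volume(sub_dir / "t1c.nii.gz", "t1c")
    t2 = volio.read_volume(sub_dir / "t2.nii.gz", "t2")
    labels = volio.read_volume(sub_dir / "labels.nii.gz", "label")
    spacing = tuple(tof.spacing)
    images = phantom.MultiparametricVolume(tof.data, t1c.data, t2.data, spacing)
    lab = phantom.LabelVolume(labels.data, spacing)
    return images, lab


def run_pipeline(config: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Execute all stages in order; returns paths to the artifacts.

    Any stage failure raises :class:`StageError` naming the stage; the
    outputs of completed stages remain on disk as a resumable
    checkpoint.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "log.jsonl"
    timings: dict[str, float] = {}
    artifacts: dict[str, object] = {}

    def log_event(stage: str, **fields):
        entry = {"stage": stage, **fields}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        logger.info("%s: %s", stage, fields)

    def run_stage(name: str, fn, done):
        t0 = time.perf_counter()
        if done() and not force:
            log_event(name, status="skipped (checkpoint)")
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage boundary
            log_event(name, status="failed", error=str(exc))
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        log_event(name, status="ok", seconds=timings[name])

    phantoms_dir = out / "phantoms"
    manifest_path = phantoms_dir / "manifest.csv"

    def do_simulate():
        phantom.make_cohort(config.n_subjects, config.phantom, config.seed, phantoms_dir)

    run_stage("simulate", do_simulate, manifest_path.exists)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    artifacts["manifest"] = manifest_path

    train_subs, val_subs = split_cohort(
        manifest,
        ratio=None if config.train_subjects else config.train_ratio,
        train_subjects=config.train_subjects,
        balance_on=config.balance_on,
        seed=config.seed,
    )
    log_event("split", train=train_subs, validation=val_subs)

    pre_dir = out / "preprocessed"

    def do_preprocess():
        for sub in manifest["subject"]:
            images, _ = _subject_volumes(phantoms_dir / sub)
            aff = volio.default_affine(images.voxel_size)
            for tag in ("tof", "t1c", "t2"):
                norm = volio.normalize_slices(
                    volio.ImageVolume(images.channel(tag), aff, tag)
                )
                volio.write_volume(norm, pre_dir / sub / f"{tag}.nii.gz")

    run_stage(
        "preprocess",
        do_preprocess,
        lambda: all(
            (pre_dir / s / "t2.nii.gz").exists() for s in manifest["subject"]
        ),
    )

    rough_dir = out / "rough_labels"

    def do_bootstrap():
        for i, sub in enumerate(train_subs):
            images, labels = _subject_volumes(phantoms_dir / sub)
            sseed = phantom.subject_seed(config.seed, 500 + i)
            contours = phantom.sample_contours(labels, config.contour_fraction, sseed)
            samples = bl.extract_features(images, contours)
            model = bl.train_ecoc_svm(samples, bl.EcocConfig(seed=sseed))
            rough = bl.predict_labels(model, images, labels.mask)
            volio.write_volume(
                volio.ImageVolume(rough, labels.affine, "label"),
                rough_dir / sub / "rough_labels.nii.gz",
            )
            bl.save_model(model, rough_dir / sub / "ecoc_model.npz")
            acc = float(
                (rough[labels.mask] == labels.data[labels.mask]).mean()
            )
            log_event("bootstrap", subject=sub, voxel_accuracy=acc)

    if config.run_bootstrap:
        run_stage(
            "bootstrap",
            do_bootstrap,
            lambda: all(
                (rough_dir / s / "rough_labels.nii.gz").exists() for s in train_subs
            ),
        )

    model_path = out / "model.npz"

    def do_train():
        xs, ys = [], []
        for sub in train_subs:
            images, labels = _subject_volumes(phantoms_dir / sub)
            x, y = subject_dataset(labels, images)
            xs.append(x)
            ys.append(y)
        model = cnn.build_unet(config.unet)
        seg = cnn.train(
            model, np.concatenate(xs), np.concatenate(ys), config.training
        )
        cnn.save_segmenter(seg, model_path)

    run_stage("train", do_train, model_path.exists)
    artifacts["model"] = model_path

    pred_dir = out / "predictions"

    def do_predict():
        seg = cnn.load_segmenter(model_path)
        for sub in val_subs:
            images, labels = _subject_volumes(phantoms_dir / sub)
            stack = np.stack([images.tof, images.t1c, images.t2], axis=1)
            proba = cnn.predict_proba(seg, stack)
            preds = cnn.assign_labels(proba, labels.mask)
            volio.write_volume(
                volio.ImageVolume(preds, labels.affine, "label"),
                pred_dir / sub / "predicted_labels.nii.gz",
            )

    run_stage(
        "predict",
        do_predict,
        lambda: all(
            (pred_dir / s / "predicted_labels.nii.gz").exists() for s in val_subs
        ),
    )

    report_path = out / "report.csv"

    def do_evaluate():
        pairs = {}
        for sub in val_subs:
            _, labels = _subject_volumes(phantoms_dir / sub)
            preds = volio.read_volume(
                pred_dir / sub / "predicted_labels.nii.gz", "label"
            )
            pairs[sub] = (labels.data, preds.data)
        report = evaluation.evaluate_cohort(pairs)
        report.to_csv(report_path)
        summary = {
            CLASS_NAMES[c]: report.combined[c] for c in TISSUE_CLASSES
        }
        (out / "report.json").write_text(
            json.dumps({"combined_dsc": summary}, indent=2, sort_keys=True)
        )

    run_stage("evaluate", do_evaluate, report_path.exists)
    artifacts["report"] = report_path

    import sklearn

    run_manifest = {
        "config_hash": config.config_hash(),
        "master_seed": int(config.seed),
        "train_subjects": train_subs,
        "validation_subjects": val_subs,
        "stage_seconds": timings,
        "versions": {"numpy": np.__version__, "sklearn": sklearn.__version__},
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    artifacts["run_manifest"] = out / "run_manifest.json"
    return artifacts
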