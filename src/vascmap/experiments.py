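"""End-to-end study protocols run at desk scale.

`scaled_validation_run` reproduces the full training/validation
protocol on synthetic phantoms: simulate a cohort, train the
three-channel five-class U-Net on the training subjects' ground-truth
maps, predict the held-out subjects and pool per-class Dice
coefficients across them. Problem sizes default to a scaled-down
setting (ten 48x128x128 phantoms, a depth-3 base-16 network, five
epochs) chosen so the whole protocol completes in minutes on one CPU
core while exercising every stage of the method.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import cnn_segmenter as cnn
from . import evaluation, phantom
from .classes import TISSUE_CLASSES, CLASS_NAMES
from .volio import normalize_slices_array

logger = logging.getLogger(__name__)

__all__ = ["scaled_validation_run", "subject_dataset"]


def subject_dataset(
    labels: phantom.LabelVolume, images: phantom.MultiparametricVolume
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice normalized 3-channel samples and label slices."""
    x = np.stack(
        [
            normalize_slices_array(images.tof),
            normalize_slices_array(images.t1c),
            normalize_slices_array(images.t2),
        ],
        axis=1,
    )
    return x.astype(np.float32), labels.data.astype(np.uint8)


def scaled_validation_run(
    seed: int,
    n_subjects: int = 10,
    n_train: int = 8,
    grid_shape: tuple[int, int, int] = (48, 128, 128),
    noise_sigma: float = 0.05,
    depth: int = 3,
    base_filters: int = 16,
    epochs: int = 5,
    batch_size: int = 6,
) -> dict:
    """Simulate, train and evaluate the scaled-down protocol.

    Phantoms use the default contrast table and class-prevalence
    targets; the first ``n_train`` subjects train the network and the
    remainder are held out. Returns pooled validation DSC per class,
    the full report, the training history and the voxel count pooled
    over validation subjects.
    """
    if not 1 <= n_train < n_subjects:
        raise ValueError("need at least one training and one validation subject")
    master = int(seed) % (2**31)
    cfg = phantom.PhantomConfig(
        grid_shape=grid_shape, noise_sigma=noise_sigma, seed=master
    )
    train_x, train_y = [], []
    validation: dict[str, tuple[phantom.LabelVolume, phantom.MultiparametricVolume]] = {}
    for i in range(n_subjects):
        scfg = dataclasses.replace(cfg, seed=phantom.subject_seed(master, i))
        labels, images, _ = phantom.simulate_subject(scfg)
        if i < n_train:
            x, y = subject_dataset(labels, images)
            train_x.append(x)
            train_y.append(y)
        else:
            validation[f"sub-{i:02d}"] = (labels, images)
    images_arr = np.concatenate(train_x, axis=0)
    labels_arr = np.concatenate(train_y, axis=0)
    logger.info("training on %d slices from %d subjects", images_arr.shape[0], n_train)

    ucfg = cnn.UNetConfig(depth=depth, base_filters=base_filters, seed=master)
    tcfg = cnn.TrainingConfig(
        batch_size=batch_size, epochs=epochs, augment=True, seed=master
    )
    model = cnn.build_unet(ucfg)
    segmenter = cnn.train(model, images_arr, labels_arr, tcfg)

    pairs = {}
    for sub, (labels, images) in validation.items():
        stack = np.stack([images.tof, images.t1c, images.t2], axis=1)
        proba = cnn.predict_proba(segmenter, stack)
        preds = cnn.assign_labels(proba, labels.mask)
        pairs[sub] = (labels.data, preds)
    report = evaluation.evaluate_cohort(pairs)
    n_voxels = int(sum(np.count_nonzero(lab != 0) for lab, _ in pairs.values()))
    dsc = {CLASS_NAMES[c]: report.combined[c] for c in TISSUE_CLASSES}
    logger.info("pooled validation DSC: %s", dsc)
    return {
        "dsc": dsc,
        "report": report,
        "history": segmenter.history,
        "n_validation_voxels": n_voxels,
        "segmenter": segmenter,
    }
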