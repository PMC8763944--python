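"""Dice similarity coefficient evaluation.

For a class x, DSC_x = 2 |X_label ∩ X_pred| / (|X_label| + |X_pred|),
computed over non-excluded voxels only. A class absent from both the
labels and the predictions of a unit (subject or slice) yields N/A
(``None``), mirroring subjects that simply contain no embolized
vessel; a class present on exactly one side yields 0.

Cohort-level ("combined") DSCs pool voxel counts across subjects
(micro-average: summed intersections over summed sizes) rather than
averaging per-subject coefficients; the per-subject mean is also
reported for comparison.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .classes import CLASS_NAMES, EXCLUDED, TISSUE_CLASSES

__all__ = [
    "compute_dsc",
    "evaluate_subject",
    "evaluate_cohort",
    "class_prevalence",
    "DiceReport",
]


def compute_dsc(label_mask: np.ndarray, pred_mask: np.ndarray) -> float | None:
    """DSC between two boolean masks; None (N/A) when both are empty."""
    label_mask = np.asarray(label_mask, dtype=bool)
    pred_mask = np.asarray(pred_mask, dtype=bool)
    if label_mask.shape != pred_mask.shape:
        raise ValueError(
            f"mask grids differ: {label_mask.shape} vs {pred_mask.shape}"
        )
    n_label = int(label_mask.sum())
    n_pred = int(pred_mask.sum())
    if n_label == 0 and n_pred == 0:
        return None
    inter = int(np.count_nonzero(label_mask & pred_mask))
    return 2.0 * inter / (n_label + n_pred)


def _class_counts(labels: np.ndarray, preds: np.ndarray) -> dict[int, tuple[int, int, int]]:
    """(intersection, |label|, |pred|) per class over non-excluded voxels."""
    included = labels != EXCLUDED
    counts = {}
    for c in TISSUE_CLASSES:
        lm = (labels == c) & included
        pm = (preds == c) & included
        counts[c] = (
            int(np.count_nonzero(lm & pm)),
            int(np.count_nonzero(lm)),
            int(np.count_nonzero(pm)),
        )
    return counts


def _dsc_from_counts(inter: int, n_label: int, n_pred: int) -> float | None:
    if n_label == 0 and n_pred == 0:
        return None
    return 2.0 * inter / (n_label + n_pred)


def evaluate_subject(labels: np.ndarray, preds: np.ndarray) -> dict[int, float | None]:
    """Per-class DSC row for one subject.

    Predictions are restricted to the labels' non-excluded region, so
    extracranial voxels never influence the coefficients. Codes outside
    0..5 are rejected.
    """
    labels = np.asarray(labels)
    preds = np.asarray(preds)
    if labels.shape != preds.shape:
        raise ValueError(f"grids differ: {labels.shape} vs {preds.shape}")
    for arr, name in ((labels, "labels"), (preds, "predictions")):
        u = np.unique(arr)
        if u.size and (u.min() < 0 or u.max() > 5):
            raise ValueError(f"{name} contain codes outside 0..5: {u}")
    counts = _class_counts(labels, preds)
    return {c: _dsc_from_counts(*counts[c]) for c in TISSUE_CLASSES}


@dataclasses.dataclass
class DiceReport:
    """Per-subject, pooled and optional per-slice DSCs plus the voxel
    counts the pooled values derive from."""

    per_subject: dict[str, dict[int, float | None]]
    combined: dict[int, float | None]
    subject_mean: dict[int, float | None]
    voxel_counts: dict[int, tuple[int, int, int]]
    per_slice: dict | None = None

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular layout: subjects as rows, classes as columns, a
        final pooled row (and a per-subject mean row)."""
        cols = [CLASS_NAMES[c] for c in TISSUE_CLASSES]
        rows = {}
        for sub, row in self.per_subject.items():
            rows[sub] = [row[c] for c in TISSUE_CLASSES]
        rows["combined"] = [self.combined[c] for c in TISSUE_CLASSES]
        rows["subject_mean"] = [self.subject_mean[c] for c in TISSUE_CLASSES]
        df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        df.index.name = "subject"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, na_rep="N/A", float_format="%.6f")


def evaluate_cohort(
    subjects: dict[str, tuple[np.ndarray, np.ndarray]],
    per_slice: bool = False,
) -> DiceReport:
    """Evaluate (labels, predictions) pairs for >= 1 subject.

    The combined row pools voxel counts across subjects; N/A appears
    only for classes empty in both labels and predictions everywhere.
    """
    if not subjects:
        raise ValueError("evaluate_cohort requires at least one subject")
    per_subject = {}
    pooled = {c: np.zeros(3, dtype=np.int64) for c in TISSUE_CLASSES}
    slice_rows = {} if per_slice else None
    for sub, (labels, preds) in subjects.items():
        per_subject[sub] = evaluate_subject(labels, preds)
        counts = _class_counts(np.asarray(labels), np.asarray(preds))
        for c in TISSUE_CLASSES:
            pooled[c] += np.asarray(counts[c])
        if per_slice:
            for k in range(np.asarray(labels).shape[0]):
                slice_rows[(sub, k)] = evaluate_subject(
                    np.asarray(labels)[k : k + 1], np.asarray(preds)[k : k + 1]
                )
    combined = {c: _dsc_from_counts(*pooled[c]) for c in TISSUE_CLASSES}
    subject_mean = {}
    for c in TISSUE_CLASSES:
        vals = [row[c] for row in per_subject.values() if row[c] is not None]
        subject_mean[c] = float(np.mean(vals)) if vals else None
    return DiceReport(
        per_subject=per_subject,
        combined=combined,
        subject_mean=subject_mean,
        voxel_counts={c: tuple(int(v) for v in pooled[c]) for c in TISSUE_CLASSES},
        per_slice=slice_rows,
    )


def class_prevalence(labels: np.ndarray) -> dict[int, float]:
    """Fraction of non-excluded voxels per tissue class (sums to 1)."""
    labels = np.asarray(labels)
    included = labels != EXCLUDED
    n = int(included.sum())
    if n == 0:
        raise ValueError("label volume is entirely excluded")
    return {c: int(np.count_nonzero(labels == c)) / n for c in TISSUE_CLASSES}
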