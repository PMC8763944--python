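"""Per-subject SVM + error-correcting-output-codes voxel classifier.

Small per-class sample contours provide intensity triplets (TOF, T1+c,
T2) from which a multiclass model is trained: features are
standardized, one linear-kernel margin classifier is fitted per column
of an ECOC coding matrix (one-vs-one by default, one-vs-all
available), and whole-volume prediction assigns each intracranial
voxel the class minimizing the hinge-loss-weighted decoding distance
over learner margins. The output is the rough vascular-anatomical map
that a human editor would then refine.

The binary learners are scikit-learn linear SVMs with per-class
balanced misclassification weights; the coding matrix construction and
loss-weighted decoding are implemented here.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

from .classes import EXCLUDED
from .phantom import MultiparametricVolume

__all__ = [
    "VoxelSamples",
    "EcocModel",
    "extract_features",
    "train_ecoc_svm",
    "predict_labels",
    "decode_distances",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class VoxelSamples:
    """Per-voxel intensity triplets with their contour class codes."""

    features: np.ndarray  # (n, 3) float
    class_codes: np.ndarray  # (n,) int in 1..5

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.class_codes = np.asarray(self.class_codes, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[1] != 3:
            raise ValueError("features must be (n, 3) intensity triplets")
        if self.features.shape[0] != self.class_codes.shape[0]:
            raise ValueError("features and class_codes disagree in length")
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        classes, counts = np.unique(self.class_codes, return_counts=True)
        if classes.size < 2:
            raise ValueError("samples must contain at least 2 distinct classes")
        if counts.min() < 2:
            raise ValueError("every sampled class needs at least 2 voxels")

    @property
    def counts(self) -> dict[int, int]:
        classes, counts = np.unique(self.class_codes, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))


def extract_features(
    volumes: MultiparametricVolume, contours: dict[int, np.ndarray]
) -> VoxelSamples:
    """Intensity triplets at the contoured voxels.

    One feature row per contoured voxel, ordered by class code then by
    voxel raster order; the class is taken from the contour's code.
    """
    if not contours:
        raise ValueError("empty contour set")
    shape = np.asarray(volumes.shape)
    feats = []
    codes = []
    for cls in sorted(contours):
        idx = np.asarray(contours[cls], dtype=np.int64)
        if idx.size == 0:
            continue
        if idx.ndim != 2 or idx.shape[1] != 3:
            raise ValueError("contour indices must be (m, 3) voxel triples")
        if (idx < 0).any() or (idx >= shape).any():
            raise IndexError(
                f"contour for class {cls} contains indices outside the grid"
            )
        raster = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), tuple(shape))
        idx = idx[np.argsort(raster, kind="stable")]
        feats.append(volumes.features(idx))
        codes.append(np.full(idx.shape[0], cls, dtype=np.int64))
    if not feats:
        raise ValueError("contours contain no voxels")
    return VoxelSamples(np.concatenate(feats), np.concatenate(codes))


def _coding_matrix(classes: np.ndarray, scheme: str) -> np.ndarray:
    k = classes.size
    if scheme == "one_vs_one":
        cols = []
        for i, j in combinations(range(k), 2):
            col = np.zeros(k, dtype=np.int8)
            col[i], col[j] = 1, -1
            cols.append(col)
        m = np.stack(cols, axis=1) if cols else np.zeros((k, 0), dtype=np.int8)
    elif scheme == "one_vs_all":
        m = -np.ones((k, k), dtype=np.int8)
        np.fill_diagonal(m, 1)
        if k == 2:  # both columns encode the same dichotomy; keep one
            m = m[:, :1]
    else:
        raise ValueError(f"unknown coding scheme {scheme!r}")
    return m


@dataclasses.dataclass
class EcocConfig:
    coding: str = "one_vs_one"
    C: float = 1.0
    seed: int = 0


@dataclasses.dataclass
class EcocModel:
    """Coding matrix, fitted binary learners and feature scaling."""

    coding_matrix: np.ndarray  # (k, L) in {-1, 0, +1}
    learner_weights: np.ndarray  # (L, 3)
    learner_biases: np.ndarray  # (L,)
    feature_mean: np.ndarray  # (3,)
    feature_scale: np.ndarray  # (3,)
    class_codes: np.ndarray  # (k,) ordered class list
    config: EcocConfig = dataclasses.field(default_factory=EcocConfig)

    def __post_init__(self) -> None:
        m = np.asarray(self.coding_matrix)
        if np.unique(m, axis=0).shape[0] != m.shape[0]:
            raise ValueError("coding matrix has duplicate class rows")
        for col in range(m.shape[1]):
            if not ((m[:, col] == 1).any() and (m[:, col] == -1).any()):
                raise ValueError(f"coding column {col} lacks a +1 or -1 entry")

    def margins(self, features: np.ndarray) -> np.ndarray:
        z = (features - self.feature_mean) / self.feature_scale
        return z @ self.learner_weights.T + self.learner_biases


def train_ecoc_svm(samples: VoxelSamples, config: EcocConfig | None = None) -> EcocModel:
    """Fit the ECOC ensemble of linear SVMs on sampled voxels.

    Features are standardized to zero mean and unit scale on the
    training set. One linear margin classifier is trained per coding
    column on the +-1 classes of that column, with balanced class
    weights; a column whose dichotomy has a single class present in the
    samples is skipped with a warning (degenerate subject).
    """
    if config is None:
        config = EcocConfig()
    classes = np.unique(samples.class_codes)
    coding = _coding_matrix(classes, config.coding)
    mean = samples.features.mean(axis=0)
    scale = samples.features.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    z = (samples.features - mean) / scale
    weights, biases, kept = [], [], []
    for col in range(coding.shape[1]):
        pos = classes[coding[:, col] == 1]
        neg = classes[coding[:, col] == -1]
        sel = np.isin(samples.class_codes, np.concatenate([pos, neg]))
        y = np.where(np.isin(samples.class_codes[sel], pos), 1, -1)
        if np.unique(y).size < 2:
            warnings.warn(
                f"coding column {col} has a single class present; learner skipped"
            )
            continue
        svc = LinearSVC(
            C=config.C,
            class_weight="balanced",
            dual=False,
            random_state=config.seed,
        )
        svc.fit(z[sel], y)
        weights.append(svc.coef_[0])
        biases.append(float(svc.intercept_[0]))
        kept.append(col)
    if not kept:
        raise ValueError("no trainable coding column; samples too degenerate")
    return EcocModel(
        coding_matrix=coding[:, kept],
        learner_weights=np.asarray(weights),
        learner_biases=np.asarray(biases),
        feature_mean=mean,
        feature_scale=scale,
        class_codes=classes,
        config=config,
    )


def decode_distances(coding_matrix: np.ndarray, margins: np.ndarray) -> np.ndarray:
    """Hinge loss-weighted ECOC decoding distance per class.

    For class row m_k and learner margins s, the distance is
    sum_l |m_kl| * max(0, 1 - m_kl s_l) / (2 sum_l |m_kl|).
    Returns (n, k) distances.
    """
    m = np.asarray(coding_matrix, dtype=np.float64)  # (k, L)
    s = np.asarray(margins, dtype=np.float64)  # (n, L)
    hinge = np.maximum(0.0, 1.0 - s[:, None, :] * m[None, :, :])  # (n, k, L)
    w = np.abs(m)
    return (hinge * w[None]).sum(axis=2) / (2.0 * w.sum(axis=1)[None, :])


def predict_samples(model: EcocModel, features: np.ndarray) -> np.ndarray:
    """Class codes minimizing the decoding distance (ties break to the
    lowest class code)."""
    d = decode_distances(model.coding_matrix, model.margins(features))
    return model.class_codes[d.argmin(axis=1)]


def predict_labels(
    model: EcocModel,
    volumes: MultiparametricVolume,
    mask: np.ndarray,
    chunk: int = 1 << 18,
) -> np.ndarray:
    """Classify every intracranial voxel; the rough whole-volume map.

    Voxels outside the mask receive the excluded code.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volumes.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {volumes.shape}"
        )
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[:] = EXCLUDED
    idx = np.argwhere(mask)
    for start in range(0, idx.shape[0], chunk):
        block = idx[start : start + chunk]
        feats = volumes.features(block)
        out[block[:, 0], block[:, 1], block[:, 2]] = predict_samples(model, feats)
    return out


# ---------------------------------------------------------------------------
# serialization (versioned single-file schema)


def save_model(model: EcocModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"format": "vascmap-ecoc-v1", "config": dataclasses.asdict(model.config)}
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        coding_matrix=model.coding_matrix,
        learner_weights=model.learner_weights,
        learner_biases=model.learner_biases,
        feature_mean=model.feature_mean,
        feature_scale=model.feature_scale,
        class_codes=model.class_codes,
    )
    return path


def load_model(path) -> EcocModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "vascmap-ecoc-v1":
            raise ValueError(f"unrecognized ECOC model format in {path}")
        return EcocModel(
            coding_matrix=data["coding_matrix"],
            learner_weights=data["learner_weights"],
            learner_biases=data["learner_biases"],
            feature_mean=data["feature_mean"],
            feature_scale=data["feature_scale"],
            class_codes=data["class_codes"],
            config=EcocConfig(**meta["config"]),
        )
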