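"""Modified 2D U-Net for five-class vascular-anatomical mapping.

The network follows the classic U-Net encoder-decoder with skip
connections — two 3x3 convolutions + ReLU per level, 2x2 max pooling
down, 2x2 up-convolution up — modified to take three input channels
(TOF, T1+c, T2) and to end in a 1x1 convolution with five output
channels followed by a voxel-wise softmax.

Two padding conventions are supported. ``padding_mode="same"`` (the
default) keeps every feature map at the input size, so no pad
bookkeeping is needed. ``padding_mode="paper_valid"`` uses valid
convolutions as in the original U-Net: the input is zero-padded before
the network by the traced convolution loss (16/40/88/184 for depths
1-4) so the crop chain returns the original matrix size; where strict
even-halving is infeasible at the loss-only pad, the pad is enlarged to
the next feasible size and the output center-cropped back.

Training minimizes categorical cross-entropy over non-excluded voxels
only (excluded voxels contribute zero loss and zero gradient), with
Adam at its canonical defaults and offline left-right reflection
augmentation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np

from . import nn
from .classes import EXCLUDED
from .volio import normalize_slices_array

logger = logging.getLogger(__name__)

__all__ = [
    "UNetConfig",
    "TrainingConfig",
    "UNet",
    "TrainedSegmenter",
    "build_unet",
    "augment_lr",
    "train",
    "predict_proba",
    "assign_labels",
    "valid_unet_trace",
    "valid_total_loss",
    "padded_input_size",
    "feasible_padded_input_size",
    "save_segmenter",
    "load_segmenter",
]


@dataclasses.dataclass
class UNetConfig:
    depth: int = 3  # number of pooling levels
    base_filters: int = 16
    padding_mode: str = "same"
    input_channels: int = 3
    output_classes: int = 5
    batch_norm: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.input_channels != 3:
            raise ValueError("the model contract fixes input_channels at 3")
        if self.output_classes != 5:
            raise ValueError("the model contract fixes output_classes at 5")
        if self.padding_mode not in ("same", "paper_valid"):
            raise ValueError("padding_mode must be 'same' or 'paper_valid'")
        if self.batch_norm:
            raise NotImplementedError("batch_norm is reserved; default is off")


@dataclasses.dataclass
class TrainingConfig:
    batch_size: int = 6
    epochs: int = 20
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# valid-convolution size arithmetic


def valid_unet_trace(input_size: int, depth: int) -> list[int]:
    """Layer-by-layer spatial sizes of a valid-convolution U-Net.

    Raises ValueError when the size chain is infeasible (a feature map
    would be odd before pooling or vanish).
    """
    sizes = [input_size]
    s = input_size
    for _ in range(depth):
        s -= 4  # two 3x3 valid convolutions
        if s <= 0:
            raise ValueError(f"feature map vanishes (input {input_size}, depth {depth})")
        sizes.append(s)
        if s % 2:
            raise ValueError(
                f"odd feature map {s} before pooling (input {input_size})"
            )
        s //= 2
        sizes.append(s)
    s -= 4  # bottleneck convolutions
    if s <= 0:
        raise ValueError(f"feature map vanishes (input {input_size}, depth {depth})")
    sizes.append(s)
    for _ in range(depth):
        s *= 2
        sizes.append(s)
        s -= 4  # two 3x3 valid convolutions after concatenation
        if s <= 0:
            raise ValueError(f"feature map vanishes (input {input_size}, depth {depth})")
        sizes.append(s)
    return sizes


def valid_total_loss(depth: int) -> int:
    """Total input-minus-output spatial loss of a valid U-Net, found by
    brute-force tracing the smallest feasible input."""
    for size in range(8, 1 << 16):
        try:
            out = valid_unet_trace(size, depth)[-1]
        except ValueError:
            continue
        return size - out
    raise ValueError(f"no feasible valid-U-Net input for depth {depth}")


def padded_input_size(output_size: int, depth: int) -> int:
    """Padded input required for a valid U-Net to return ``output_size``
    by loss-only arithmetic (e.g. 512 -> 696 at depth 4)."""
    return output_size + valid_total_loss(depth)


def feasible_padded_input_size(output_size: int, depth: int) -> int:
    """Smallest input >= the loss-only pad that also satisfies the
    even-halving constraint at every pooling step; its traced output
    (>= output_size) is center-cropped back to output_size."""
    size = padded_input_size(output_size, depth)
    while True:
        try:
            if valid_unet_trace(size, depth)[-1] >= output_size:
                return size
        except ValueError:
            pass
        size += 1


# ---------------------------------------------------------------------------
# model


def _center_crop(x: np.ndarray, h: int, w: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Center-crop the spatial axes of an (N, H, W, C) array."""
    dh = (x.shape[1] - h) // 2
    dw = (x.shape[2] - w) // 2
    return x[:, dh : dh + h, dw : dw + w], (dh, dw)


class UNet:
    """Encoder-decoder network; weights are float32 NumPy arrays."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 100)))
        pad = 1 if config.padding_mode == "same" else 0
        f, d = config.base_filters, config.depth
        self.enc: list[list] = []
        cin = config.input_channels
        for i in range(d):
            cout = f * 2**i
            self.enc.append([
                nn.Conv2D(cin, cout, rng, pad=pad), nn.ReLU(),
                nn.Conv2D(cout, cout, rng, pad=pad), nn.ReLU(),
            ])
            cin = cout
        self.pools = [nn.MaxPool2() for _ in range(d)]
        cb = f * 2**d
        self.bottleneck = [
            nn.Conv2D(cin, cb, rng, pad=pad), nn.ReLU(),
            nn.Conv2D(cb, cb, rng, pad=pad), nn.ReLU(),
        ]
        self.ups: list = []
        self.dec: list[list] = []
        cin = cb
        for i in reversed(range(d)):
            cout = f * 2**i
            self.ups.append(nn.UpConv2(cin, cout, rng))
            self.dec.append([
                nn.Conv2D(2 * cout, cout, rng, pad=pad), nn.ReLU(),
                nn.Conv2D(cout, cout, rng, pad=pad), nn.ReLU(),
            ])
            cin = cout
        self.head = nn.Conv2D(cin, config.output_classes, rng, ksize=1, pad=0)
        self._skip_crops: list = []

    # -- plumbing

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        for up, blk in zip(self.ups, self.dec):
            out.append(up)
            out.extend(blk)
        out.append(self.head)
        return out

    def param_layers(self):
        return [l for l in self.layers() if l.params()]

    def weight_arrays(self) -> list[np.ndarray]:
        return [w for layer in self.param_layers() for (w, _) in layer.params()]

    def min_input_size(self) -> int:
        return 2**self.config.depth

    def _check_size(self, h: int, w: int) -> None:
        m = self.min_input_size()
        if h % m or w % m or h < m or w < m:
            raise ValueError(
                f"input {h}x{w} incompatible with depth {self.config.depth}: "
                f"spatial dims must be multiples of {m} (minimum {m})"
            )

    # -- forward / backward

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N, 3, H, W) -> logits (N, H, W, 5).

        Layers run channels-last internally; the input is transposed
        once on entry.
        """
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} input channels, got {x.shape[1]}"
            )
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1), dtype=np.float32)
        h, w = x.shape[1], x.shape[2]
        if self.config.padding_mode == "paper_valid":
            ph = feasible_padded_input_size(h, self.config.depth)
            pw = feasible_padded_input_size(w, self.config.depth)
            top, left = (ph - h) // 2, (pw - w) // 2
            x = np.pad(
                x,
                ((0, 0), (top, ph - h - top), (left, pw - w - left), (0, 0)),
            )
            self._out_size = (h, w)
        else:
            self._check_size(h, w)
            self._out_size = None
        skips = []
        self._skip_crops = []
        for blk, pool in zip(self.enc, self.pools):
            for layer in blk:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            if skip.shape[1:3] != x.shape[1:3]:
                skip_c, off = _center_crop(skip, x.shape[1], x.shape[2])
            else:
                skip_c, off = skip, (0, 0)
            self._skip_crops.append((skip.shape, off))
            x = np.concatenate([skip_c, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, train)
        x = self.head.forward(x, train)
        if self._out_size is not None:
            x, self._final_off = _center_crop(x, *self._out_size)
            x = np.ascontiguousarray(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(logits) of shape (N, H, W, 5)."""
        dy = dlogits
        if self._out_size is not None:
            # undo the final center crop; the 1x1 head preserves spatial
            # size, so its cached input dims give the pre-crop extent
            hh, ww = self.head._cache[1][1], self.head._cache[1][2]
            big = np.zeros((dy.shape[0], hh, ww, dy.shape[3]), dtype=dy.dtype)
            dh, dw = self._final_off
            big[:, dh : dh + dy.shape[1], dw : dw + dy.shape[2]] = dy
            dy = big
        dy = self.head.backward(dy)
        skip_grads = []
        for i in range(len(self.dec) - 1, -1, -1):
            blk = self.dec[i]
            for layer in reversed(blk):
                dy = layer.backward(dy)
            n_skip = dy.shape[-1] // 2
            dskip_c, dy = dy[..., :n_skip], dy[..., n_skip:]
            skip_shape, off = self._skip_crops[i]
            if dskip_c.shape[1:3] != skip_shape[1:3]:
                full = np.zeros(
                    (dskip_c.shape[0], skip_shape[1], skip_shape[2], dskip_c.shape[3]),
                    dtype=dskip_c.dtype,
                )
                full[:, off[0] : off[0] + dskip_c.shape[1],
                     off[1] : off[1] + dskip_c.shape[2]] = dskip_c
                dskip_c = full
            skip_grads.append(np.ascontiguousarray(dskip_c))
            dy = self.ups[i].backward(np.ascontiguousarray(dy))
        for layer in reversed(self.bottleneck):
            dy = layer.backward(dy)
        # skip_grads were appended shallowest-first, matching enc order
        for i in range(len(self.enc) - 1, -1, -1):
            dy = self.pools[i].backward(dy)
            dy = dy + skip_grads[i]
            for layer in reversed(self.enc[i]):
                dy = layer.backward(dy)


def build_unet(config: UNetConfig) -> UNet:
    """Instantiate the network with seeded weight initialization."""
    return UNet(config)


# ---------------------------------------------------------------------------
# data handling


def augment_lr(images: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Offline left-right reflection augmentation.

    ``images`` (S, 3, H, W) and ``labels`` (S, H, W) are doubled: the
    originals are retained unchanged and each added sample is the
    column-axis mirror of image and label jointly.
    """
    if images.shape[0] == 0:
        raise ValueError("augment_lr requires a nonempty dataset")
    if images.shape[0] != labels.shape[0]:
        raise ValueError("images and labels disagree in sample count")
    return (
        np.concatenate([images, images[:, :, :, ::-1]], axis=0),
        np.concatenate([labels, labels[:, :, ::-1]], axis=0),
    )


@dataclasses.dataclass
class TrainedSegmenter:
    """A fitted network plus its configuration and training history."""

    model: UNet
    unet_config: UNetConfig
    training_config: TrainingConfig
    history: list[dict] = dataclasses.field(default_factory=list)


def train(
    model: UNet,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainingConfig,
) -> TrainedSegmenter:
    """Fit the network on per-slice samples.

    ``images`` must already be normalized per slice to [0, 1];
    ``labels`` carry codes 0 (excluded) to 5. The loss is categorical
    cross-entropy over non-excluded voxels only. Slice order is
    shuffled each epoch with the training seed; per-epoch mean loss and
    per-class training Dice are recorded in the history.
    """
    if images.min() < -1e-6 or images.max() > 1 + 1e-6:
        raise ValueError("training images must be per-slice normalized to [0, 1]")
    if config.augment:
        images, labels = augment_lr(images, labels)
    images = np.ascontiguousarray(images, dtype=np.float32)
    labels = np.ascontiguousarray(labels)
    n = images.shape[0]
    k = model.config.output_classes
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 200)))
    opt = nn.Adam(
        model.param_layers(), lr=config.learning_rate,
        beta1=config.adam_beta1, beta2=config.adam_beta2,
    )
    history: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses: list[float] = []
        inter = np.zeros(k)
        n_lab = np.zeros(k)
        n_pred = np.zeros(k)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = images[idx]
            yb = labels[idx]
            mask = yb != EXCLUDED
            if not mask.any():
                warnings.warn("skipping batch with all voxels excluded")
                continue
            target = np.maximum(yb.astype(np.int64) - 1, 0)
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.masked_cross_entropy(logits, target, mask)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            pred = logits.argmax(axis=-1)
            for c in range(k):
                pl = (target == c) & mask
                pp = (pred == c) & mask
                inter[c] += np.count_nonzero(pl & pp)
                n_lab[c] += np.count_nonzero(pl)
                n_pred[c] += np.count_nonzero(pp)
        denom = n_lab + n_pred
        dsc = np.where(denom > 0, 2 * inter / np.maximum(denom, 1), np.nan)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)) if losses else float("nan"),
            "train_dsc": dsc.tolist(),
        }
        history.append(entry)
        logger.info("epoch %d: loss %.4f", epoch, entry["loss"])
    return TrainedSegmenter(model, model.config, config, history)


# ---------------------------------------------------------------------------
# inference


def predict_proba(
    segmenter: TrainedSegmenter | UNet,
    volume: np.ndarray,
    batch_size: int = 8,
) -> np.ndarray:
    """Slice-wise inference over a multiparametric volume.

    ``volume`` is a raw stacked array (S, 3, H, W); per-slice
    normalization is applied internally, identically to training.
    Returns per-voxel class scores (S, H, W, 5) summing to 1.
    """
    model = segmenter.model if isinstance(segmenter, TrainedSegmenter) else segmenter
    if volume.ndim != 4 or volume.shape[1] != 3:
        raise ValueError(
            f"expected (slices, 3, rows, cols) input, got shape {volume.shape}"
        )
    x = np.stack(
        [normalize_slices_array(volume[:, c]) for c in range(3)], axis=1
    )
    out = np.empty(
        (x.shape[0], x.shape[2], x.shape[3], model.config.output_classes),
        dtype=np.float32,
    )
    t0 = time.perf_counter()
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        logits = model.forward(xb, train=False)
        out[start : start + xb.shape[0]] = nn.softmax(logits, axis=-1)
    elapsed = time.perf_counter() - t0
    logger.info(
        "inference: %d slices in %.2f s (%.1f ms/slice)",
        x.shape[0], elapsed, 1e3 * elapsed / max(1, x.shape[0]),
    )
    return out


def assign_labels(proba: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hard labels from class scores: masked voxels take the argmax
    class (ties break to the lowest class code); voxels outside the
    intracranial mask get the excluded code. No probability threshold
    is applied. ``proba`` is channels-last (S, H, W, 5)."""
    if proba.shape[:3] != mask.shape:
        raise ValueError(
            f"probability grid {proba.shape} does not match mask grid {mask.shape}"
        )
    hard = (proba.argmax(axis=-1) + 1).astype(np.uint8)
    hard[~mask] = EXCLUDED
    return hard


# ---------------------------------------------------------------------------
# serialization


def save_segmenter(segmenter: TrainedSegmenter, path) -> Path:
    """Serialize a trained segmenter to a single portable .npz file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "vascmap-segmenter-v1",
        "unet_config": dataclasses.asdict(segmenter.unet_config),
        "training_config": dataclasses.asdict(segmenter.training_config),
        "history": segmenter.history,
    }
    arrays = {
        f"w{i:03d}": w for i, w in enumerate(segmenter.model.weight_arrays())
    }
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path


def load_segmenter(path) -> TrainedSegmenter:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "vascmap-segmenter-v1":
            raise ValueError(f"unrecognized segmenter file format in {path}")
        ucfg = UNetConfig(**meta["unet_config"])
        tcfg = TrainingConfig(**meta["training_config"])
        model = UNet(ucfg)
        weights = model.weight_arrays()
        for i, w in enumerate(weights):
            arr = data[f"w{i:03d}"]
            if arr.shape != w.shape:
                raise ValueError("weight shape mismatch on load")
            w[...] = arr
    return TrainedSegmenter(model, ucfg, tcfg, meta["history"])
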