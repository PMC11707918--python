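"""VGG16-style deep features with an optimizable multiplicative gain vector.

Phase 1 of the pipeline: images pass through a fixed convolutional
backbone (3x3 convolutions, 2x2 max pooling, a fully-connected feature
layer), and the exported feature columns are partitioned into ``G``
contiguous groups, each scaled by a gain in ``[0, 1]``.  The gain vector
— ``G = 6`` by default, matching the optimizer's chromosome length — is
tuned by the metaheuristic to minimize ``1/accuracy`` of a fast proxy
classifier (nearest centroid) on a held-out stratified fold.

Two backbone profiles exist: the full 13-conv VGG16 layout with a
4096-wide feature layer (input 224x224), and ``tiny_mode`` — two small
convolution blocks and a 64-wide feature layer for 64x64 inputs — used
throughout the test suite.  Weights are seeded-random by default;
externally trained weights can be supplied as an ``.npz`` file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage.transform import resize

from bcdnet import metrics
from bcdnet.optimizers import OptimizeResult, OptimizerConfig, SearchSpace, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "ImageBatch",
    "BackboneConfig",
    "FeatureMatrix",
    "FeatureGainVector",
    "VGGBackbone",
    "preprocess_images",
    "extract_deep_features",
    "apply_feature_gains",
    "phase1_objective",
    "optimize_feature_gains",
    "save_features",
    "load_features",
]

#: VGG16 convolution widths per block (13 conv layers)
VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
#: desk-scale backbone: two small blocks
TINY_BLOCKS = ((8,), (16,))


@dataclass
class ImageBatch:
    """Preprocessed images ``(n, H, W, 3)`` in [0,1] with labels and ids."""

    pixels: np.ndarray
    labels: np.ndarray
    source_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class BackboneConfig:
    conv_kernel: int = 3
    pool_size: int = 2
    fc_width: int = 4096
    head_width: int = 1000
    pretrained: bool = False
    weights_path: str | None = None
    feature_layer: str = "fc1"
    tiny_mode: bool = False
    input_size: int = 224
    pool_mode: str | None = None       # None: max (full) / avg (tiny)
    fc_activation: str | None = None   # None: relu (full) / linear (tiny)
    seed: int = 0

    @property
    def blocks(self) -> tuple[tuple[int, ...], ...]:
        return TINY_BLOCKS if self.tiny_mode else VGG16_BLOCKS

    @property
    def effective_fc_width(self) -> int:
        return 64 if self.tiny_mode and self.fc_width == 4096 else self.fc_width

    @property
    def effective_input_size(self) -> int:
        return 64 if self.tiny_mode and self.input_size == 224 else self.input_size

    # With untrained (seeded-random) filters, max pooling amplifies
    # speckle noise and a ReLU on the random projection layer discards
    # half of it; the tiny profile therefore averages and stays linear.
    @property
    def effective_pool_mode(self) -> str:
        if self.pool_mode is not None:
            return self.pool_mode
        return "avg" if self.tiny_mode else "max"

    @property
    def effective_fc_activation(self) -> str:
        if self.fc_activation is not None:
            return self.fc_activation
        return "linear" if self.tiny_mode else "relu"


@dataclass
class FeatureMatrix:
    """Deep features, one row per image."""

    values: np.ndarray   # (n, F)
    labels: np.ndarray

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureGainVector:
    """Per-group multiplicative gains in [0,1] over contiguous column blocks."""

    gains: np.ndarray
    n_features: int

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.ndim != 1 or self.gains.size < 1:
            raise ValueError("gains must be a non-empty 1-D vector")
        if np.any(self.gains < 0) or np.any(self.gains > 1):
            logger.warning("gains outside [0,1] clipped")
            self.gains = np.clip(self.gains, 0.0, 1.0)

    @property
    def grouping(self) -> list[np.ndarray]:
        """Contiguous equal-width partition of the feature columns."""
        return np.array_split(np.arange(self.n_features), self.gains.size)

    def column_gains(self) -> np.ndarray:
        out = np.empty(self.n_features)
        for g, idx in zip(self.gains, self.grouping):
            out[idx] = g
        return out


def preprocess_images(
    inputs: Sequence,
    target_size: int = 224,
    labels: Sequence[int] | None = None,
) -> ImageBatch:
    """Resize to ``target_size`` square (bilinear), scale to [0,1],
    replicate grayscale into 3 channels.

    ``inputs`` may be file paths or 2-D/3-D arrays.  Unreadable files
    are skipped with a logged per-file error; an empty input is a usage
    error.
    """
    if len(inputs) == 0:
        raise ValueError("no input images")
    pixels, ids, kept = [], [], []
    for i, item in enumerate(inputs):
        if isinstance(item, (str, Path)):
            try:
                with Image.open(item) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
            except Exception as exc:
                logger.error("cannot read image %s: %s", item, exc)
                continue
            ids.append(str(item))
        else:
            arr = np.asarray(item, dtype=float)
            if arr.max() > 1.0:
                arr = arr / 255.0
            if arr.ndim == 2:
                arr = np.repeat(arr[:, :, None], 3, axis=2)
            ids.append(f"array_{i}")
        if arr.shape[:2] != (target_size, target_size):
            arr = resize(
                arr, (target_size, target_size), order=1, mode="reflect",
                anti_aliasing=False, preserve_range=True,
            )
        pixels.append(np.clip(arr, 0.0, 1.0))
        kept.append(i)
    if not pixels:
        raise ValueError("no readable images")
    label_arr = (
        np.asarray(labels)[kept] if labels is not None else np.zeros(len(pixels), dtype=int)
    )
    return ImageBatch(np.stack(pixels), label_arr, ids)


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 (or kxk) same-padded convolution: x (n,H,W,Cin), w (k,k,Cin,Cout)."""
    k = w.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, H, W, c_in = x.shape
    cols = np.empty((n, H, W, k * k * c_in))
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[..., idx * c_in : (idx + 1) * c_in] = xp[:, di : di + H, dj : dj + W, :]
            idx += 1
    return cols @ w.reshape(-1, w.shape[-1]) + b


def _pool2d(x: np.ndarray, p: int, mode: str = "max") -> np.ndarray:
    n, H, W, c = x.shape
    Ho, Wo = H // p, W // p
    tiles = x[:, : Ho * p, : Wo * p, :].reshape(n, Ho, p, Wo, p, c)
    return tiles.max(axis=(2, 4)) if mode == "max" else tiles.mean(axis=(2, 4))


class VGGBackbone:
    """Fixed (non-trained) convolutional feature extractor.

    Stacked 3x3 same-padded convolutions with ReLU, 2x2 max pooling
    after each block, then a fully-connected feature layer (``fc1``)
    whose activations are exported.  Weights are drawn once from the
    config seed, or loaded from ``weights_path`` when ``pretrained``.
    """

    def __init__(self, config: BackboneConfig):
        self.config = config
        size = config.effective_input_size
        rng = np.random.default_rng(config.seed)
        self.conv_params: list[tuple[np.ndarray, np.ndarray]] = []
        c_in = 3
        k = config.conv_kernel
        for block in config.blocks:
            for c_out in block:
                fan_in = k * k * c_in
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
                self.conv_params.append((w, np.zeros(c_out)))
                c_in = c_out
            size //= config.pool_size
        if size < 1:
            raise ValueError("input too small for this backbone depth")
        flat = size * size * c_in
        self.fc1_w = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, config.effective_fc_width))
        self.fc1_b = np.zeros(config.effective_fc_width)
        if config.pretrained:
            self._load_weights(config.weights_path)

    def _load_weights(self, path: str | None) -> None:
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                "pretrained=True requires an .npz weights file via weights_path "
                "(keys conv0_w, conv0_b, ..., fc1_w, fc1_b)"
            )
        with np.load(path) as data:
            for i in range(len(self.conv_params)):
                self.conv_params[i] = (data[f"conv{i}_w"], data[f"conv{i}_b"])
            self.fc1_w, self.fc1_b = data["fc1_w"], data["fc1_b"]

    @property
    def feature_width(self) -> int:
        return self.fc1_w.shape[1]

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for w, b in self.conv_params:
            h.update(w.tobytes()); h.update(b.tobytes())
        h.update(self.fc1_w.tobytes()); h.update(self.fc1_b.tobytes())
        return h.hexdigest()[:16]

    def forward(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels
        layer = 0
        for block in self.config.blocks:
            for _ in block:
                w, b = self.conv_params[layer]
                x = np.maximum(_conv2d_same(x, w, b), 0.0)
                layer += 1
            x = _pool2d(x, self.config.pool_size, self.config.effective_pool_mode)
        flat = x.reshape(x.shape[0], -1)
        out = flat @ self.fc1_w + self.fc1_b
        if self.config.effective_fc_activation == "relu":
            out = np.maximum(out, 0.0)
        return out


def extract_deep_features(
    batch: ImageBatch, config: BackboneConfig | None = None,
    backbone: VGGBackbone | None = None,
) -> FeatureMatrix:
    """Exported feature-layer activations, one row per image."""
    if backbone is None:
        backbone = VGGBackbone(config or BackboneConfig())
    expected = backbone.config.effective_input_size
    if batch.pixels.shape[1] != expected or batch.pixels.shape[2] != expected:
        raise ValueError(
            f"batch size {batch.pixels.shape[1:3]} does not match backbone "
            f"input {expected}x{expected}"
        )
    values = backbone.forward(batch.pixels)
    if not np.all(np.isfinite(values)):
        raise RuntimeError("non-finite activations in feature extraction")
    return FeatureMatrix(values, np.asarray(batch.labels))


def apply_feature_gains(
    features: FeatureMatrix, gains: FeatureGainVector
) -> FeatureMatrix:
    """Scale each feature column by its group's gain."""
    if gains.n_features != features.width:
        raise ValueError(
            f"gain grouping covers {gains.n_features} columns, features have "
            f"{features.width}"
        )
    return FeatureMatrix(features.values * gains.column_gains(), features.labels)


def _stratified_indices(
    labels: np.ndarray, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    tr, va = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        if n_val >= idx.size:
            raise ValueError(f"class {c} too small for an {val_fraction} split")
        va.append(idx[:n_val])
        tr.append(idx[n_val:])
    return np.concatenate(tr), np.concatenate(va)


def _nearest_centroid_accuracy(
    x_train: np.ndarray, y_train: np.ndarray, x_val: np.ndarray, y_val: np.ndarray
) -> float:
    """Closed-form nearest-centroid proxy.

    Ties (including the fully degenerate all-zero-gain case, where every
    centroid coincides) resolve to the lowest class id, so the objective
    stays finite for any gain vector.
    """
    classes = np.unique(y_train)
    centroids = np.stack([x_train[y_train == c].mean(axis=0) for c in classes])
    d2 = ((x_val[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[np.argmin(d2, axis=1)]
    return metrics.multiclass_accuracy(y_val, pred)


def phase1_objective(
    gains: np.ndarray,
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    split_seed: int = 0,
    val_fraction: float = 0.2,
    n_splits: int = 5,
) -> float:
    """Gain-search objective ``1/accuracy`` of the nearest-centroid proxy.

    Gains are applied to the grouped feature columns and the proxy's
    accuracy is averaged over ``n_splits`` seeded stratified 80/20
    splits (the proxy is closed-form, so repeated splits are cheap and
    keep a lucky single fold from rewarding degenerate gain vectors);
    the mean accuracy feeds the reciprocal, clamped at 1e-6.  Always
    >= 1.
    """
    labels = np.asarray(labels if labels is not None else features.labels)
    gv = FeatureGainVector(np.asarray(gains, dtype=float), features.width)
    gained = apply_feature_gains(features, gv)
    accs = []
    for k in range(n_splits):
        tr, va = _stratified_indices(labels, val_fraction, split_seed + k)
        if np.unique(labels[va]).size < 2:
            tr, va = _stratified_indices(labels, val_fraction, split_seed + n_splits + k)
            if np.unique(labels[va]).size < 2:
                raise RuntimeError("validation fold collapsed to a single class")
        accs.append(
            _nearest_centroid_accuracy(
                gained.values[tr], labels[tr], gained.values[va], labels[va]
            )
        )
    return 1.0 / max(float(np.mean(accs)), metrics.EPSILON)


def optimize_feature_gains(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    optimizer_config: OptimizerConfig | None = None,
    n_groups: int = 6,
    method: str = "rpaosm-eso",
) -> tuple[FeatureGainVector, OptimizeResult]:
    """Tune the gain vector with the metaheuristic over ``[0,1]^G``."""
    optimizer_config = optimizer_config or OptimizerConfig()
    labels = np.asarray(labels if labels is not None else features.labels)
    space = SearchSpace(lower=np.zeros(n_groups), upper=np.ones(n_groups))

    def objective(position: np.ndarray) -> float:
        return phase1_objective(
            position, features, labels, split_seed=optimizer_config.seed
        )

    result = optimize(objective, space, optimizer_config, method=method)
    return FeatureGainVector(result.best_position, features.width), result


def save_features(
    features: FeatureMatrix, path: str | Path, backbone: VGGBackbone | None = None
) -> None:
    """Portable cache: .npy array plus a JSON sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), features.values)
    np.save(path.with_name(path.stem + "_labels.npy"), features.labels)
    sidecar = {"feature_width": features.width, "n": int(features.values.shape[0])}
    if backbone is not None:
        sidecar.update(
            layer=backbone.config.feature_layer,
            seed=backbone.config.seed,
            backbone_hash=backbone.weights_hash(),
        )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    labels = np.load(path.with_name(path.stem + "_labels.npy"))
    return FeatureMatrix(values, labels)
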