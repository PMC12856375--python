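"""The split convolutional-extractor / linear-head fusion network.

Architecture (multimodal mode)::

    images (B, 4, D, H, W)
      -> Conv(4->8, k6) ReLU MaxPool(3, s2)
      -> Conv(8->16, k3, pad 1) ReLU MaxPool
      -> Conv(16->24, k3, pad 1) ReLU MaxPool
      -> Conv(24->24, k3, pad 1) ReLU MaxPool
      -> Conv(24->32, k3, pad 1) ReLU MaxPool
      -> Conv(32->64, k3, pad 1) ReLU GlobalMaxPool  -> features (B, 64)
    concat(features, clinical (B, 6))                -> (B, 70)
      -> Linear(70->32) BatchNorm ReLU Dropout(0.2)
      -> Linear(32->1)                               -> logit -> sigmoid -> P(AD)

The global max pool guarantees a 64-value feature vector for any input grid
of spatial size >= 6 per axis, so the head input width is exactly 70
(multimodal) or 64 (unimodal) regardless of grid size. In unimodal mode the
clinical vector is ignored and the first linear layer is 64 wide; the two
variants share an identical extractor layout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from dmnfuse import nn
from dmnfuse.cohort_io import InputBundle
from dmnfuse.errors import ShapeError

MULTIMODAL = "multimodal"
UNIMODAL = "unimodal"

#: Smallest spatial extent the first (unpadded, kernel-6) conv accepts.
MIN_INPUT_SIZE = 6


@dataclass(frozen=True)
class ModelConfig:
    """Layer specification with a multimodal/unimodal switch."""

    mode: str = MULTIMODAL
    in_channels: int = 4
    clinical_dim: int = 6
    conv_channels: tuple[int, ...] = (8, 16, 24, 24, 32, 64)
    conv_kernels: tuple[int, ...] = (6, 3, 3, 3, 3, 3)
    pool_kernel: int = 3
    pool_stride: int = 2
    hidden_dim: int = 32
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in (MULTIMODAL, UNIMODAL):
            raise ValueError(f"mode must be {MULTIMODAL!r} or {UNIMODAL!r}")
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ValueError("conv_channels and conv_kernels must align")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def feature_dim(self) -> int:
        return self.conv_channels[-1]

    @property
    def head_input_dim(self) -> int:
        extra = self.clinical_dim if self.mode == MULTIMODAL else 0
        return self.feature_dim + extra

    def as_mode(self, mode: str) -> "ModelConfig":
        return replace(self, mode=mode)


def _build_extractor(config: ModelConfig, rng: np.random.Generator,
                     dtype) -> nn.Sequential:
    layers: list[nn.Layer] = []
    cin = config.in_channels
    last = len(config.conv_channels) - 1
    for i, (cout, k) in enumerate(zip(config.conv_channels, config.conv_kernels)):
        pad = 0 if i == 0 else (k - 1) // 2  # conv1 unpadded, rest keep size
        layers.append(nn.Conv3d(cin, cout, k, pad=pad, rng=rng, dtype=dtype,
                                need_input_grad=i > 0))
        layers.append(nn.ReLU())
        if i < last:
            layers.append(nn.MaxPool3d(config.pool_kernel, config.pool_stride))
        cin = cout
    layers.append(nn.GlobalMaxPool3d())
    return nn.Sequential(*layers)


def _build_head(config: ModelConfig, rng: np.random.Generator,
                dtype) -> nn.Sequential:
    return nn.Sequential(
        nn.Linear(config.head_input_dim, config.hidden_dim, rng=rng, dtype=dtype),
        nn.BatchNorm1d(config.hidden_dim, dtype=dtype),
        nn.ReLU(),
        nn.Dropout(config.dropout),
        nn.Linear(config.hidden_dim, 1, rng=rng, dtype=dtype),
    )


class FusionModel:
    """Extractor + head, split so features can be inspected and perturbed."""

    def __init__(self, config: ModelConfig, extractor: nn.Sequential,
                 head: nn.Sequential):
        self.config = config
        self.extractor = extractor
        self.head = head

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        return self.extractor.parameters() + self.head.parameters()

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.head.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    # -- forward / backward ------------------------------------------------

    def _check_images(self, images: np.ndarray) -> None:
        if images.ndim != 5 or images.shape[1] != self.config.in_channels:
            raise ShapeError(
                f"expected images of shape (B, {self.config.in_channels}, D, H, W), "
                f"got {images.shape}")
        if min(images.shape[2:]) < MIN_INPUT_SIZE:
            raise ShapeError(
                f"spatial size {images.shape[2:]} below the minimum supported "
                f"size of {MIN_INPUT_SIZE} per axis")

    def extract_features(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (B, C, D, H, W) images to (B, feature_dim) features."""
        self._check_images(images)
        return self.extractor.forward(images, train=train)

    def forward_logit(self, images: np.ndarray, clinical: np.ndarray | None,
                      train: bool = False) -> np.ndarray:
        feats = self.extract_features(images, train=train)
        if self.config.mode == MULTIMODAL:
            clinical = np.asarray(clinical, dtype=feats.dtype)
            if clinical.ndim != 2 or clinical.shape[1] != self.config.clinical_dim:
                raise ShapeError(
                    f"expected clinical of shape (B, {self.config.clinical_dim}), "
                    f"got {None if clinical is None else clinical.shape}")
            head_in = np.concatenate([feats, clinical], axis=1)
        else:
            head_in = feats
        return self.head.forward(head_in, train=train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logit), shape (B,)."""
        dhead = self.head.backward(dlogit[:, None])
        dfeat = dhead[:, :self.config.feature_dim]  # clinical gradient is discarded
        self.extractor.backward(dfeat)

    # -- inference ---------------------------------------------------------

    def predict_proba(self, images: np.ndarray,
                      clinical: np.ndarray | None = None) -> np.ndarray | float:
        """P(AD) in evaluation mode; accepts a single sample or a batch."""
        single = images.ndim == 4
        if single:
            images = images[None]
            if clinical is not None:
                clinical = np.asarray(clinical)[None]
        logit = self.forward_logit(images, clinical, train=False)
        prob = nn.sigmoid(logit)
        return float(prob[0]) if single else prob

    def predict_proba_bundle(self, bundle: InputBundle) -> float:
        return self.predict_proba(bundle.image_stack, bundle.clinical)


def build_model(config: ModelConfig, seed: int | np.random.SeedSequence = 0,
                dtype=np.float32) -> FusionModel:
    """Instantiate a model with seeded fan-in ('He') weight initialization."""
    rng = np.random.default_rng(seed)
    return FusionModel(config, _build_extractor(config, rng, dtype),
                       _build_head(config, rng, dtype))


def _state_arrays(model: FusionModel) -> list[np.ndarray]:
    """All weights plus batch-norm running statistics, in layer order."""
    arrays: list[np.ndarray] = []
    for layer in model.extractor.layers + model.head.layers:
        arrays.extend(p.data for p in layer.parameters())
        if isinstance(layer, nn.BatchNorm1d):
            arrays.extend([layer.running_mean, layer.running_var])
    return arrays


def save_model(model: FusionModel, path: str | Path) -> Path:
    """Checkpoint a model to one ``.npz`` file, with the configuration
    serialized alongside as JSON (``<path>.json``)."""
    path = Path(path)
    np.savez(path, **{f"a{i}": a for i, a in enumerate(_state_arrays(model))})
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends it
    config_path = path.with_suffix(".json")
    config_path.write_text(json.dumps(dataclasses.asdict(model.config)) + "\n")
    return path


def load_model(path: str | Path) -> FusionModel:
    """Rebuild a model from :func:`save_model` output."""
    path = Path(path)
    doc = json.loads(path.with_suffix(".json").read_text())
    for key in ("conv_channels", "conv_kernels"):
        doc[key] = tuple(doc[key])
    model = build_model(ModelConfig(**doc), seed=0)
    with np.load(path) as blob:
        stored = [blob[f"a{i}"] for i in range(len(blob.files))]
    targets = _state_arrays(model)
    if len(stored) != len(targets):
        raise ShapeError(f"checkpoint has {len(stored)} arrays, "
                         f"model needs {len(targets)}")
    for dst, src in zip(targets, stored):
        dst[...] = src
    return model


def forward(bundle: InputBundle, model: FusionModel) -> float:
    """Evaluate one participant bundle; returns P(AD) strictly inside (0, 1)."""
    return model.predict_proba_bundle(bundle)


def bce_loss(probability, label, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, probabilities clamped away from {0, 1}."""
    return float(np.mean(nn.binary_cross_entropy(probability, label, eps=eps)))
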