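"""The three convolutional feature extractors and their fusion.

Three networks see each (median-filtered, resized) patch:

* an AlexNet-style net: five conv layers and two 4096-unit fully connected
  layers with dropout 0.5; the embedding is the FC7 activation,
* a SqueezeNet-style net of fire modules ending in a 1x1 conv and global
  average pooling,
* a capsule network whose embedding concatenates the routed output capsules.

Fusion is concatenation of the three embeddings in fixed order with recorded
span offsets.  Each extractor is trained on the task through a temporary
softmax head, then frozen for feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .capsule import CapsuleLayerParams
from .labels import N_CLASSES

EXTRACTOR_ORDER = ("alexnet_style", "squeezenet_style", "capsnet")


@dataclass
class ExtractorSpec:
    name: str
    input_side: int = 64
    embedding_dim: int = 0  # filled in by the builders
    trainable: bool = True

    def validate(self) -> None:
        if self.name not in EXTRACTOR_ORDER:
            raise ValueError(f"name must be one of {EXTRACTOR_ORDER}, got {self.name!r}")
        if self.input_side < 16:
            raise ValueError(f"input_side must be >= 16, got {self.input_side}")


@dataclass
class FusedFeatureVector:
    """Concatenated embeddings with per-extractor span offsets."""

    values: np.ndarray
    provenance: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused feature vector contains non-finite entries")

    def span(self, name: str) -> np.ndarray:
        lo, hi = self.provenance[name]
        return self.values[lo:hi]


class FeatureExtractor:
    """A trained-then-frozen embedding network with a temporary softmax head."""

    def __init__(self, name: str, input_side: int, body: nn.Sequential, embedding_dim: int,
                 head: nn.Dense) -> None:
        self.name = name
        self.input_side = input_side
        self.body = body
        self.embedding_dim = embedding_dim
        self.head = head

    def prepare(self, img: np.ndarray) -> np.ndarray:
        """Resize an HxWx3 uint8 patch to the input side and scale to [-0.5, 0.5]."""
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 RGB patch, got shape {img.shape}")
        side = self.input_side
        if img.shape[:2] != (side, side):
            img = resize(img, (side, side), order=1, preserve_range=True, anti_aliasing=True)
        return (img.astype(np.float32) / 255.0) - 0.5

    def embed(self, images: np.ndarray) -> np.ndarray:
        """Forward a prepared (B, side, side, 3) batch in eval mode."""
        return np.asarray(self.body.forward(images, train=False), dtype=np.float32)

    def fit(self, images: np.ndarray, labels: np.ndarray, *, epochs: int = 3,
            batch_size: int = 16, lr: float = 1e-3, seed: int = 0) -> list[float]:
        """Train body + temporary softmax head with Adam / cross-entropy."""
        return nn.fit_classifier(self.body, self.head, images, labels,
                                 epochs=epochs, batch_size=batch_size, lr=lr, seed=seed)

    # introspection helpers
    def conv_layers(self) -> list[nn.Conv2D]:
        return self.body.find(nn.Conv2D)

    def dense_layers(self) -> list[nn.Dense]:
        return self.body.find(nn.Dense)

    def dropout_layers(self) -> list[nn.Dropout]:
        return self.body.find(nn.Dropout)


def build_alexnet_extractor(
    spec: ExtractorSpec,
    seed: int = 0,
    conv_channels: tuple[int, int, int, int, int] = (96, 256, 384, 384, 256),
    fc_units: int = 4096,
    dropout: float = 0.5,
    n_classes: int = N_CLASSES,
) -> FeatureExtractor:
    """AlexNet-style extractor at reduced input size.

    Five 3x3 conv layers (conv2 fixed at 256 'same'-padded filters), 2x2
    stride-2 max pooling after conv1, conv2 and conv5, then FC6 and FC7 with
    ``fc_units`` ReLU units and dropout 0.5 each.  The classification head is
    excluded from the embedding, which is the FC7 activation.
    """
    spec.validate()
    if spec.name != "alexnet_style":
        raise ValueError(f"spec.name must be 'alexnet_style', got {spec.name!r}")
    if spec.input_side % 8 != 0:
        raise ValueError("alexnet input_side must be divisible by 8 (three 2x2 pools)")
    rng = np.random.default_rng(seed)
    c1, c2, c3, c4, c5 = conv_channels
    final_side = spec.input_side // 8
    body = nn.Sequential([
        nn.Conv2D(3, c1, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(c1, c2, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(c2, c3, 3, rng), nn.ReLU(),
        nn.Conv2D(c3, c4, 3, rng), nn.ReLU(),
        nn.Conv2D(c4, c5, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Flatten(),
        nn.Dense(final_side * final_side * c5, fc_units, rng), nn.ReLU(), nn.Dropout(dropout),
        nn.Dense(fc_units, fc_units, rng), nn.ReLU(), nn.Dropout(dropout),
    ])
    head = nn.Dense(fc_units, n_classes, rng)
    spec.embedding_dim = fc_units
    return FeatureExtractor(spec.name, spec.input_side, body, fc_units, head)


def build_squeezenet_extractor(
    spec: ExtractorSpec,
    seed: int = 0,
    embedding_dim: int = 64,
    dropout: float = 0.5,
    n_classes: int = N_CLASSES,
) -> FeatureExtractor:
    """SqueezeNet-style extractor: fire modules, dropout, 1x1 conv, global
    average pooling.  The embedding is the pooled vector."""
    spec.validate()
    if spec.name != "squeezenet_style":
        raise ValueError(f"spec.name must be 'squeezenet_style', got {spec.name!r}")
    if spec.input_side % 8 != 0:
        raise ValueError("squeezenet input_side must be divisible by 8")
    rng = np.random.default_rng(seed)
    body = nn.Sequential([
        nn.Conv2D(3, 32, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.FireModule(32, 16, 32, 32, rng),
        nn.FireModule(64, 16, 32, 32, rng), nn.MaxPool2(),
        nn.FireModule(64, 32, 64, 64, rng), nn.MaxPool2(),
        nn.Dropout(dropout),
        nn.Conv2D(128, embedding_dim, 1, rng), nn.ReLU(),
        nn.GlobalAvgPool(),
    ])
    head = nn.Dense(embedding_dim, n_classes, rng)
    spec.embedding_dim = embedding_dim
    return FeatureExtractor(spec.name, spec.input_side, body, embedding_dim, head)


def build_capsnet_extractor(
    spec: ExtractorSpec,
    caps: CapsuleLayerParams | None = None,
    seed: int = 0,
    stem_channels: tuple[int, int] = (16, 32),
    n_classes: int = N_CLASSES,
) -> FeatureExtractor:
    """Capsule-network extractor: conv stem -> primary capsules -> routing.

    Primary capsules are 8-component vectors reshaped from a 32-channel conv
    map (configurable); the embedding concatenates the routed output capsule
    vectors, each of norm < 1 by the squashing bound.
    """
    spec.validate()
    if spec.name != "capsnet":
        raise ValueError(f"spec.name must be 'capsnet', got {spec.name!r}")
    if spec.input_side % 4 != 0:
        raise ValueError("capsnet input_side must be divisible by 4 (two 2x2 pools)")
    rng = np.random.default_rng(seed)
    c1, c2 = stem_channels
    map_side = spec.input_side // 4
    n_scalars = map_side * map_side * c2
    if caps is None:
        caps = CapsuleLayerParams(num_input_capsules=n_scalars // 8, input_dim=8)
    caps.validate()
    if caps.num_input_capsules * caps.input_dim != n_scalars:
        raise ValueError(
            f"capsule config ({caps.num_input_capsules} x {caps.input_dim}) does not "
            f"tile the {n_scalars}-scalar conv map"
        )
    body = nn.Sequential([
        nn.Conv2D(3, c1, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.Conv2D(c1, c2, 3, rng), nn.ReLU(), nn.MaxPool2(),
        nn.CapsuleHead(caps, rng),
    ])
    embedding_dim = caps.num_output_capsules * caps.output_dim
    head = nn.Dense(embedding_dim, n_classes, rng)
    spec.embedding_dim = embedding_dim
    return FeatureExtractor(spec.name, spec.input_side, body, embedding_dim, head)


def extract_fused(img: np.ndarray, extractors: list[FeatureExtractor]) -> FusedFeatureVector:
    """Resize, forward and concatenate one patch through all extractors.

    Embeddings are concatenated in the order the extractors are given
    (canonically alexnet, squeezenet, capsnet) with provenance offsets.
    """
    parts = []
    provenance: dict[str, tuple[int, int]] = {}
    offset = 0
    for ex in extractors:
        x = ex.prepare(img)[None]
        emb = ex.embed(x)[0]
        provenance[ex.name] = (offset, offset + emb.size)
        offset += emb.size
        parts.append(emb)
    return FusedFeatureVector(values=np.concatenate(parts), provenance=provenance)


def extract_features(images: list[np.ndarray], extractors: list[FeatureExtractor],
                     batch_size: int = 32) -> np.ndarray:
    """Fused feature matrix (n_images, total_dim) for a list of patches."""
    prepared = {ex.name: np.stack([ex.prepare(im) for im in images]) for ex in extractors}
    blocks = []
    for ex in extractors:
        chunks = [ex.embed(prepared[ex.name][i : i + batch_size])
                  for i in range(0, len(images), batch_size)]
        blocks.append(np.concatenate(chunks, axis=0))
    return np.concatenate(blocks, axis=1)
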