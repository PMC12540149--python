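"""Synthetic four-class texture patches emulating the laryngeal patch dataset.

The real study data are 1,320 narrow-band laryngoscopy patches of 100x100 px
in four balanced classes.  This module generates procedural RGB textures with
the same layout (class-named directories, CSV manifest, balanced counts) and
class-conditional statistics chosen so a simple classifier can beat chance:

* ``Hbv``  - curvilinear high-contrast dark filaments on a red background,
* ``He``   - smooth, low-variance pink background,
* ``IPCL`` - scattered small dark dots,
* ``Le``   - bright irregular blobs.

Optional salt-and-pepper corruption exercises the median-filter stage.
Textures are clipped to [1, 254] before corruption so every noised pixel is
guaranteed to differ from its clean twin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .labels import ClassLabel, CLASS_NAMES

#: per-class texture parameters: amplitude of the structural component and a
#: frequency/density scalar controlling how much of the patch it covers.
DEFAULT_TEXTURE_PARAMS: dict[str, dict[str, float]] = {
    "Hbv": {"amplitude": 110.0, "frequency": 4.0},
    "He": {"amplitude": 4.0, "frequency": 6.0},
    "IPCL": {"amplitude": 120.0, "frequency": 40.0},
    "Le": {"amplitude": 70.0, "frequency": 10.0},
}

_BASE_COLOR = {
    "Hbv": (190.0, 95.0, 95.0),
    "He": (215.0, 170.0, 170.0),
    "IPCL": (200.0, 135.0, 125.0),
    "Le": (185.0, 130.0, 115.0),
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic patch generator.

    Defaults reproduce the real dataset's composition: 100x100-px patches,
    330 per class (1,320 total), with 5% salt-and-pepper corruption so the
    denoising stage has an observable effect.
    """

    patch_side: int = 100
    per_class_count: int = 330
    noise_fraction: float = 0.05
    seed: int = 0
    texture_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEXTURE_PARAMS.items()}
    )

    def validate(self) -> None:
        if self.patch_side < 16:
            raise ValueError(f"patch_side must be >= 16, got {self.patch_side}")
        if self.per_class_count < 1:
            raise ValueError(f"per_class_count must be >= 1, got {self.per_class_count}")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError(f"noise_fraction must be in [0, 1], got {self.noise_fraction}")


@dataclass
class DatasetManifest:
    """Record set mapping image ids to file paths, class labels and splits."""

    records: pd.DataFrame  # columns: image_id, file_path, class_label, split

    COLUMNS = ("image_id", "file_path", "class_label", "split")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.records["image_id"].duplicated().any():
            raise ValueError("manifest image_ids are not unique")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(self.records[self.records["split"] == split].reset_index(drop=True))

    def class_counts(self) -> pd.Series:
        return self.records["class_label"].value_counts()

    def labels(self) -> np.ndarray:
        return np.array([ClassLabel.from_name(n) for n in self.records["class_label"]], dtype=int)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False, columns=list(self.COLUMNS))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(path))


def _smooth_noise(rng: np.random.Generator, side: int, sigma: float) -> np.ndarray:
    """Band-limited noise field in roughly [-1, 1]."""
    raw = ndimage.gaussian_filter(rng.standard_normal((side, side)), sigma=sigma, mode="wrap")
    scale = max(np.abs(raw).max(), 1e-9)
    return raw / scale


def _texture_field(label: ClassLabel, side: int, params: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Scalar structural field in [-1, 1]; positive values mark the structure."""
    amp = params["amplitude"]
    freq = params["frequency"]
    yy, xx = np.mgrid[0:side, 0:side] / float(side)
    if label is ClassLabel.Hbv:
        # curvilinear filaments: thresholded bent sine waves
        field = np.zeros((side, side))
        for _ in range(3):
            phase, wobble = rng.uniform(0, 2 * math.pi, size=2)
            bend = rng.uniform(0.05, 0.15)
            wave = np.sin(2 * math.pi * freq * (xx + bend * np.sin(2 * math.pi * 2 * yy + wobble)) + phase)
            field = np.maximum(field, (wave > 0.82).astype(float))
        return field
    if label is ClassLabel.He:
        return _smooth_noise(rng, side, sigma=side / 12.0)
    if label is ClassLabel.IPCL:
        field = np.zeros((side, side))
        n_dots = max(4, int(freq * (side / 100.0) ** 2))
        centers = rng.uniform(0, side, size=(n_dots, 2))
        radii = rng.uniform(1.5, 3.5, size=n_dots)
        ygrid, xgrid = np.mgrid[0:side, 0:side]
        for (cy, cx), r in zip(centers, radii):
            field = np.maximum(field, ((ygrid - cy) ** 2 + (xgrid - cx) ** 2 <= r**2).astype(float))
        return field
    if label is ClassLabel.Le:
        blob = _smooth_noise(rng, side, sigma=side / float(params.get("frequency", 10.0)))
        return (blob > 0.35).astype(float)
    raise ValueError(f"unknown class label: {label!r}")


def generate_patch(
    label: ClassLabel, cfg: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    """Generate one ``patch_side x patch_side x 3`` uint8 patch for ``label``.

    The structural texture is drawn first from ``rng``; salt-and-pepper
    corruption (if ``cfg.noise_fraction > 0``) is drawn afterwards from the
    same stream, so two patches generated at the same seed with different
    noise fractions share the underlying texture and differ exactly at the
    corrupted pixels.
    """
    cfg.validate()
    if not isinstance(label, ClassLabel):
        try:
            label = ClassLabel.from_name(str(label))
        except ValueError as exc:
            raise ValueError(f"unknown class label: {label!r}") from exc
    side = cfg.patch_side
    params = cfg.texture_params.get(label.name, DEFAULT_TEXTURE_PARAMS[label.name])
    base = np.array(_BASE_COLOR[label.name], dtype=np.float64)
    img = np.broadcast_to(base, (side, side, 3)).copy()

    field = _texture_field(label, side, params, rng)
    amp = params["amplitude"]
    if label is ClassLabel.Hbv:
        tint = np.array([-amp, -amp * 0.65, -amp * 0.55])
    elif label is ClassLabel.He:
        tint = np.array([amp, amp, amp])
    elif label is ClassLabel.IPCL:
        tint = np.array([-amp, -amp * 0.8, -amp * 0.55])
    else:  # Le: brighten toward white
        tint = np.array([amp * 0.75, amp, amp * 1.4])
    img += field[:, :, None] * tint[None, None, :]

    # mild pixel-level shot noise so patches at different indices differ
    img += rng.normal(0.0, 2.0, size=img.shape)
    img = np.clip(np.rint(img), 1, 254).astype(np.uint8)

    if cfg.noise_fraction > 0:
        mask = rng.random((side, side)) < cfg.noise_fraction
        values = rng.integers(0, 2, size=(side, side)).astype(np.uint8) * 255
        img[mask] = values[mask, None]
    return img


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(math.floor(n * fractions[0]))
    n_val = int(math.floor(n * fractions[1]))
    return n_train, n_val, n - n_train - n_val


def generate_dataset(
    cfg: GeneratorConfig,
    out_dir: str | Path,
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> DatasetManifest:
    """Materialize a balanced four-class dataset under ``out_dir``.

    Writes ``<out_dir>/<ClassLabel>/<image_id>.png`` for every patch plus a
    ``manifest.csv`` with header ``image_id,file_path,class_label,split``.
    Splits are stratified by class.  Fully deterministic in ``cfg.seed``:
    each image uses an independent RNG keyed by (seed, class, index).
    """
    cfg.validate()
    if not math.isclose(sum(split_fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"split_fractions must sum to 1, got {split_fractions}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    n_train, n_val, n_test = _split_counts(cfg.per_class_count, split_fractions)
    for label in ClassLabel:
        class_dir = out_dir / label.name
        class_dir.mkdir(exist_ok=True)
        split_rng = np.random.default_rng([cfg.seed, 1000 + int(label)])
        order = split_rng.permutation(cfg.per_class_count)
        split_of = np.empty(cfg.per_class_count, dtype=object)
        split_of[order[:n_train]] = "train"
        split_of[order[n_train : n_train + n_val]] = "val"
        split_of[order[n_train + n_val :]] = "test"
        for i in range(cfg.per_class_count):
            rng = np.random.default_rng([cfg.seed, int(label), i])
            patch = generate_patch(label, cfg, rng)
            image_id = f"{label.name}_{i:04d}"
            path = class_dir / f"{image_id}.png"
            try:
                Image.fromarray(patch, mode="RGB").save(path)
            except OSError as exc:
                raise OSError(f"failed writing image {path}: {exc}") from exc
            rows.append((image_id, str(path), label.name, split_of[i]))

    records = pd.DataFrame(rows, columns=list(DatasetManifest.COLUMNS))
    manifest = DatasetManifest(records)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_patch(path: str | Path) -> np.ndarray:
    """Read an RGB patch as an H x W x 3 uint8 array."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"))
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
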