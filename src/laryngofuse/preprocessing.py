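"""Median-filter denoising applied to every patch before feature extraction.

The marginal (per-channel) median with a 3x3 kernel is the default: it is the
canonical remedy for salt-and-pepper noise and preserves edges, which matters
for vascular structures in narrow-band laryngoscopy patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synthetic import DatasetManifest, load_patch

_BORDER_MODES = {"reflect": "reflect", "edge": "nearest"}


@dataclass
class FilterConfig:
    kernel_side: int = 3
    border_mode: str = "reflect"

    def validate(self) -> None:
        if self.kernel_side < 1 or self.kernel_side % 2 == 0:
            raise ValueError(f"kernel_side must be an odd integer >= 1, got {self.kernel_side}")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(
                f"border_mode must be one of {sorted(_BORDER_MODES)}, got {self.border_mode!r}"
            )


def median_filter(img: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Per-channel median filter with an odd square kernel.

    Each output pixel is the median of its ``kernel_side**2`` neighborhood in
    the same channel, so every output value is one of the input values (the
    order-statistic property) and the spatial dimensions are preserved.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    img = np.asarray(img)
    if img.ndim == 2:
        size: tuple[int, ...] = (cfg.kernel_side, cfg.kernel_side)
    elif img.ndim == 3:
        size = (cfg.kernel_side, cfg.kernel_side, 1)
    else:
        raise ValueError(f"expected an HxW or HxWx3 image, got shape {img.shape}")
    if cfg.kernel_side > min(img.shape[:2]):
        raise ValueError(
            f"kernel_side {cfg.kernel_side} exceeds image dims {img.shape[:2]}"
        )
    return ndimage.median_filter(img, size=size, mode=_BORDER_MODES[cfg.border_mode])


def preprocess_dataset(
    manifest: DatasetManifest, cfg: FilterConfig, out_dir: str | Path
) -> DatasetManifest:
    """Median-filter every image in ``manifest`` into ``out_dir``.

    Class subdirectories, image ids, labels and split assignments are
    preserved; the returned manifest points at the filtered copies.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = manifest.records.copy()
    new_paths = []
    for row in records.itertuples(index=False):
        try:
            img = load_patch(row.file_path)
        except OSError as exc:
            raise OSError(f"record {row.image_id}: {exc}") from exc
        filtered = median_filter(img, cfg)
        class_dir = out_dir / row.class_label
        class_dir.mkdir(exist_ok=True)
        path = class_dir / f"{row.image_id}.png"
        Image.fromarray(filtered, mode="RGB").save(path)
        new_paths.append(str(path))
    records["file_path"] = new_paths
    out = DatasetManifest(records)
    out.save(out_dir / "manifest.csv")
    return out
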