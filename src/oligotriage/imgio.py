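"""Image and table IO helpers: 8-bit grayscale PNG/TIFF, ground-truth CSV."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .simulate import GROUND_TRUTH_COLUMNS, CellGroundTruth


def write_field_png(image: np.ndarray, path) -> None:
    if image.dtype != np.uint8 or image.ndim != 2:
        raise ValueError("expected an 8-bit single-channel image")
    iio.imwrite(Path(path), image)


def read_field_image(path) -> np.ndarray:
    """Read an 8-bit grayscale field image (PNG or TIFF)."""
    image = iio.imread(Path(path))
    if image.ndim == 3:  # tolerate gray saved with redundant channels
        if not (image == image[..., :1]).all():
            raise ValueError(f"{path}: expected a single-channel image")
        image = image[..., 0]
    if image.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixel data, got {image.dtype}")
    return image


def write_ground_truth_csv(truth: CellGroundTruth, path) -> None:
    truth.table.to_csv(path, index=False)


def read_ground_truth_csv(path) -> CellGroundTruth:
    table = pd.read_csv(path)
    missing = set(GROUND_TRUTH_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ground-truth CSV missing columns: {sorted(missing)}")
    return CellGroundTruth(table[GROUND_TRUTH_COLUMNS])
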