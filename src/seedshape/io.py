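"""Image reading, binarization, plate segmentation and serialization.

Plates are grayscale photographs of ~20 seeds on a uniform background;
binarization is a global threshold (Otsu by default, or a fixed level)
with configurable polarity, and segmentation is connected-component
labelling with an area filter and optional border exclusion (drops
ruler-like artifacts touching the frame).  Physical scale is always
supplied explicitly (mm per pixel); it is never inferred from the image.

Masks round-trip losslessly as 0/255 8-bit PNG.  Coordinates in all
outputs are 0-based (row, col) with the origin at the top-left.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import List, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_level: Optional[float] = None
    min_area_px: int = 64
    exclude_border: bool = False
    polarity: str = "dark_seeds"  # "dark_seeds" | "light_seeds"
    crop_margin_px: int = 2

    def __post_init__(self):
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if self.threshold_mode == "fixed" and self.fixed_level is None:
            raise ValueError("fixed_level is required with threshold_mode='fixed'")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.polarity not in ("dark_seeds", "light_seeds"):
            raise ValueError("polarity must be 'dark_seeds' or 'light_seeds'")


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as 2D grayscale."""
    try:
        img = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path!r}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2:
        raise ValueError(f"unsupported image layout with shape {img.shape}")
    return img


def binarize(img: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    if config.threshold_mode == "otsu":
        if np.ptp(img) == 0:
            # uniform image: no threshold exists; empty mask, caught downstream
            return np.zeros(img.shape, dtype=bool)
        level = threshold_otsu(np.asarray(img))
    else:
        level = config.fixed_level
    if config.polarity == "dark_seeds":
        return np.asarray(img) <= level
    return np.asarray(img) > level


def read_and_binarize(
    path, config: SegmentationConfig = SegmentationConfig()
) -> Tuple[np.ndarray, np.ndarray]:
    """Grayscale image and its deterministic binary mask."""
    img = read_image(path)
    return img, binarize(img, config)


def segment_plate(
    mask: np.ndarray, config: SegmentationConfig = SegmentationConfig()
) -> Tuple[List[np.ndarray], pd.DataFrame]:
    """Split a plate mask into per-seed masks.

    Components smaller than ``min_area_px`` are dropped, as are
    border-touching components when ``exclude_border`` is set.  Each seed
    is cropped with a margin; provenance (bounding boxes in plate
    coordinates) comes back as a table.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: nothing to segment")
    lab0, n_total = label(mask, return_num=True)
    lab = clear_border(lab0) if config.exclude_border else lab0
    props = [p for p in regionprops(lab) if p.area >= config.min_area_px]
    if not props:
        n_after_border = len(regionprops(lab))
        raise ValueError(
            f"no components left after filtering: {n_total} found, "
            f"{n_after_border} after border exclusion, 0 of at least "
            f"{config.min_area_px} px"
        )
    props.sort(key=lambda p: (p.bbox[0], p.bbox[1]))
    m = config.crop_margin_px
    seeds, rows = [], []
    for i, p in enumerate(props):
        r0, c0, r1, c1 = p.bbox
        rr0, cc0 = max(r0 - m, 0), max(c0 - m, 0)
        rr1 = min(r1 + m, mask.shape[0])
        cc1 = min(c1 + m, mask.shape[1])
        crop = (lab[rr0:rr1, cc0:cc1] == p.label)
        seeds.append(crop)
        rows.append({"seed": i, "row0": rr0, "col0": cc0,
                     "row1": rr1, "col1": cc1, "area_px": int(p.area)})
    return seeds, pd.DataFrame(rows)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as lossless 8-bit PNG (0 background, 255
    foreground)."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    img = read_image(path)
    return img >= 128


def write_run_log(out_dir, command: str, payload: dict) -> Path:
    """JSON run-log (inputs, config, versions) written beside outputs."""
    import seedshape

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seedshape_version": seedshape.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        **payload,
    }
    path = out_dir / f"seedshape-{command}-runlog.json"
    path.write_text(json.dumps(log, indent=2, default=str))
    return path
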