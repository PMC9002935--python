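"""Average silhouette of a population of seed masks.

A stack of aligned seed silhouettes is summed into a per-pixel coverage
count; the average silhouette is the region covered by at least a
fraction ``tau`` of the stack ("where most of the seeds coincided" — the
darkest area of a superimposed stack), with majority coverage
(``tau = 0.5``) as the default.  ``tau = 1`` yields the intersection of
the stack, ``tau -> 1/N`` its union.

Alignment standardizes each mask before stacking: centroid centered,
principal axis vertical, heavier half down, optionally a canonical
chirality.  Stacking without alignment (``align=False``) is available for
masks already superimposed on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .registration import _centroid, _principal_angle


@dataclass(frozen=True)
class SilhouetteConfig:
    tau: float = 0.5  # coverage fraction in (0, 1]
    scale_normalize: bool = False
    n_min: int = 20
    align: bool = True
    canonicalize_flip: bool = False

    def __post_init__(self):
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must lie in (0, 1]")


def _crop_to_bbox(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    r0, c0 = idx.min(axis=0)
    r1, c1 = idx.max(axis=0)
    return mask[r0:r1 + 1, c0:c1 + 1]


def _rotate_mask(mask: np.ndarray, degrees: float) -> np.ndarray:
    out = ndimage.rotate(mask.astype(np.float32), degrees, reshape=True,
                         order=1, prefilter=False)
    return out > 0.5


def align_mask(
    mask: np.ndarray,
    canonicalize_flip: bool = False,
    scale_height: int | None = None,
) -> np.ndarray:
    """Standardized orientation: principal axis vertical, heavier half
    down, centroid-cropped; optional mirror canonicalization and height
    normalization.  Returns the aligned mask cropped to its bounding box.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    _, ncomp = label(mask, return_num=True)
    if ncomp > 1:
        raise ValueError("align_mask expects a single-component mask")
    angle, defined = _principal_angle(mask)
    out = mask
    if defined and abs(angle) > 1e-4:
        # principal angle is measured from the row axis; remove it, then
        # re-estimate once and fold the residual into a single rotation of
        # the original (avoids compounding interpolation error)
        out = _rotate_mask(out, -np.degrees(angle))
        residual, ok = _principal_angle(out)
        if ok and abs(residual) > np.deg2rad(2.0):
            angle = -angle
            out = _rotate_mask(mask, np.degrees(-angle))
            residual, ok = _principal_angle(out)
        if ok and abs(residual) > np.deg2rad(0.05):
            out = _rotate_mask(mask, -np.degrees(angle + residual))
    # heavier half down: compare mass on either side of the bbox mid-row
    # (areas about the centroid nearly balance by construction)
    out = _crop_to_bbox(out)
    mid = out.shape[0] // 2
    if out[:mid, :].sum() > out[out.shape[0] - mid:, :].sum():
        out = out[::-1, ::-1]
    if canonicalize_flip:
        cx = _centroid(out)[1]
        cols = np.nonzero(out)[1].astype(float)
        if np.sum((cols - cx) ** 3) < 0.0:
            out = out[:, ::-1]
    out = _crop_to_bbox(out)
    if scale_height is not None:
        zoom = scale_height / out.shape[0]
        out = ndimage.zoom(out.astype(np.float32), zoom, order=1,
                           prefilter=False) > 0.5
        if not out.any():
            raise ValueError("scale normalization erased the mask")
        out = _crop_to_bbox(out)
    return out


def stack_coverage(masks, config: SilhouetteConfig = SilhouetteConfig()):
    """Per-pixel coverage counts of the (aligned) stack.

    Returns an integer array; with ``align=False`` all masks must already
    share one pixel grid.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to build a silhouette")
    if len(masks) < config.n_min:
        raise ValueError(
            f"{len(masks)} masks < n_min={config.n_min}; lower n_min in the "
            "config if this is intended"
        )
    if not config.align:
        shapes = {m.shape for m in masks}
        if len(shapes) > 1:
            raise ValueError("align=False requires masks on a shared grid")
        return np.sum([m.astype(np.int32) for m in masks], axis=0)
    target = (max(m.shape[0] for m in masks) if config.scale_normalize
              else None)
    aligned = [
        align_mask(m, canonicalize_flip=config.canonicalize_flip,
                   scale_height=target)
        for m in masks
    ]
    rows = max(a.shape[0] for a in aligned) + 4
    cols = max(a.shape[1] for a in aligned) + 4
    cov = np.zeros((rows, cols), dtype=np.int32)
    center = np.array([rows / 2.0, cols / 2.0])
    for a in aligned:
        cy, cx = _centroid(a)
        r0 = int(round(center[0] - cy))
        c0 = int(round(center[1] - cx))
        cov[r0:r0 + a.shape[0], c0:c0 + a.shape[1]] += a
    return cov


def average_silhouette(
    masks, config: SilhouetteConfig = SilhouetteConfig()
) -> np.ndarray:
    """Coverage-thresholded silhouette of a stack of masks.

    A pixel belongs to the silhouette when covered by at least
    ``tau * N`` of the ``N`` masks; the largest connected component is
    kept.
    """
    masks = list(masks)
    cov = stack_coverage(masks, config)
    n = len(masks)
    sil = cov >= (config.tau * n - 1e-9)
    if not sil.any():
        raise ValueError(f"no pixel reaches coverage tau={config.tau}")
    lab, ncomp = label(sil, return_num=True)
    if ncomp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        sil = lab == (int(np.argmax(sizes)) + 1)
    return sil
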