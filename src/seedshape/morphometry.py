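"""Size/shape descriptors of a binary seed mask and convexity classification.

Descriptors follow the ImageJ particle-analysis conventions: area ``A`` and
perimeter ``P`` in physical units; ``L`` and ``W`` are the major/minor axes
of the best-fit (equal-second-moments) ellipse; aspect ratio ``AR = L/W``;
circularity ``C = 4*pi*A / P**2`` (sensitive to boundary roughness) and
roundness ``R = 4*A / (pi*L**2)`` (insensitive to it).

The perimeter is the arc length of the marching-squares contour at level
0.5 rather than a raw pixel-edge count, so a rasterized disk measures
``C`` close to 1.  Digital perimeters carry a small residual anisotropy;
an allowance of a few percent is documented where ``C`` or ``R`` may
slightly exceed 1 on coarse rasters.

Convexity is judged operationally through solidity (area over convex-hull
area): small surface protuberances (colliculae) cost little hull area, so
a modest threshold (default 0.97) keeps them from flipping the label,
while the dorsal channel of non-convex seeds does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, label, regionprops

#: default solidity threshold separating convex from non-convex outlines
DEFAULT_SOLIDITY_THRESHOLD = 0.97


@dataclass(frozen=True)
class ShapeDescriptors:
    """Measurements of one seed mask, in physical units (mm, mm^2)."""

    A: float
    P: float
    L: float
    W: float
    AR: float
    C: float
    R: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("A", "P", "L", "W", "AR", "C", "R")}


@dataclass(frozen=True)
class ConvexityReport:
    solidity: float
    label: str  # "convex" | "nonconvex"
    threshold_used: float


def _single_region(mask: np.ndarray, min_px: int = 1):
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D array")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no foreground pixels")
    lab, ncomp = label(mask, return_num=True)
    if ncomp > 1:
        raise ValueError(
            f"mask has {ncomp} connected components; segment the image into "
            "single-seed masks first (see seedshape.io.segment_plate)"
        )
    if n < min_px:
        raise ValueError(f"foreground too small ({n} px < {min_px} px)")
    return mask, regionprops(lab)[0]


def contour_perimeter(mask: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Arc length (px) of the longest marching-squares contour at 0.5.

    The binary image is lightly Gaussian-smoothed first; contouring the
    raw 0/1 field yields a pixel staircase that overestimates smooth
    boundaries by ~5%, while the smoothed contour tracks them to <1%.
    """
    field = ndi.gaussian_filter(np.asarray(mask, dtype=float), smooth_sigma)
    padded = np.pad(field, 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask: no contour found")
    lengths = [
        float(np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)))
        for c in contours
    ]
    return max(lengths)


def measure_mask(mask: np.ndarray, mm_per_px: float = 1.0) -> ShapeDescriptors:
    """Compute the descriptor set for a single-component mask.

    Parameters
    ----------
    mask : 2D boolean array, exactly one connected component of >= 64 px.
    mm_per_px : physical size of one pixel side, > 0.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    mask, rp = _single_region(mask, min_px=64)
    area_px = float(rp.area)
    perim_px = contour_perimeter(mask)
    major_px = float(rp.axis_major_length)
    minor_px = float(rp.axis_minor_length)
    if minor_px <= 0:
        raise ValueError("degenerate mask: zero minor axis")
    A = area_px * mm_per_px ** 2
    P = perim_px * mm_per_px
    L = major_px * mm_per_px
    W = minor_px * mm_per_px
    return ShapeDescriptors(
        A=A, P=P, L=L, W=W,
        AR=L / W,
        C=4.0 * np.pi * A / P ** 2,
        R=4.0 * A / (np.pi * L ** 2),
    )


def classify_convexity(
    mask: np.ndarray, threshold: float = DEFAULT_SOLIDITY_THRESHOLD
) -> ConvexityReport:
    """Label a dorsal outline convex or non-convex by its solidity."""
    _mask, rp = _single_region(mask)
    solidity = float(rp.solidity)
    lab = "convex" if solidity >= threshold else "nonconvex"
    return ConvexityReport(solidity=solidity, label=lab, threshold_used=threshold)
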