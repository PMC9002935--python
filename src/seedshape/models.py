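"""Dorsal geometric seed models DM1–DM9 and their rasterization.

The registry holds nine closed planar curves used as references for the
dorsal outline of *Silene* seeds.  DM1 is a superellipse ("squared
circle"), DM2–DM8 are two-arc curves (a region bounded above and below by
two modified half-ellipse arcs, obtained by setting a product of two
factors to zero), and DM9 is defined in polar coordinates.  DM1–DM4
describe convex seeds; DM5–DM9 describe non-convex ("dorso canaliculata")
seeds whose outline carries a shallow channel at the ends of the long
axis, expressed through a shared rational bump term with denominator
x**4 + x**2 + 6.

Model coordinates are mathematical (x right, y up); the rasterizer owns
the flip to row/col image coordinates (row 0 at top).  A pixel is
foreground iff its *center* lies inside the curve (even-touch fill).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from matplotlib.path import Path as _MplPath

logger = logging.getLogger(__name__)

MODEL_IDS = tuple(f"DM{i}" for i in range(1, 10))

#: two-arc endpoints closer than this (model units) are declared coincident
ARC_CLOSURE_TOL = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one dorsal model.

    Parameters are the plain numeric coefficients of the boundary
    functions; ``provenance_note`` records, coefficient by coefficient,
    which values were transcribed from the printed equations and which
    were reconstructed against the published silhouette class and the
    species aspect-ratio ranges.
    """

    id: str
    kind: str  # "superellipse" | "two_arc" | "polar"
    convexity_class: str  # "convex" | "nonconvex"
    params: Dict[str, float] = field(default_factory=dict)
    provenance_note: str = ""


# --- boundary function families -------------------------------------------

def _superellipse_point(t: np.ndarray, n: float, a: float, b: float):
    """Angle parameterization of |x/a|**n + |y/b|**n = 1."""
    ct, st = np.cos(t), np.sin(t)
    x = a * np.sign(ct) * np.abs(ct) ** (2.0 / n)
    y = b * np.sign(st) * np.abs(st) ** (2.0 / n)
    return x, y


def _two_arc_funcs(p: Dict[str, float]) -> Tuple[Callable, Callable, float]:
    """Build upper(x), lower(x) and the half-domain from a parameter dict.

    upper(x) = au*sqrt(c - x**k) + tip(x) - bump_u/q(x) + const_u
    lower(x) = -al*(1 + skew_l*x)*sqrt(c - x**k) + tip(x) + bump_l/q(x) + const_l

    with tip(x) = tip_amp * (x**2 / c**(2/k)) ** tip_pow and
    q(x) = x**4 + x**2 + 6 (shared by all non-convex models).
    """
    c, k = p["c"], p["k"]
    half = c ** (1.0 / k)
    au, al = p["au"], p["al"]
    skew = p.get("skew_l", 0.0)
    tip_amp, tip_pow = p.get("tip_amp", 0.0), p.get("tip_pow", 1.0)
    bu, bl = p.get("bump_u", 0.0), p.get("bump_l", 0.0)
    cu, cl = p.get("const_u", 0.0), p.get("const_l", 0.0)

    def _tip(x):
        if tip_amp == 0.0:
            return 0.0
        return tip_amp * (x * x / (half * half)) ** tip_pow

    def _q(x):
        return x ** 4 + x ** 2 + 6.0

    def upper(x):
        x = np.asarray(x, dtype=float)
        root = np.sqrt(np.clip(c - np.abs(x) ** k, 0.0, None))
        return au * root + _tip(x) - bu / _q(x) + cu

    def lower(x):
        x = np.asarray(x, dtype=float)
        root = np.sqrt(np.clip(c - np.abs(x) ** k, 0.0, None))
        return -al * (1.0 + skew * x) * root + _tip(x) + bl / _q(x) + cl

    return upper, lower, half


def _polar_radius_dm9(theta: np.ndarray) -> np.ndarray:
    """rho(theta) = (cos(theta)**20 + 4*sin(theta)**2) ** (-2/3)."""
    theta = np.asarray(theta, dtype=float)
    return (np.cos(theta) ** 20 + 4.0 * np.sin(theta) ** 2) ** (-2.0 / 3.0)


# --- the registry ----------------------------------------------------------

def _registry() -> Dict[str, ModelSpec]:
    specs = [
        ModelSpec(
            "DM1", "superellipse", "convex",
            {"n": 3.0, "a": 2.0 / 3.0, "b": 1.0},
            "Transcribed: |3x/2|^3 + |y|^3 = 1 (exponent 3, x-semi-axis 2/3), "
            "the only reading consistent with a 'squared circle' at aspect "
            "ratio 1.5.",
        ),
        ModelSpec(
            "DM2", "two_arc", "convex",
            {"c": 40.0, "k": 2.0, "au": 10.0 / 7.0, "al": 10.0 / 7.0,
             "tip_amp": 1.25, "tip_pow": 30.0,
             "const_u": 0.875, "const_l": 0.625},
            "Structure and constants (5/4*(…+7/10), 5/4*(…+1/2)), sqrt(40-x^2) "
            "and exponent 30 transcribed; arc amplitude 10/7 and tip base "
            "x^2/40 reconstructed (printed 10/11 and 10x^2/363 give aspect "
            "ratio 1.08, far outside the convex species range).",
        ),
        ModelSpec(
            "DM3", "two_arc", "convex",
            {"c": 40.0, "k": 2.0, "au": 14.0 / 9.0, "al": 49.0 / 36.0,
             "tip_amp": 5.0 / 6.0, "tip_pow": 10.0},
            "Structure (asymmetric 9y/10 vs 4y/5 factors, sqrt(40-x^2), tip "
            "exponent 10, amplitude 5/6) transcribed; arc amplitudes "
            "reconstructed to the S. dioica aspect-ratio range.",
        ),
        ModelSpec(
            "DM4", "two_arc", "convex",
            {"c": 40.0, "k": 2.0, "au": 1.62, "al": 1.50, "skew_l": 0.02,
             "tip_amp": 0.75, "tip_pow": 6.0},
            "Structure transcribed (sqrt(40-x^2); 3/4 tip constant); the "
            "printed linear-in-x term '(10x/11 + 1/2)' is kept as a small "
            "left-right skew of the lower arc; amplitudes reconstructed to "
            "the S. littorea aspect-ratio range.",
        ),
        ModelSpec(
            "DM5", "two_arc", "nonconvex",
            {"c": 33.0, "k": 4.0, "au": 1.00, "al": 0.55,
             "bump_u": 7.3, "bump_l": 9.1},
            "Structure transcribed: sqrt(33 - x^4) arcs, asymmetric "
            "amplitudes (printed 9/10 vs 1/2), shared channel denominator "
            "x^4 + x^2 + 6; channel numerators reconstructed (about twice "
            "the printed 40/11 and 50/11, which leave the raster convex).",
        ),
        ModelSpec(
            "DM6", "two_arc", "nonconvex",
            {"c": 33.0, "k": 4.0, "au": 1.17, "al": 0.58,
             "bump_u": 9.0, "bump_l": 10.0},
            "Structure transcribed: sqrt(33 - x^4) arcs scaled by the 9y/10 "
            "factor, channel denominator x^4 + x^2 + 6; amplitudes and "
            "channel numerators reconstructed to the S. coutinhoi "
            "aspect-ratio range and the non-convex class.",
        ),
        ModelSpec(
            "DM7", "two_arc", "nonconvex",
            {"c": 33.0, "k": 2.0, "au": 1.36, "al": 1.36,
             "bump_u": 12.0, "bump_l": 12.0},
            "Structure transcribed: symmetric sqrt(33 - x^2) arcs with equal "
            "channels top and bottom (printed 50/11 both factors); amplitude "
            "and channel depth reconstructed (printed 6/5 and 50/11 give "
            "aspect ratio 1.07, below the S. pseudoatocion range, and a "
            "convex raster).",
        ),
        ModelSpec(
            "DM8", "two_arc", "nonconvex",
            {"c": 33.0, "k": 2.0, "au": 2.26, "al": 2.26,
             "bump_u": 18.0, "bump_l": 18.0},
            "Structure transcribed: symmetric sqrt(33 - x^2) arcs under the "
            "3y factor with deep equal channels (printed 250/11); amplitude "
            "and channel depth reconstructed to the S. ramosissima "
            "aspect-ratio range and the non-convex class.",
        ),
        ModelSpec(
            "DM9", "polar", "nonconvex",
            {"cos_pow": 20.0, "sin_coef": 4.0, "exponent": -2.0 / 3.0},
            "Transcribed verbatim: rho = (cos^20(theta) + 4 sin^2(theta))"
            "^(-2/3).",
        ),
    ]
    return {s.id: s for s in specs}


_REGISTRY = _registry()


def list_models() -> Sequence[ModelSpec]:
    """Return the nine dorsal model specs, DM1..DM9 in order."""
    return [_REGISTRY[mid] for mid in MODEL_IDS]


def get_model(model_id: str) -> ModelSpec:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; valid ids are {', '.join(MODEL_IDS)}"
        ) from None


def evaluate_boundary(model_id: str, t):
    """Evaluate the boundary at parameter ``t``.

    * superellipse (DM1): ``t`` is the angle parameter in [0, 2*pi];
      returns one (x, y) point.
    * two-arc (DM2–DM8): ``t`` is the abscissa x inside the model domain;
      returns ((x, upper(x)), (x, lower(x))).
    * polar (DM9): ``t`` is theta in [0, 2*pi); returns the (x, y) point
      rho(theta) * (cos(theta), sin(theta)).
    """
    spec = get_model(model_id)
    t_arr = np.asarray(t, dtype=float)
    if spec.kind == "superellipse":
        p = spec.params
        if np.any(t_arr < 0.0) or np.any(t_arr > 2.0 * np.pi):
            raise ValueError(
                f"{model_id}: angle parameter must lie in [0, {2 * np.pi:.6f}]"
            )
        x, y = _superellipse_point(t_arr, p["n"], p["a"], p["b"])
        return np.stack([x, y], axis=-1)
    if spec.kind == "polar":
        if np.any(t_arr < 0.0) or np.any(t_arr >= 2.0 * np.pi + 1e-12):
            raise ValueError(
                f"{model_id}: theta must lie in [0, {2 * np.pi:.6f})"
            )
        rho = _polar_radius_dm9(t_arr)
        return np.stack([rho * np.cos(t_arr), rho * np.sin(t_arr)], axis=-1)
    upper, lower, half = _two_arc_funcs(spec.params)
    if np.any(np.abs(t_arr) > half + 1e-12):
        raise ValueError(
            f"{model_id}: abscissa must lie in [{-half:.6f}, {half:.6f}]"
        )
    return (
        np.stack([t_arr, upper(t_arr)], axis=-1),
        np.stack([t_arr, lower(t_arr)], axis=-1),
    )


def polar_radius(model_id: str, theta) -> np.ndarray:
    """Radius rho(theta) for the polar model (DM9)."""
    spec = get_model(model_id)
    if spec.kind != "polar":
        raise ValueError(f"{model_id} is not a polar model")
    return _polar_radius_dm9(theta)


def _two_arc_domain(spec: ModelSpec) -> Tuple[float, float]:
    """Trim the nominal domain to where upper >= lower (arcs may cross
    slightly before the nominal endpoints when channel terms differ)."""
    upper, lower, half = _two_arc_funcs(spec.params)

    def gap(x):
        return float(upper(x) - lower(x))

    lo, hi = -half, half
    for sign in (-1.0, 1.0):
        end = sign * half
        if gap(end) >= 0.0:
            continue
        # bisect between the center (gap > 0) and the crossing end
        a, b = 0.0, end
        for _ in range(80):
            m = 0.5 * (a + b)
            if gap(m) >= 0.0:
                a = m
            else:
                b = m
        if sign < 0:
            lo = a
        else:
            hi = a
    return lo, hi


def boundary_polyline(model_id: str, n: int = 2000) -> np.ndarray:
    """Dense closed polyline (n_points, 2) of the model boundary, in model
    units, counter-clockwise, first point repeated last."""
    spec = get_model(model_id)
    if spec.kind == "superellipse":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = evaluate_boundary(model_id, t)
    elif spec.kind == "polar":
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        pts = evaluate_boundary(model_id, t)
    else:
        upper, lower, _half = _two_arc_funcs(spec.params)
        lo, hi = _two_arc_domain(spec)
        m = max(n // 2, 16)
        # cosine spacing: dense near the endpoints where arcs turn fast
        u = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, m)))
        xs = lo + (hi - lo) * u
        top = np.stack([xs, upper(xs)], axis=-1)
        bot = np.stack([xs[::-1], lower(xs[::-1])], axis=-1)
        gap_hi = abs(float(upper(hi) - lower(hi)))
        gap_lo = abs(float(upper(lo) - lower(lo)))
        if max(gap_hi, gap_lo) > ARC_CLOSURE_TOL:
            logger.info(
                "%s: arcs meet within %.3g/%.3g model units at the domain "
                "ends; joining with vertical segments", model_id, gap_lo,
                gap_hi,
            )
        pts = np.concatenate([top, bot], axis=0)
    return np.concatenate([pts, pts[:1]], axis=0)


def model_extent(model_id: str, n: int = 4000) -> Tuple[float, float]:
    """(width, height) of the model bounding box in model units."""
    pts = boundary_polyline(model_id, n=n)
    return (
        float(pts[:, 0].max() - pts[:, 0].min()),
        float(pts[:, 1].max() - pts[:, 1].min()),
    )


def rasterize_polyline(
    poly: np.ndarray, height_px: int, margin_px: int = 0
) -> np.ndarray:
    """Fill a closed model-unit polyline into a boolean mask.

    The region is scaled so its bounding-box height equals ``height_px``
    rows, y is flipped into row coordinates, and a pixel is foreground iff
    its center lies inside the polygon.
    """
    xmin, ymin = poly[:, 0].min(), poly[:, 1].min()
    xmax, ymax = poly[:, 0].max(), poly[:, 1].max()
    scale = height_px / (ymax - ymin)
    width_px = int(np.ceil((xmax - xmin) * scale))
    rows = height_px + 2 * margin_px
    cols = width_px + 2 * margin_px
    # map model coords to (row, col) pixel-center coords; the half-pixel
    # shift makes the filled extent span exactly height_px rows
    rr = margin_px + (ymax - poly[:, 1]) * scale - 0.5
    cc = margin_px + (poly[:, 0] - xmin) * scale - 0.5
    path = _MplPath(np.stack([cc, rr], axis=-1))
    cgrid, rgrid = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = np.stack([cgrid.ravel(), rgrid.ravel()], axis=-1)
    inside = path.contains_points(centers)
    return inside.reshape(rows, cols)


def rasterize_model(
    model_id: str, height_px: int, margin_px: int = 0, n_boundary: int = 4000
) -> np.ndarray:
    """Rasterize a model to a boolean mask of bounding-box height
    ``height_px`` with ``margin_px`` background on all sides."""
    if height_px < 16:
        raise ValueError("height_px must be at least 16")
    poly = boundary_polyline(model_id, n=n_boundary)
    mask = rasterize_polyline(poly, height_px, margin_px)
    if mask.sum() < 16:
        raise ValueError(
            f"degenerate rasterization of {model_id}: "
            f"{int(mask.sum())} foreground pixels"
        )
    return mask


def boundary_csv(model_id: str, path, n: int = 2000) -> None:
    """Write the boundary polyline as a two-column x,y CSV (model units)."""
    poly = boundary_polyline(model_id, n=n)
    np.savetxt(path, poly, delimiter=",", header="x,y", comments="")
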