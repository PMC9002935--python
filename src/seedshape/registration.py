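"""J index: percent area overlap between a seed mask and a model under an
optimally chosen similarity transform.

The J index between two binary silhouettes is ``J = S / T * 100`` with
``S`` the shared (intersection) and ``T`` the total (union) pixel area
once the model has been superimposed on the seed for maximum coincidence.
``J = 100`` iff the silhouettes coincide pixel for pixel; a fit with
``J > 90`` is conventionally called good.

The superposition is a similarity transform (translation, isotropic
scale, rotation, optional mirror) of the model onto the seed grid — the
seed stays fixed so its pixel counts are stable across models.  The
search initializes from moment matching (centroids, areas, principal
axes; both axis polarities and, for mirror-asymmetric models, both
chiralities) and refines each candidate with a derivative-free simplex
over (tx, ty, log s, phi).  The model is resampled with bilinear
interpolation and thresholded at 0.5, which smooths the otherwise
pixel-quantized objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.measure import label, regionprops

from .models import MODEL_IDS, get_model, model_extent, rasterize_model

logger = logging.getLogger(__name__)

GOOD_FIT_THRESHOLD = 90.0  # J above this is a "good" adjustment


@dataclass(frozen=True)
class SimilarityTransform:
    """Maps model pixel coordinates into seed image coordinates.

    A model point ``p`` (row, col) maps to
    ``s * R(phi) @ F @ (p - c_model) + c_model + (ty, tx)`` where
    ``c_model`` is the model-foreground centroid and ``F`` mirrors the
    column axis when ``flip`` is set (mirror applied before rotation).
    """

    tx: float = 0.0  # column translation, px
    ty: float = 0.0  # row translation, px
    s: float = 1.0
    phi: float = 0.0  # radians, normalized to (-pi, pi]
    flip: bool = False

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scale must be positive")
        phi = (self.phi + np.pi) % (2.0 * np.pi) - np.pi
        if phi == -np.pi:
            phi = np.pi
        object.__setattr__(self, "phi", float(phi))


@dataclass(frozen=True)
class JResult:
    """Outcome of fitting one model to one seed mask."""

    model_id: str
    J: float  # percent, 0..100
    S: int  # shared (intersection) pixels
    T: int  # total (union) pixels
    transform: SimilarityTransform
    converged: bool = True

    def good_fit(self) -> bool:
        return self.J > GOOD_FIT_THRESHOLD


@dataclass(frozen=True)
class FitOptions:
    maxiter: int = 200
    jtol: float = 1e-3  # convergence tolerance on J (percent)
    scale_bounds: Tuple[float, float] = (0.5, 2.0)  # x the area-matched scale
    model_height: Optional[int] = None  # default: seed bounding-box long side
    n_boundary: int = 2000
    # run the candidate search on a 2x-downsampled grid first, then polish
    # at full resolution (skipped automatically for small masks)
    coarse_to_fine: bool = True


def jaccard_percent(a: np.ndarray, b: np.ndarray) -> float:
    """100 * |a & b| / |a | b| for two masks on the same pixel grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"masks must share a pixel grid: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("both masks are empty; J index is undefined")
    shared = int(np.count_nonzero(a & b))
    return 100.0 * shared / union


def _centroid(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx.mean(axis=0)


def _principal_angle(mask: np.ndarray) -> Tuple[float, bool]:
    """Principal-axis angle (radians from the row axis toward the column
    axis) of a mask, and whether the orientation is well defined."""
    rp = regionprops(np.asarray(mask, dtype=np.uint8))[0]
    mu = rp.moments_central
    mu20, mu02, mu11 = mu[2, 0], mu[0, 2], mu[1, 1]
    aniso = np.hypot(mu20 - mu02, 2.0 * mu11) / (mu20 + mu02)
    if aniso < 1e-3:
        return 0.0, False
    return 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02), True


def apply_transform(
    model: np.ndarray,
    transform: SimilarityTransform,
    out_shape: Tuple[int, int],
    threshold: float = 0.5,
) -> np.ndarray:
    """Resample a model mask onto the seed grid under a transform.

    Bilinear interpolation of the 0/1 model image, thresholded at 0.5.
    """
    model_f = np.asarray(model, dtype=np.float32)
    c_model = _centroid(np.asarray(model, dtype=bool))
    s, phi, flip = transform.s, transform.phi, transform.flip
    t = np.array([transform.ty, transform.tx])
    cos, sin = np.cos(phi), np.sin(phi)
    rot = np.array([[cos, -sin], [sin, cos]])
    fmat = np.array([[1.0, 0.0], [0.0, -1.0 if flip else 1.0]])
    # inverse map: p_model = (1/s) F R(-phi) (p_seed - c_model - t) + c_model
    minv = (fmat @ rot.T) / s
    offset = c_model - minv @ (c_model + t)
    out = ndimage.affine_transform(
        model_f, minv, offset=offset, output_shape=out_shape,
        order=1, mode="constant", cval=0.0, prefilter=False,
    )
    return out > threshold


def initial_candidates(
    seed: np.ndarray, model: np.ndarray, try_flip: bool = True
) -> List[SimilarityTransform]:
    """Moment-matching starting transforms: centroid + area + principal
    axis, both axis polarities, optionally both chiralities."""
    seed = np.asarray(seed, dtype=bool)
    model = np.asarray(model, dtype=bool)
    if not seed.any() or not model.any():
        raise ValueError("seed and model masks must be non-empty")
    c_seed, c_model = _centroid(seed), _centroid(model)
    s0 = float(np.sqrt(seed.sum() / model.sum()))
    ang_seed, ok_seed = _principal_angle(seed)
    ang_model, ok_model = _principal_angle(model)
    if not (ok_seed and ok_model):
        logger.info("near-circular mask: principal orientation undefined, "
                    "starting rotation set to 0")
        ang_seed = ang_model = 0.0
    ty, tx = (c_seed - c_model)
    out = []
    for flip in ([False, True] if try_flip else [False]):
        base = ang_seed + ang_model if flip else ang_seed - ang_model
        for pol in (0.0, np.pi):
            out.append(SimilarityTransform(
                tx=float(tx), ty=float(ty), s=s0, phi=base + pol, flip=flip))
    return out


def initial_alignment(seed: np.ndarray, model: np.ndarray) -> SimilarityTransform:
    """Best-J moment-matching transform (no local refinement)."""
    cands = initial_candidates(seed, model)
    js = [
        jaccard_percent(seed, apply_transform(model, tr, seed.shape))
        for tr in cands
    ]
    return cands[int(np.argmax(js))]


def _mirror_symmetric(model: np.ndarray, tol: float = 0.02) -> bool:
    """True when the model raster equals its own mirror image about the
    foreground centroid (so flipped starting candidates are redundant)."""
    m = np.asarray(model, dtype=bool)
    flipped = m[:, ::-1]
    # re-center the mirror on the original centroid column
    shift = int(round(2.0 * _centroid(m)[1])) - (m.shape[1] - 1)
    flipped = np.roll(flipped, shift, axis=1)
    xor = np.count_nonzero(m ^ flipped)
    return xor <= tol * max(int(m.sum()), 1)


def refine(
    seed: np.ndarray,
    model: np.ndarray,
    start: SimilarityTransform,
    options: FitOptions = FitOptions(),
) -> Tuple[SimilarityTransform, float, bool]:
    """Nelder–Mead refinement of (tx, ty, log s, phi) from one start.

    Returns (best transform, best J, converged flag).  The returned J is
    never below the J of the start (keep-best refinement).
    """
    seed = np.asarray(seed, dtype=bool)
    s0 = start.s
    smin, smax = options.scale_bounds[0] * s0, options.scale_bounds[1] * s0
    best = {"J": -1.0, "x": None}

    def objective(x):
        tx, ty, logs, phi = x
        s = float(np.exp(logs))
        if not (smin <= s <= smax):
            return 1000.0
        tr = SimilarityTransform(tx=tx, ty=ty, s=s, phi=phi, flip=start.flip)
        j = jaccard_percent(seed, apply_transform(model, tr, seed.shape))
        if j > best["J"]:
            best["J"], best["x"] = j, x.copy()
        return -j

    x0 = np.array([start.tx, start.ty, np.log(s0), start.phi])
    steps = np.array([2.0, 2.0, 0.04, 0.06])
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={
            "maxiter": options.maxiter,
            "fatol": options.jtol,
            "xatol": 1e-2,
            "initial_simplex": simplex,
        },
    )
    converged = bool(res.success)
    if not converged:
        logger.warning("refinement hit the iteration cap; returning best-so-far")
    j_start = jaccard_percent(seed, apply_transform(model, start, seed.shape))
    if best["x"] is None or best["J"] < j_start:
        return start, j_start, converged
    tx, ty, logs, phi = best["x"]
    tr = SimilarityTransform(tx=float(tx), ty=float(ty), s=float(np.exp(logs)),
                             phi=float(phi), flip=start.flip)
    return tr, float(best["J"]), converged


def _check_single_component(seed: np.ndarray) -> None:
    _, ncomp = label(np.asarray(seed, dtype=bool), return_num=True)
    if ncomp == 0:
        raise ValueError("seed mask is empty")
    if ncomp > 1:
        raise ValueError(
            f"seed mask has {ncomp} components; fit one seed at a time"
        )


def _model_raster_for(seed: np.ndarray, model_id: str,
                      options: FitOptions) -> np.ndarray:
    if options.model_height is not None:
        height = options.model_height
    else:
        idx = np.argwhere(seed)
        bbox = idx.max(axis=0) - idx.min(axis=0) + 1
        height = int(max(bbox))
    height = max(height, 16)
    return rasterize_model(model_id, height_px=height, margin_px=2,
                           n_boundary=options.n_boundary)


def fit_model(
    seed: np.ndarray,
    model_id: str,
    options: FitOptions = FitOptions(),
    model_mask: Optional[np.ndarray] = None,
) -> JResult:
    """Maximize J of a model over similarity transforms onto one seed.

    ``model_mask`` may supply a pre-rasterized model (resolution reuse
    across many seeds); otherwise the model is rasterized to the seed's
    bounding-box long side.
    """
    seed = np.asarray(seed, dtype=bool)
    _check_single_component(seed)
    get_model(model_id)
    model = (np.asarray(model_mask, dtype=bool) if model_mask is not None
             else _model_raster_for(seed, model_id, options))
    # work on a bbox crop of the seed (the search cost scales with the
    # grid); the final transform/counts are reported on the full grid
    idx = np.argwhere(seed)
    pad = 16
    r0 = max(int(idx[:, 0].min()) - pad, 0)
    c0 = max(int(idx[:, 1].min()) - pad, 0)
    r1 = min(int(idx[:, 0].max()) + pad + 1, seed.shape[0])
    c1 = min(int(idx[:, 1].max()) + pad + 1, seed.shape[1])
    crop = seed[r0:r1, c0:c1]
    try_flip = not _mirror_symmetric(model)
    coarse = (options.coarse_to_fine and min(crop.shape) >= 80
              and min(model.shape) >= 48)
    best: Tuple[SimilarityTransform, float, bool] | None = None
    if coarse:
        crop2, model2 = crop[::2, ::2], model[::2, ::2]
        for cand in initial_candidates(crop2, model2, try_flip=try_flip):
            tr2, j2, _conv = refine(crop2, model2, cand, options)
            if best is None or j2 > best[1]:
                best = (tr2, j2, True)
        tr2 = best[0]
        start = SimilarityTransform(tx=2.0 * tr2.tx, ty=2.0 * tr2.ty,
                                    s=tr2.s, phi=tr2.phi, flip=tr2.flip)
        tr, _j, conv = refine(crop, model, start, options)
    else:
        for cand in initial_candidates(crop, model, try_flip=try_flip):
            tr_c, j_c, conv_c = refine(crop, model, cand, options)
            if best is None or j_c > best[1]:
                best = (tr_c, j_c, conv_c)
        tr, _j, conv = best
    tr = SimilarityTransform(tx=tr.tx + c0, ty=tr.ty + r0, s=tr.s,
                             phi=tr.phi, flip=tr.flip)
    fitted = apply_transform(model, tr, seed.shape)
    s_px = int(np.count_nonzero(seed & fitted))
    t_px = int(np.count_nonzero(seed | fitted))
    return JResult(model_id=model_id, J=100.0 * s_px / t_px, S=s_px, T=t_px,
                   transform=tr, converged=conv)


@dataclass
class ModelFitTable:
    """Per-model J results for one seed, plus the best model."""

    results: Dict[str, JResult] = field(default_factory=dict)
    best_model: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for mid in sorted(self.results, key=lambda m: MODEL_IDS.index(m)):
            r = self.results[mid]
            t = r.transform
            rows.append({
                "model": mid, "J": r.J, "S": r.S, "T": r.T,
                "tx": t.tx, "ty": t.ty, "s": t.s, "phi": t.phi,
                "flip": t.flip, "converged": r.converged,
            })
        return pd.DataFrame(rows)


def fit_all_models(
    seed: np.ndarray,
    model_ids: Optional[Iterable[str]] = None,
    options: FitOptions = FitOptions(),
    model_masks: Optional[Dict[str, np.ndarray]] = None,
) -> ModelFitTable:
    """Fit a subset of models (default: all nine) to one seed.

    The best model is the argmax of J; ties break toward the lower model
    ordinal.
    """
    ids = list(model_ids) if model_ids is not None else list(MODEL_IDS)
    if not ids:
        raise ValueError("model_ids must be a non-empty subset of DM1..DM9")
    ids = sorted(set(ids), key=lambda m: MODEL_IDS.index(m))
    table = ModelFitTable()
    for mid in ids:
        mm = model_masks.get(mid) if model_masks else None
        table.results[mid] = fit_model(seed, mid, options, model_mask=mm)
    best = max(ids, key=lambda m: (table.results[m].J, -MODEL_IDS.index(m)))
    table.best_model = best
    return table
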