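"""Synthetic seed masks and composed plates with known ground truth.

Seeds are drawn from one of the DM models by perturbing its boundary
radially with a band-limited harmonic field (outline-shape variation
between seeds, not sensor noise), then applying small affine jitter.
``noise_amplitude`` is the maximum radial displacement as a fraction of
the mean boundary radius; harmonic content defaults to wavenumbers 4–12,
the scale of natural outline variation between seeds of one accession.
Optional "colliculae" add narrow boundary bumps that lengthen the
perimeter (lowering circularity) without touching roundness.

Randomness is driven by one integer seed; each seed of a population uses
an independent counter-indexed substream, so populations are
order-independent and bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon

from .models import boundary_polyline, get_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSeedConfig:
    model_id: str = "DM1"
    noise_amplitude: float = 0.02  # max radial displacement / mean radius
    noise_harmonics: Tuple[int, int] = (4, 12)
    rotation_jitter: float = np.deg2rad(10.0)  # radians, uniform +-
    scale_jitter: float = 0.05  # uniform +- fraction
    translation_jitter: float = 0.03  # fraction of height_px, uniform +-
    colliculae_count: int = 0
    colliculae_size: float = 0.02  # bump height / mean radius
    height_px: int = 160
    rng_seed: int = 0


def _seed_rng(config: SyntheticSeedConfig, index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(config.rng_seed),
                                spawn_key=(int(index),))
    return np.random.default_rng(ss)


def _harmonic_field(theta: np.ndarray, rng: np.random.Generator,
                    kmin: int, kmax: int) -> np.ndarray:
    """Band-limited random field on the circle, normalized to max |f| = 1."""
    f = np.zeros_like(theta)
    for k in range(kmin, kmax + 1):
        a, b = rng.normal(0.0, 1.0 / k, size=2)
        f += a * np.cos(k * theta) + b * np.sin(k * theta)
    peak = np.max(np.abs(f))
    return f / peak if peak > 0 else f


def _perturb_boundary(
    poly: np.ndarray, rng: np.random.Generator, config: SyntheticSeedConfig
) -> np.ndarray:
    """Radial harmonic perturbation about the outline centroid; the
    amplitude is damped (and logged) if the perturbed curve
    self-intersects."""
    pts = poly[:-1]  # drop closing vertex
    centroid = np.asarray(Polygon(pts).centroid.coords[0])
    rel = pts - centroid
    radius = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    rbar = radius.mean()
    kmin, kmax = config.noise_harmonics
    f = _harmonic_field(theta, rng, kmin, kmax)
    bumps = np.zeros_like(theta)
    if config.colliculae_count > 0:
        centers = rng.uniform(-np.pi, np.pi, size=config.colliculae_count)
        width = 0.04  # radians
        for u in centers:
            d = np.angle(np.exp(1j * (theta - u)))
            bumps += np.exp(-0.5 * (d / width) ** 2)
        bumps *= config.colliculae_size * rbar
    eps = config.noise_amplitude
    for attempt in range(6):
        r_new = radius + eps * rbar * f + bumps
        if np.all(r_new > 0):
            cand = centroid + np.stack(
                [r_new * np.cos(theta), r_new * np.sin(theta)], axis=-1)
            if Polygon(cand).is_valid:
                return np.concatenate([cand, cand[:1]], axis=0)
        eps *= 0.5
        logger.info("perturbed outline self-intersects; damping amplitude "
                    "to %.4g", eps)
    return poly


def _fill_polygon(poly_px: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    path = _MplPath(poly_px[:, ::-1])  # (col, row) vertex order
    cgrid, rgrid = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    pts = np.stack([cgrid.ravel(), rgrid.ravel()], axis=-1)
    return path.contains_points(pts).reshape(shape)


def generate_seed(
    config: SyntheticSeedConfig, index: int = 0
) -> Tuple[np.ndarray, dict]:
    """One synthetic seed mask plus its ground-truth record."""
    get_model(config.model_id)
    rng = _seed_rng(config, index)
    poly = boundary_polyline(config.model_id, n=720)
    poly = _perturb_boundary(poly, rng, config)

    rot = float(rng.uniform(-config.rotation_jitter, config.rotation_jitter))
    scale = float(rng.uniform(1.0 - config.scale_jitter,
                              1.0 + config.scale_jitter))
    tmax = config.translation_jitter * config.height_px
    trans = rng.uniform(-tmax, tmax, size=2)

    pts = poly[:-1]
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    # height_px sizes the seed's long axis, whichever direction it runs
    long_side = max(poly[:, 0].max() - poly[:, 0].min(),
                    poly[:, 1].max() - poly[:, 1].min())
    px_per_unit = (config.height_px - 1) / long_side
    cos, sin = np.cos(rot), np.sin(rot)
    rot_mat = np.array([[cos, -sin], [sin, cos]])
    xy = (rel @ rot_mat.T) * px_per_unit * scale

    side = int(np.ceil(config.height_px * 1.5)) + 1
    center = side / 2.0
    rows = center - xy[:, 1] + trans[0]  # y up -> row down
    cols = center + xy[:, 0] + trans[1]
    poly_px = np.stack([rows, cols], axis=-1)
    poly_px = np.concatenate([poly_px, poly_px[:1]], axis=0)
    mask = _fill_polygon(poly_px, (side, side))
    truth = {
        "index": index,
        "model_id": config.model_id,
        "noise_amplitude": config.noise_amplitude,
        "rotation": rot,
        "scale": scale,
        "t_row": float(trans[0]),
        "t_col": float(trans[1]),
        "rng_seed": config.rng_seed,
        "area_px": int(mask.sum()),
    }
    return mask, truth


def generate_population(
    model_id: str, n: int, config: Optional[SyntheticSeedConfig] = None
) -> Tuple[list, pd.DataFrame]:
    """n independent seeds from one model plus their ground-truth table."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    base = config if config is not None else SyntheticSeedConfig()
    base = replace(base, model_id=model_id)
    masks, records = [], []
    for i in range(n):
        m, t = generate_seed(base, index=i)
        masks.append(m)
        records.append(t)
    return masks, pd.DataFrame(records)


def generate_plate(
    masks,
    n_cols: int = 5,
    pad_px: int = 12,
    background: int = 230,
    foreground: int = 40,
    noise_sigma: float = 4.0,
    ruler: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Compose masks into a grayscale plate: dark seeds on a light,
    mildly noisy background, optionally with a ruler-like artifact along
    the bottom border."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ValueError("cannot compose a plate from 0 masks")
    if rng is None:
        rng = np.random.default_rng(0)
    cell_h = max(m.shape[0] for m in masks) + pad_px
    cell_w = max(m.shape[1] for m in masks) + pad_px
    n_rows = int(np.ceil(len(masks) / n_cols))
    h = n_rows * cell_h + pad_px + (30 if ruler else 0)
    w = n_cols * cell_w + pad_px
    plate = np.full((h, w), float(background))
    for i, m in enumerate(masks):
        r = (i // n_cols) * cell_h + pad_px
        c = (i % n_cols) * cell_w + pad_px
        if r + m.shape[0] > h or c + m.shape[1] > w:
            raise ValueError("masks overlap the requested layout; use a "
                             "larger canvas (more columns or padding)")
        sub = plate[r:r + m.shape[0], c:c + m.shape[1]]
        sub[m] = foreground
    if ruler:
        plate[h - 12:h, :] = foreground  # bar touching the border
        for c in range(0, w, 20):
            plate[h - 24:h - 12, c:c + 2] = foreground
    plate += rng.normal(0.0, noise_sigma, size=plate.shape)
    return np.clip(plate, 0, 255).astype(np.uint8)
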