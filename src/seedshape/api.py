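"""Model/Results facade for fitting dorsal geometric models to a seed.

``DorsalModelFit`` is constructed from one seed mask (or an image file);
``fit()`` runs the J-index registration against a set of candidate
models and returns a ``DorsalModelFitResults`` carrying the per-model J
table, the winning model, the morphometric descriptors and the convexity
report, with a ``summary()`` table and an overlay plot.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

from .io import SegmentationConfig, read_and_binarize, segment_plate
from .models import MODEL_IDS
from .morphometry import (DEFAULT_SOLIDITY_THRESHOLD, ConvexityReport,
                          ShapeDescriptors, classify_convexity, measure_mask)
from .registration import (FitOptions, JResult, ModelFitTable, apply_transform,
                           fit_all_models)


class DorsalModelFit:
    """Fit of the dorsal model family to one seed silhouette.

    Parameters
    ----------
    seed_mask : 2D boolean array with a single connected component.
    models : iterable of model ids (default: all of DM1..DM9).
    mm_per_px : physical pixel size for the descriptor block.
    options : registration settings (iteration cap, scale bounds, ...).
    """

    def __init__(
        self,
        seed_mask: np.ndarray,
        models: Optional[Iterable[str]] = None,
        mm_per_px: float = 1.0,
        options: FitOptions = FitOptions(),
        solidity_threshold: float = DEFAULT_SOLIDITY_THRESHOLD,
    ):
        self.seed_mask = np.asarray(seed_mask, dtype=bool)
        self.model_ids = list(models) if models is not None else list(MODEL_IDS)
        self.mm_per_px = mm_per_px
        self.options = options
        self.solidity_threshold = solidity_threshold

    @classmethod
    def from_image(
        cls,
        path,
        config: SegmentationConfig = SegmentationConfig(),
        seed_index: int = 0,
        **kwargs,
    ) -> "DorsalModelFit":
        """Build from an image file; for plates, pick one segmented seed."""
        _img, mask = read_and_binarize(path, config)
        seeds, _prov = segment_plate(mask, config)
        return cls(seeds[seed_index], **kwargs)

    def fit(self) -> "DorsalModelFitResults":
        table = fit_all_models(self.seed_mask, self.model_ids, self.options)
        desc = measure_mask(self.seed_mask, self.mm_per_px)
        conv = classify_convexity(self.seed_mask, self.solidity_threshold)
        return DorsalModelFitResults(self, table, desc, conv)


class DorsalModelFitResults:
    """J-index table, best model, descriptors and convexity of one seed."""

    def __init__(
        self,
        model: DorsalModelFit,
        table: ModelFitTable,
        descriptors: ShapeDescriptors,
        convexity: ConvexityReport,
    ):
        self.model = model
        self.table = table
        self.descriptors = descriptors
        self.convexity = convexity

    @property
    def best_model(self) -> str:
        return self.table.best_model

    @property
    def best_result(self) -> JResult:
        return self.table.results[self.table.best_model]

    @property
    def j_values(self) -> Dict[str, float]:
        return {m: r.J for m, r in self.table.results.items()}

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.to_dataframe()

    def summary(self) -> str:
        d = self.descriptors
        br = self.best_result
        lines = [
            "Dorsal model fit",
            "=" * 52,
            f"best model      {self.best_model:>8}   "
            f"J = {br.J:6.2f}  ({'good' if br.good_fit() else 'poor'} fit, "
            f"S={br.S}, T={br.T})",
            f"convexity       {self.convexity.label:>8}   "
            f"solidity = {self.convexity.solidity:.3f} "
            f"(threshold {self.convexity.threshold_used:.2f})",
            "-" * 52,
            f"A = {d.A:8.4f}  P = {d.P:8.4f}  L = {d.L:8.4f}  "
            f"W = {d.W:8.4f}",
            f"AR = {d.AR:7.3f}  C = {d.C:7.3f}  R = {d.R:7.3f}",
            "-" * 52,
            f"{'model':>6} {'J':>7} {'S':>9} {'T':>9} {'scale':>7} "
            f"{'phi_deg':>8} {'flip':>5}",
        ]
        for mid in sorted(self.table.results,
                          key=lambda m: MODEL_IDS.index(m)):
            r = self.table.results[mid]
            t = r.transform
            mark = " *" if mid == self.best_model else "  "
            lines.append(
                f"{mid:>6} {r.J:7.2f} {r.S:9d} {r.T:9d} {t.s:7.3f} "
                f"{np.degrees(t.phi):8.2f} {str(t.flip):>5}{mark}"
            )
        return "\n".join(lines)

    def plot_overlay(self, model_id: Optional[str] = None, ax=None):
        """Seed silhouette with the fitted model outline superimposed."""
        import matplotlib.pyplot as plt
        from .models import rasterize_model

        mid = model_id or self.best_model
        r = self.table.results[mid]
        model_mask = rasterize_model(mid, height_px=max(
            int(np.ptp(np.argwhere(self.model.seed_mask), axis=0).max()) + 1,
            16), margin_px=2)
        fitted = apply_transform(model_mask, r.transform,
                                 self.model.seed_mask.shape)
        if ax is None:
            _fig, ax = plt.subplots()
        ax.imshow(self.model.seed_mask, cmap="gray")
        ax.contour(fitted.astype(float), levels=[0.5], colors="red")
        ax.set_title(f"{mid}: J = {r.J:.1f}")
        ax.set_axis_off()
        return ax
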