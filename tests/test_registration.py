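"""J index, alignment initialization and model fitting."""

import numpy as np
import pytest

from seedshape.registration import (FitOptions, SimilarityTransform,
                                    apply_transform, fit_all_models,
                                    fit_model, initial_alignment,
                                    jaccard_percent, refine)
from seedshape.synthetic import SyntheticSeedConfig, generate_seed


def _counts_masks(shared: int, union: int):
    """Two rectangles with |a & b| = shared, |a | b| = union."""
    width = 512
    rows = union // width + 2
    a = np.zeros((rows, width), bool)
    b = np.zeros((rows, width), bool)
    a.ravel()[:union] = True
    b.ravel()[:shared] = True
    return a, b


class TestJaccard:
    def test_worked_example_pixel_counts(self):
        # S = 39,998 px and T = 44,223 px give J = 90.4 to one decimal
        a, b = _counts_masks(39998, 44223)
        assert round(jaccard_percent(a, b), 1) == 90.4

    def test_identical_masks_give_100(self, disk_mask):
        m = disk_mask(50)
        assert jaccard_percent(m, m) == 100.0

    def test_disjoint_masks_give_0(self):
        a = np.zeros((40, 40), bool)
        b = np.zeros((40, 40), bool)
        a[5:15, 5:15] = True
        b[25:35, 25:35] = True
        assert jaccard_percent(a, b) == 0.0

    def test_symmetric(self, disk_mask, ellipse_mask):
        a = disk_mask(60, pad=160)
        b = np.zeros_like(a)
        e = ellipse_mask(100, 50)
        b[:e.shape[0], :e.shape[1]] = e
        assert jaccard_percent(a, b) == jaccard_percent(b, a)

    def test_empty_union_is_an_error(self):
        z = np.zeros((10, 10), bool)
        with pytest.raises(ValueError, match="empty"):
            jaccard_percent(z, z)

    def test_grid_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="grid"):
            jaccard_percent(np.ones((5, 5), bool), np.ones((6, 5), bool))


class TestInitialAlignment:
    def test_self_alignment_is_identity(self, raster):
        m = raster("DM3", 150, 20)
        tr = initial_alignment(m, m)
        assert abs(tr.tx) <= 0.5 and abs(tr.ty) <= 0.5
        assert tr.s == pytest.approx(1.0, abs=0.005)
        assert abs(np.degrees(tr.phi)) <= 1.0 or \
            abs(abs(np.degrees(tr.phi)) - 180) <= 1.0

    def test_translation_recovery(self, raster):
        m = raster("DM3", 150, 40)
        seed = np.roll(np.roll(m, 30, axis=0), -12, axis=1)
        tr = initial_alignment(seed, m)
        assert tr.ty == pytest.approx(30, abs=0.5)
        assert tr.tx == pytest.approx(-12, abs=0.5)

    def test_scale_recovery(self, raster):
        from scipy import ndimage
        m = raster("DM3", 120, 50)
        seed = ndimage.zoom(m.astype(float), 1.5, order=1,
                            prefilter=False) > 0.5
        pad = [(0, m.shape[0] * 2 - seed.shape[0]),
               (0, m.shape[1] * 2 - seed.shape[1])]
        seed = np.pad(seed, pad)
        tr = initial_alignment(seed, m)
        assert tr.s == pytest.approx(1.5, rel=0.01)

    def test_near_circular_orientation_defaults_to_zero(self, disk_mask):
        m = disk_mask(60)
        tr = initial_alignment(m, m)
        assert tr.phi == pytest.approx(0.0, abs=1e-9)


class TestTransforms:
    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            SimilarityTransform(s=-1.0)

    def test_phi_normalized(self):
        tr = SimilarityTransform(phi=3 * np.pi)
        assert -np.pi < tr.phi <= np.pi

    def test_identity_transform_reproduces_mask(self, raster):
        m = raster("DM6", 120, 10)
        out = apply_transform(m, SimilarityTransform(), m.shape)
        assert jaccard_percent(m, out) == 100.0


class TestFit:
    def test_self_fit_recovers_high_overlap(self, raster):
        seed = raster("DM4", 140, 20)
        res = fit_model(seed, "DM4")
        assert res.J >= 99.0
        assert res.J == pytest.approx(100.0 * res.S / res.T)
        assert res.good_fit()

    def test_refinement_never_below_start(self, raster):
        seed = raster("DM5", 110, 15)
        model = raster("DM6", 110, 4)
        start = initial_alignment(seed, model)
        j_start = jaccard_percent(seed,
                                  apply_transform(model, start, seed.shape))
        _tr, j_ref, _conv = refine(seed, model, start)
        assert j_ref >= j_start

    def test_rigid_motion_of_seed_leaves_j_invariant(self):
        config = SyntheticSeedConfig(model_id="DM5", rng_seed=21,
                                     height_px=120)
        seed, _ = generate_seed(config, 0)
        j0 = fit_model(seed, "DM5").J
        j90 = fit_model(np.rot90(seed), "DM5").J
        assert abs(j0 - j90) <= 0.5

    def test_iteration_cap_flags_nonconvergence(self, raster):
        seed = raster("DM2", 100, 12)
        res = fit_model(seed, "DM3", FitOptions(maxiter=3))
        assert res.converged is False

    def test_fit_all_sorted_and_tiebreak(self):
        config = SyntheticSeedConfig(model_id="DM7", rng_seed=4,
                                     height_px=110)
        seed, _ = generate_seed(config, 0)
        table = fit_all_models(seed, ["DM9", "DM7", "DM5"])
        df = table.to_dataframe()
        assert list(df["model"]) == ["DM5", "DM7", "DM9"]
        assert table.best_model == "DM7"

    def test_single_model_subset(self, raster):
        seed = raster("DM5", 100, 10)
        table = fit_all_models(seed, ["DM5"])
        assert len(table.results) == 1
        assert table.best_model == "DM5"

    def test_empty_subset_rejected(self, raster):
        with pytest.raises(ValueError, match="non-empty"):
            fit_all_models(raster("DM5", 100, 10), [])

    def test_multi_component_seed_rejected(self):
        two = np.zeros((80, 80), bool)
        two[5:30, 5:30] = True
        two[50:75, 50:75] = True
        with pytest.raises(ValueError, match="components"):
            fit_model(two, "DM1")
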