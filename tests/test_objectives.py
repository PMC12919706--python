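"""Loss functions: similarity, uncertainty weighting, Dice, bending energy."""

import numpy as np
import pytest

from gridreg import (GriddedDisplacementField, ImageVolume, LossWeights,
                     MaskVolume, UpsamplerConfig, bending_energy, dice_loss,
                     make_control_grid, similarity_image, total_loss,
                     uncertainty_loss)
from gridreg._tensor import Tensor


class TestSimilarity:
    def test_identical_images_zero(self, rng):
        v = ImageVolume(rng.random((6, 6, 6)))
        assert similarity_image(v, v) == 0.0

    def test_constant_offset_gives_squared_constant(self, rng):
        a = rng.random((6, 6, 6))
        assert similarity_image(ImageVolume(a), ImageVolume(a + 0.3)) \
            == pytest.approx(0.09, rel=1e-12)

    def test_matches_explicit_loop(self, rng):
        a, b = rng.random((8, 8, 8)), rng.random((8, 8, 8))
        acc = 0.0
        for x in range(8):
            for y in range(8):
                for z in range(8):
                    acc += (a[x, y, z] - b[x, y, z]) ** 2
        assert similarity_image(ImageVolume(a), ImageVolume(b)) \
            == pytest.approx(acc / 512, rel=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            similarity_image(ImageVolume(rng.random((4, 4, 4))),
                             ImageVolume(rng.random((5, 5, 5))))


def _unit_var_setup(rng, shape=(8, 8, 8), grid_size=(3, 3, 3), disp=0.0):
    grid = make_control_grid(shape, grid_size)
    vec = np.full((3,) + grid_size, disp)
    sample = GriddedDisplacementField(grid=grid, vectors=vec)
    var = np.ones((3,) + grid_size)
    moving = ImageVolume(rng.random(shape))
    fixed = ImageVolume(rng.random(shape))
    return moving, fixed, sample, var


class TestUncertaintyLoss:
    def test_unit_variance_reduces_to_half_mse(self, rng):
        moving, fixed, sample, var = _unit_var_setup(rng)
        w = LossWeights(lambda0=0.0)
        loss = uncertainty_loss(moving, fixed, [sample], var,
                                UpsamplerConfig(), w)
        expect = 0.5 * np.mean((moving.data - fixed.data) ** 2)
        assert loss.item() == pytest.approx(expect, rel=1e-6)

    def test_zero_residual_leaves_log_variance_term(self, rng):
        moving, _, sample, _ = _unit_var_setup(rng)
        var = np.full((3, 3, 3, 3), 2.0)
        w = LossWeights(lambda0=0.05)
        loss = uncertainty_loss(moving, moving, [sample], var,
                                UpsamplerConfig(), w)
        assert loss.item() == pytest.approx(0.05 * np.log(2.0), rel=1e-6)

    def test_duplicate_samples_equal_single(self, rng):
        moving, fixed, sample, var = _unit_var_setup(rng, disp=0.4)
        w = LossWeights(lambda0=0.01)
        l1 = uncertainty_loss(moving, fixed, [sample], var,
                              UpsamplerConfig(), w)
        l2 = uncertainty_loss(moving, fixed, [sample, sample], var,
                              UpsamplerConfig(), w)
        assert l1.item() == pytest.approx(l2.item(), rel=1e-7)

    def test_nonpositive_variance_rejected(self, rng):
        moving, fixed, sample, var = _unit_var_setup(rng)
        var[0, 0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            uncertainty_loss(moving, fixed, [sample], var,
                             UpsamplerConfig(), LossWeights())

    def test_stationary_variance_matches_closed_form(self):
        """d/d(sigma^2) [r^2/(2 s) + lam0 log s] = 0 at s = r^2/(2 lam0)."""
        r2, lam0 = 0.3, 0.05
        s_grid = np.linspace(0.5, 6.0, 2000)
        vals = r2 / (2 * s_grid) + lam0 * np.log(s_grid)
        s_star = s_grid[np.argmin(vals)]
        assert s_star == pytest.approx(r2 / (2 * lam0), rel=1e-2)

    def test_mc_variance_shrinks_with_sample_count(self, rng):
        """Loss variance across seeds decays roughly like 1/S."""
        from gridreg.network import sample_transform, BayesianGridOutput

        grid = make_control_grid((8, 8, 8), (3, 3, 3))
        mu = GriddedDisplacementField(grid=grid,
                                      vectors=np.zeros((3, 3, 3, 3)))
        out = BayesianGridOutput(mean=mu, raw_var=np.zeros((3, 3, 3, 3)),
                                 var=np.full((3, 3, 3, 3), 0.5))
        moving = ImageVolume(rng.random((8, 8, 8)))
        fixed = ImageVolume(rng.random((8, 8, 8)))
        w = LossWeights(lambda0=0.0)
        var_by_S = {}
        for S in (1, 4, 16):
            vals = []
            for seed in range(24):
                samples = sample_transform(out, S, seed=seed)
                loss = uncertainty_loss(moving, fixed, samples, out.var,
                                        UpsamplerConfig(), w)
                vals.append(loss.item())
            var_by_S[S] = np.var(vals)
        assert var_by_S[4] < var_by_S[1]
        assert var_by_S[16] < var_by_S[4]
        # roughly 1/S: a factor-16 sample increase cuts variance >= 4x
        assert var_by_S[16] < var_by_S[1] / 4


class TestDiceLoss:
    def test_identical_masks_near_zero(self):
        m = np.zeros((6, 6, 6)); m[2:5, 2:5, 2:5] = 1
        assert dice_loss(MaskVolume(m), MaskVolume(m), eps=1e-9) \
            == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_masks_one(self):
        a = np.zeros((6, 6, 6)); a[:2] = 1
        b = np.zeros((6, 6, 6)); b[4:] = 1
        assert dice_loss(MaskVolume(a), MaskVolume(b)) \
            == pytest.approx(1.0, abs=1e-4)

    def test_half_overlap_cubes(self):
        """4^3 cubes overlapping in a 2x4x4 slab: Dice loss ~ 0.5."""
        a = np.zeros((10, 10, 10)); a[0:4, 0:4, 0:4] = 1
        b = np.zeros((10, 10, 10)); b[2:6, 0:4, 0:4] = 1
        eps = 1e-7
        expect = 1 - 2 * 32 / (64 + 64 + eps)
        assert dice_loss(MaskVolume(a), MaskVolume(b), eps=eps) \
            == pytest.approx(expect, abs=1e-6)

    def test_identity_minimizes(self, rng):
        a = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        b = (rng.random((8, 8, 8)) > 0.6).astype(np.uint8)
        assert dice_loss(MaskVolume(a), MaskVolume(a)) <= dice_loss(
            MaskVolume(a), MaskVolume(b))


class TestBendingEnergy:
    def test_zero_and_affine_fields_have_no_energy(self, rng):
        assert bending_energy(np.zeros((3, 9, 9, 9))) == 0.0
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            b = rng.normal(size=3)
            grids = np.stack(np.meshgrid(*[np.arange(9.0)] * 3,
                                         indexing="ij"))
            aff = np.einsum("ij,jxyz->ixyz", A, grids) + b[:, None, None,
                                                           None]
            assert bending_energy(aff) <= 1e-10

    def test_quadratic_field_closed_form(self):
        """t_x = x^2: interior d2/dx2 = 2, energy = 4 * interior fraction."""
        grids = np.stack(np.meshgrid(*[np.arange(9.0)] * 3, indexing="ij"))
        vec = np.zeros((3, 9, 9, 9))
        vec[0] = grids[0] ** 2
        expect = 4.0 * (7 ** 3) / (9 ** 3)
        assert bending_energy(vec) == pytest.approx(expect, abs=1e-8)

    def test_matches_explicit_loop(self, rng):
        vec = rng.normal(size=(3, 5, 5, 5))
        acc = 0.0
        for c in range(3):
            for x in range(1, 4):
                for y in range(1, 4):
                    for z in range(1, 4):
                        v = vec[c]
                        dxx = v[x+1, y, z] - 2*v[x, y, z] + v[x-1, y, z]
                        dyy = v[x, y+1, z] - 2*v[x, y, z] + v[x, y-1, z]
                        dzz = v[x, y, z+1] - 2*v[x, y, z] + v[x, y, z-1]
                        dxy = (v[x+1, y+1, z] - v[x+1, y-1, z]
                               - v[x-1, y+1, z] + v[x-1, y-1, z]) / 4
                        dxz = (v[x+1, y, z+1] - v[x+1, y, z-1]
                               - v[x-1, y, z+1] + v[x-1, y, z-1]) / 4
                        dyz = (v[x, y+1, z+1] - v[x, y+1, z-1]
                               - v[x, y-1, z+1] + v[x, y-1, z-1]) / 4
                        acc += (dxx**2 + dyy**2 + dzz**2
                                + 2 * (dxy**2 + dxz**2 + dyz**2))
        assert bending_energy(vec) == pytest.approx(acc / 125, rel=1e-10)

    def test_affine_invariance(self, rng):
        vec = rng.normal(size=(3, 9, 9, 9))
        A = rng.normal(size=(3, 3))
        grids = np.stack(np.meshgrid(*[np.arange(9.0)] * 3, indexing="ij"))
        aff = np.einsum("ij,jxyz->ixyz", A, grids)
        assert bending_energy(vec + aff) == pytest.approx(
            bending_energy(vec), abs=1e-8)

    def test_small_axis_raises(self):
        with pytest.raises(ValueError):
            bending_energy(np.zeros((3, 2, 9, 9)))


class TestTotalLoss:
    def test_masks_unavailable_drops_dice(self):
        comps = {"uncertainty": 0.4, "dice": 0.7, "bending": 0.1}
        w = LossWeights(lambda1=1.0, lambda2=5.0, lambda3=2.0)
        total, rep = total_loss(comps, w, masks_available=False)
        assert rep.dice_term == 0.0
        assert total == pytest.approx(0.4 + 0.2)

    def test_all_zero_weights_zero_total(self):
        comps = {"uncertainty": 0.4, "dice": 0.7, "bending": 0.1}
        w = LossWeights(lambda0=0, lambda1=0, lambda2=0, lambda3=0)
        total, rep = total_loss(comps, w)
        assert total == 0.0

    def test_itemized_report_sums(self, rng):
        comps = {"uncertainty": Tensor(np.array(0.3)),
                 "dice": Tensor(np.array(0.2)),
                 "bending": Tensor(np.array(0.05))}
        w = LossWeights(lambda1=1.0, lambda2=0.5, lambda3=2.0)
        total, rep = total_loss(comps, w)
        assert rep.total == pytest.approx(
            w.lambda1 * rep.uncertainty_term + w.lambda2 * rep.dice_term
            + w.lambda3 * rep.bending_term, abs=1e-6)
        assert total.item() == pytest.approx(rep.total)
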