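"""Tests for DREAM map derivation, spherical-basis fitting and bias correction."""

import numpy as np
import pytest

import persardose.bias as B
from persardose.synth import (
    PhantomSpec,
    make_phantom,
    make_synthetic_b1,
    simulate_dream,
    simulate_t1w,
)
from persardose.volumes import ImageVolume


@pytest.fixture(scope="module")
def phantom():
    return make_phantom(PhantomSpec(shape=(40, 40, 40), seed=2))


@pytest.fixture(scope="module")
def dream_pair(phantom):
    b1, m0 = make_synthetic_b1(phantom, neck_dropoff_strength=0.4, seed=3)
    ste, fid = simulate_dream(b1, m0)
    return b1, m0, ste, fid


def _uniform(phantom, value):
    return ImageVolume(np.full(phantom.shape, float(value)), phantom.voxel_size)


class TestDreamMaps:
    def test_half_ratio_gives_45_degrees(self, phantom):
        """STE/FID = 1/2 means tan^2(alpha) = 1, i.e. alpha = 45 deg."""
        ste = _uniform(phantom, 1.0)
        fid = _uniform(phantom, 2.0)
        maps = B.dream_maps(ste, fid, steam_angle=50.0)
        assert np.allclose(maps.b1plus.grid, 45.0 / 50.0)

    def test_zero_ste_gives_zero_flip(self, phantom):
        maps = B.dream_maps(_uniform(phantom, 0.0), _uniform(phantom, 1.0))
        assert np.allclose(maps.b1plus.grid, 0.0)

    def test_roundtrip_recovers_known_b1(self, dream_pair, phantom):
        b1, m0, ste, fid = dream_pair
        maps = B.dream_maps(ste, fid, mask=phantom.body_mask())
        body = phantom.body_mask()
        assert np.abs(maps.b1plus.grid - b1.grid)[body].max() < 1e-10
        rel = np.abs(maps.m0b1minus.grid - m0.grid)[body] / m0.grid[body]
        assert rel.max() < 1e-10

    def test_nonpositive_fid_voxels_dropped_from_mask(self, phantom):
        ste = _uniform(phantom, 1.0)
        fid = _uniform(phantom, 2.0)
        fid.grid[0, 0, 0] = -1.0
        maps = B.dream_maps(ste, fid)
        assert not maps.mask[0, 0, 0]
        assert maps.mask.sum() == maps.mask.size - 1


class TestSphericalBasisFit:
    def test_constant_map_order_zero(self, phantom):
        fit = B.fit_spherical_basis(_uniform(phantom, 3.0), phantom.body_mask(), 0)
        assert np.allclose(fit.fitted_map.grid, 3.0, atol=1e-10)

    def test_degree_two_harmonic_reproduced(self, phantom):
        """A pure degree-2 solid harmonic lies in the basis span: the
        order-2 fit must reproduce it to solver precision."""
        idx = np.indices(phantom.shape).astype(float)
        x, y, z = (idx[i] - phantom.shape[i] / 2 for i in range(3))
        harm = x * y + 0.5 * (2 * z**2 - x**2 - y**2) / 30.0
        vol = ImageVolume(harm / np.abs(harm).max(), phantom.voxel_size)
        mask = phantom.body_mask()
        fit = B.fit_spherical_basis(vol, mask, 2)
        assert np.abs(fit.fitted_map.grid - vol.grid)[mask].max() < 1e-8

    def test_noise_suppression(self, phantom):
        """Fitting a harmonic plus 10% voxel noise recovers the clean map
        with RMSE < noise/5: the fit averages ~mask/n_basis voxels per DOF."""
        rng = np.random.default_rng(4)
        idx = np.indices(phantom.shape).astype(float)
        x = (idx[0] - 20.0) / 20.0
        clean = 1.0 + 0.5 * x
        noisy = ImageVolume(clean + 0.1 * rng.standard_normal(phantom.shape), phantom.voxel_size)
        mask = phantom.body_mask()
        fit = B.fit_spherical_basis(noisy, mask, 2)
        rmse = np.sqrt(np.mean((fit.fitted_map.grid - clean)[mask] ** 2))
        assert rmse < 0.1 / 5

    def test_degenerate_mask_rejected(self, phantom):
        mask = np.zeros(phantom.shape, dtype=bool)
        mask[5, 5, 5:9] = True  # collinear points cannot support order 2
        vol = _uniform(phantom, 1.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            B.fit_spherical_basis(vol, mask, 2)
        with pytest.raises(ValueError, match="empty"):
            B.fit_spherical_basis(vol, np.zeros(phantom.shape, bool), 2)

    def test_residual_nonincreasing_in_order(self, dream_pair, phantom):
        _, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        resids = [
            B.fit_spherical_basis(m0, mask, order).residual_norm for order in (0, 2, 4, 6)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(resids, resids[1:]))


class TestBiasFieldModels:
    def _maps(self, phantom, b1val, m0val):
        return B.B1Maps(
            _uniform(phantom, b1val), _uniform(phantom, m0val), phantom.body_mask(), fitted=True
        )

    def test_uniform_maps_give_unit_field(self, phantom):
        for make in (B.bias_field_gre, B.bias_field_fse):
            field = make(self._maps(phantom, 1.0, 7.0))
            assert np.allclose(field.field.grid[field.mask], 1.0)

    def test_mean_one_normalization(self, dream_pair, phantom):
        b1, m0, _, _ = dream_pair
        maps = B.B1Maps(b1, m0, phantom.body_mask(), fitted=True)
        for make in (B.bias_field_gre, B.bias_field_fse):
            f = make(maps)
            assert abs(f.field.grid[f.mask].mean() - 1.0) < 1e-12

    def test_small_angle_limit_proportional_to_b1_product(self, dream_pair, phantom):
        """At tau_gamma -> 0 the GRE bias tends to B1+ * B1- (both
        mean-normalized); proportionality holds to < 0.1% at 0.01 rad."""
        b1, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        maps = B.B1Maps(b1, m0, mask, fitted=True)
        f = B.bias_field_gre(maps, tau_gamma=0.01)
        prod = b1.grid * m0.grid
        prod = prod / prod[mask].mean()
        rel = np.abs(f.field.grid - prod)[mask] / prod[mask]
        assert rel.max() < 1e-3

    def test_receive_scaling_invariance(self, dream_pair, phantom):
        b1, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        f1 = B.bias_field_gre(B.B1Maps(b1, m0, mask, fitted=True))
        m0x2 = ImageVolume(2.0 * m0.grid, m0.voxel_size)
        f2 = B.bias_field_gre(B.B1Maps(b1, m0x2, mask, fitted=True))
        assert np.allclose(f1.field.grid, f2.field.grid)

    def test_fse_is_cubed_sine(self, dream_pair, phantom):
        """Pointwise, (unnormalized FSE)/(unnormalized GRE) = sin^2; after
        mean-1 normalization the ratio of ratios is constant."""
        b1, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        maps = B.B1Maps(b1, m0, mask, fitted=True)
        tau = np.deg2rad(10.0)
        gre = B.bias_field_gre(maps, tau).field.grid[mask]
        fse = B.bias_field_fse(maps, tau).field.grid[mask]
        s2 = np.sin(tau * b1.grid[mask]) ** 2
        ratio = (fse / gre) / s2
        assert np.allclose(ratio, ratio[0])

    def test_fse_monotone_on_rising_limb(self, phantom):
        tau = np.deg2rad(10.0)
        b1v = np.linspace(0.1, 2.0, 20)
        unnorm = np.sin(tau * b1v) ** 3
        assert np.all(np.diff(unnorm) > 0)


class TestCorrectImage:
    def test_unit_bias_leaves_image_unchanged_in_mask(self, phantom):
        rng = np.random.default_rng(5)
        img = ImageVolume(rng.random(phantom.shape), phantom.voxel_size)
        maps = B.B1Maps(
            _uniform(phantom, 1.0), _uniform(phantom, 1.0), phantom.body_mask(), fitted=True
        )
        bias = B.bias_field_gre(maps)
        out = B.correct_image(img, bias)
        assert np.allclose(out.grid[bias.mask], img.grid[bias.mask])
        assert np.all(out.grid[~bias.mask] == 0)

    def test_forward_inverse_recovers_clean_image(self, dream_pair, phantom):
        b1, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        bias = B.bias_field_gre(B.B1Maps(b1, m0, mask, fitted=True))
        clean = simulate_t1w(phantom, _uniform(phantom, 1.0), 0.0, 0)
        biased = ImageVolume(clean.grid * bias.field.grid, phantom.voxel_size)
        out = B.correct_image(biased, bias, floor=1e-9)
        assert np.abs(out.grid - clean.grid)[mask].max() < 1e-10

    def test_roundtrip_is_piecewise_constant(self, dream_pair, phantom):
        """simulate_t1w with a bias then correct_image with the same bias
        returns a per-tissue constant image to < 1e-8 relative."""
        b1, m0, _, _ = dream_pair
        mask = phantom.body_mask()
        bias = B.bias_field_gre(B.B1Maps(b1, m0, mask, fitted=True))
        img = simulate_t1w(phantom, bias.field, 0.0, 0)
        out = B.correct_image(img, bias, floor=1e-9)
        for code in range(1, 9):
            m = (phantom.grid == code) & mask
            vals = out.grid[m]
            if vals.size:
                assert np.abs(vals - vals.mean()).max() < 1e-8 * max(vals.mean(), 1e-12)

    def test_geometry_mismatch_rejected(self, phantom):
        img = ImageVolume(np.ones((8, 8, 8)))
        maps = B.B1Maps(
            _uniform(phantom, 1.0), _uniform(phantom, 1.0), phantom.body_mask(), fitted=True
        )
        bias = B.bias_field_gre(maps)
        with pytest.raises(Exception):
            B.correct_image(img, bias)


class TestFullCorrectionPipeline:
    def test_within_tissue_cv_reduction(self, phantom):
        """Severe known GRE bias + 5%-of-typical-signal noise: estimating
        the bias from the DREAM pair and dividing it out must cut the
        pooled within-tissue CV at least five-fold."""
        b1, m0 = make_synthetic_b1(phantom, neck_dropoff_strength=0.4, seed=13)
        body = phantom.body_mask()
        truth = B.bias_field_gre(B.B1Maps(b1, m0, body, fitted=True))
        img = simulate_t1w(
            phantom, truth.field, noise_sd=0.025, seed=7, noise_profile=m0.grid
        )
        ste, fid = simulate_dream(b1, m0)
        est = B.estimate_bias_field(ste, fid, kind="gre", order=6, mask=body)
        corr = B.correct_image(img, est)
        cv_before = B.within_tissue_cv(img, phantom)
        cv_after = B.within_tissue_cv(corr, phantom)
        assert cv_after <= cv_before / 5.0
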