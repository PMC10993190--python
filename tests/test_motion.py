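import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings
from hypothesis import strategies as st

from respmoco import trajectory as tj
from respmoco import phantom as ph
from respmoco import motion as mo
from conftest import smooth_velocity


class TestRegisterInavs:
    def test_identical_inavs_give_zero(self):
        img = ndi.gaussian_filter(np.random.default_rng(0).normal(size=(40, 40)), 3)
        t = mo.register_inavs(np.stack([img] * 5))
        np.testing.assert_allclose(t.t_mm, 0.0, atol=1e-9)

    def test_known_shift_recovered(self):
        spec = ph.default_phantom(nonrigid=0.0, nonrigid2_mm=0.0, shear_ap=0.0)
        vol = ph.render_phantom(spec, 0.0)
        navs = np.stack(
            [
                ph.simulate_inav(vol, (s, 0.0), voxel_mm=(2.0, 2.0))
                for s in (0.0, 3.0, 0.0, 3.0)
            ]
        )
        t = mo.register_inavs(navs, pixel_mm=(2.0, 2.0))
        spread = t.fh.max() - t.fh.min()
        assert abs(spread - 3.0) < 0.5

    def test_zero_mean_after_rereferencing(self):
        rng = np.random.default_rng(3)
        base = ndi.gaussian_filter(rng.normal(size=(40, 40)), 3)
        navs = np.stack([np.roll(base, s, axis=0) for s in (0, 2, 4, 1)])
        t = mo.register_inavs(navs)
        np.testing.assert_allclose(t.t_mm.mean(axis=0), 0.0, atol=1e-9)

    def test_flat_inavs_fail(self):
        with pytest.raises(ValueError):
            mo.register_inavs(np.zeros((3, 20, 20)))


class TestPhaseCorrect:
    @pytest.fixture()
    def moving(self):
        spec = ph.default_phantom(nonrigid=0.0, nonrigid2_mm=0.0, shear_ap=0.0,
                                  amp_fh_mm=6.0, noise_sd=0.0, n_coils=2)
        traj = tj.full_trajectory(tj.GridSpec(32, 16), 4, rectangular=True)
        kdata, gt = ph.simulate_acquisition(spec, traj, np.array([0, 1, 0, 1.0]), seed=2)
        return kdata, gt

    def test_zero_translation_is_bitwise_identity(self, moving):
        kdata, _ = moving
        t = mo.RespTranslations(np.zeros((4, 2)))
        out = mo.phase_correct(kdata, t)
        np.testing.assert_array_equal(out.data, kdata.data)

    def test_magnitude_preserved(self, moving):
        kdata, gt = moving
        out = mo.phase_correct(kdata, gt.translations)
        np.testing.assert_allclose(np.abs(out.data), np.abs(kdata.data), rtol=1e-12)

    def test_length_mismatch_rejected(self, moving):
        kdata, _ = moving
        with pytest.raises(ValueError):
            mo.phase_correct(kdata, mo.RespTranslations(np.zeros((7, 2))))


class TestBinning:
    def test_default_four_equal_bins(self):
        t = mo.RespTranslations(np.c_[np.linspace(-5, 5, 100), np.zeros(100)])
        bins = mo.bin_heartbeats(t)
        assert bins.n_bins == 4
        assert np.bincount(bins.primary).tolist() == [25, 25, 25, 25]

    @given(n=st.integers(5, 97), n_bins=st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_primary_counts_differ_by_at_most_one(self, n, n_bins):
        rng = np.random.default_rng(n * 7 + n_bins)
        t = mo.RespTranslations(np.c_[rng.normal(size=n), np.zeros(n)])
        bins = mo.bin_heartbeats(t, n_bins, 0.5)
        counts = np.bincount(bins.primary, minlength=n_bins)
        assert counts.max() - counts.min() <= 1
        assert (bins.weights >= 0).all() and (bins.weights <= 1).all()
        assert (bins.weights.max(axis=1) == 1.0).all()

    def test_hard_gating_limit_is_one_hot(self):
        rng = np.random.default_rng(0)
        t = mo.RespTranslations(np.c_[rng.normal(size=20), np.zeros(20)])
        bins = mo.bin_heartbeats(t, 4, softness=0.0)
        assert np.array_equal(bins.weights.sum(axis=1), np.ones(20))
        assert (bins.weights[np.arange(20), bins.primary] == 1.0).all()

    def test_end_expiration_is_extremal_bin(self):
        t = mo.RespTranslations(np.c_[np.linspace(-5, 5, 40), np.zeros(40)])
        bins = mo.bin_heartbeats(t, 4, 0.5, end_exp_sign=-1.0)
        assert bins.end_exp_bin == int(np.argmin(bins.bin_centers))

    def test_fewer_heartbeats_than_bins(self):
        t = mo.RespTranslations(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mo.bin_heartbeats(t, 4)


class TestIntegrateVelocity:
    def test_zero_velocity_gives_identity(self):
        fwd, inv = mo.integrate_velocity(np.zeros((3, 6, 6, 4)))
        assert not fwd.any() and not inv.any()

    def test_constant_velocity_is_translation(self):
        v = np.zeros((3, 12, 12, 8))
        v[0] = 1.5
        fwd, inv = mo.integrate_velocity(v, 6)
        interior = (slice(None), slice(3, -3), slice(3, -3), slice(2, -2))
        np.testing.assert_allclose(fwd[interior][0], 1.5, atol=1e-6)
        np.testing.assert_allclose(inv[interior][0], -1.5, atol=1e-6)

    def test_inverse_consistency_and_positive_jacobian(self, rng):
        v = smooth_velocity((16, 16, 12), rng, sigma=3.0, scale=6.0)
        fwd, inv = mo.integrate_velocity(v, 6)
        comp = inv + mo.warp(fwd, inv)
        assert np.abs(comp).mean() < 0.1
        grads = np.stack([np.stack(np.gradient(fwd[i], axis=(0, 1, 2))) for i in range(3)])
        jac = np.moveaxis(grads + np.eye(3).reshape(3, 3, 1, 1, 1), (0, 1), (-2, -1))
        det = np.linalg.det(jac)[1:-1, 1:-1, 1:-1]
        assert det.min() > 0

    def test_nonfinite_velocity_rejected(self):
        v = np.zeros((3, 4, 4, 4))
        v[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            mo.integrate_velocity(v)


class TestWarp:
    def test_identity(self, rng):
        x = rng.normal(size=(6, 5, 4))
        np.testing.assert_array_equal(mo.warp(x, np.zeros((3, 6, 5, 4))), x)

    def test_integer_translation_matches_index_shift(self, rng):
        x = rng.normal(size=(8, 8, 6))
        d = np.zeros((3, 8, 8, 6))
        d[0] = 2.0
        out = mo.warp(x, d)
        np.testing.assert_allclose(out[:6], x[2:], atol=1e-12)

    def test_forward_inverse_roundtrip_on_phantom(self, rng):
        vol = np.abs(ph.render_phantom(ph.default_phantom(), 0.0))
        v = smooth_velocity(vol.shape, rng, sigma=3.0, scale=4.0)
        fwd, inv = mo.integrate_velocity(v, 6)
        back = mo.warp(mo.warp(vol, fwd), inv)
        assert np.abs(back - vol).mean() < 0.02 * (vol.max() - vol.min())

    def test_linear_in_volume(self, rng):
        x = rng.normal(size=(6, 5, 4))
        y = rng.normal(size=(6, 5, 4))
        d = rng.normal(0, 0.7, (3, 6, 5, 4))
        np.testing.assert_allclose(
            mo.warp(2 * x + y, d), 2 * mo.warp(x, d) + mo.warp(y, d), atol=1e-12
        )


class TestWarpAdjoint:
    def test_identity_disp(self, rng):
        x = rng.normal(size=(5, 4, 4))
        np.testing.assert_array_equal(mo.warp_adjoint(x, np.zeros((3, 5, 4, 4))), x)

    def test_inner_product_identity(self, rng):
        for _ in range(10):
            d = rng.normal(0, 0.8, (3, 6, 5, 4))
            x = rng.normal(size=(6, 5, 4)) + 1j * rng.normal(size=(6, 5, 4))
            y = rng.normal(size=(6, 5, 4)) + 1j * rng.normal(size=(6, 5, 4))
            lhs = np.vdot(mo.warp(x, d), y)
            rhs = np.vdot(x, mo.warp_adjoint(y, d))
            assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_explicit_matrix_transpose(self, rng):
        shape = (3, 3, 2)
        n = np.prod(shape)
        d = rng.normal(0, 0.5, (3, *shape))
        fwd_mat = np.zeros((n, n))
        adj_mat = np.zeros((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = 1.0
            fwd_mat[:, i] = mo.warp(e.reshape(shape), d).ravel()
            adj_mat[:, i] = mo.warp_adjoint(e.reshape(shape), d).ravel()
        np.testing.assert_allclose(adj_mat, fwd_mat.T, atol=1e-12)
        # column sums of the forward matrix are the interpolation weight
        # sums, which the adjoint matrix reproduces as row sums
        np.testing.assert_allclose(adj_mat.sum(axis=1), fwd_mat.sum(axis=0), atol=1e-12)
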