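import numpy as np
import pytest

from respmoco import trajectory as tj
from respmoco import phantom as ph
from respmoco import operators as ops
from respmoco.motion import BinWeights, RespTranslations, bin_heartbeats, phase_correct
from conftest import smooth_coils


def dense_matrix(op):
    n = int(np.prod(op.volume_shape))
    cols = []
    for i in range(n):
        e = np.zeros(n, dtype=complex)
        e[i] = 1.0
        cols.append(op.pack(op.apply(e.reshape(op.volume_shape))))
    return np.array(cols).T


class TestEncodingOperator:
    def test_zero_volume_maps_to_zero(self, tiny_motion_operator):
        out = tiny_motion_operator.apply(np.zeros(tiny_motion_operator.volume_shape, complex))
        assert all(np.abs(s).max() == 0 for s in out)

    def test_reduces_to_masked_fft(self, rng):
        """Single uniform coil, binary weights, no motion: E samples the FFT."""
        shape = (4, 8, 8)
        traj = tj.generate_caspr(tj.GridSpec(8, 8), 1.5, n_heartbeats=4, rng_seed=0,
                                 r_center=0.2)
        coils = ph.simulate_coils(shape, 1, mode="uniform", normalize=False)
        bins = BinWeights(np.ones((4, 1)), np.zeros(1), np.zeros(4, int), 0)
        op = ops.EncodingOperator(shape, coils, traj.readouts, traj.heartbeat, bins)
        x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        ks = ph.fft3c(x)
        out = op.apply(x)[0][0]  # (rows, n_x)
        expect = ks[:, traj.readouts[:, 0], traj.readouts[:, 1]].T
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_adjoint_inner_product(self, tiny_motion_operator, rng):
        op = tiny_motion_operator
        for _ in range(10):
            x = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
            ex = op.apply(x)
            y = [rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape) for s in ex]
            lhs = sum(np.vdot(e, yy) for e, yy in zip(ex, y))
            rhs = np.vdot(x, op.adjoint(y))
            assert abs(lhs - rhs) / abs(lhs) < 1e-8

    def test_matches_dense_matrix(self, tiny_motion_operator, rng):
        op = tiny_motion_operator
        mat = dense_matrix(op)
        x = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
        fwd = op.pack(op.apply(x))
        assert np.linalg.norm(mat @ x.ravel() - fwd) / np.linalg.norm(fwd) < 1e-10
        y = rng.normal(size=mat.shape[0]) + 1j * rng.normal(size=mat.shape[0])
        adj = op.adjoint(op.unpack(y)).ravel()
        ref = mat.conj().T @ y
        assert np.linalg.norm(ref - adj) / np.linalg.norm(ref) < 1e-10

    def test_normal_is_identity_for_unitary_case(self, rng):
        """Full rectangular sampling, RSS single coil, no motion: E*E = I."""
        shape = (4, 8, 8)
        traj = tj.full_trajectory(tj.GridSpec(8, 8), 2, rectangular=True)
        coils = ph.simulate_coils(shape, 1, mode="uniform")
        bins = BinWeights(np.ones((2, 1)), np.zeros(1), np.zeros(2, int), 0)
        op = ops.EncodingOperator(shape, coils, traj.readouts, traj.heartbeat, bins)
        x = rng.normal(size=shape) + 1j * rng.normal(size=shape)
        assert np.abs(op.normal(x) - x).max() < 1e-10

    def test_unitary_fft_convention(self, rng):
        x = rng.normal(size=(8, 8, 8)) + 1j * rng.normal(size=(8, 8, 8))
        assert abs(np.linalg.norm(ph.fft3c(x)) - np.linalg.norm(x)) < 1e-12

    def test_tampered_motion_breaks_adjointness(self, tiny_motion_operator, rng):
        """Sensitivity: desynchronizing the motion field between the forward
        and adjoint applications must fail the inner-product test."""
        op = tiny_motion_operator
        x = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
        ex = op.apply(x)
        y = [rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape) for s in ex]
        lhs = sum(np.vdot(e, yy) for e, yy in zip(ex, y))
        op.motion[0].forward = -op.motion[0].forward
        try:
            rhs = np.vdot(x, op.adjoint(y))
        finally:
            op.motion[0].forward = -op.motion[0].forward
        assert abs(lhs - rhs) / abs(lhs) > 1e-8


@pytest.fixture(scope="module")
def moving_acquisition():
    spec = ph.default_phantom(noise_sd=0.0)
    traj = tj.generate_caspr(tj.GridSpec(32, 16), 7, n_heartbeats=48, rng_seed=1)
    states = ph.make_resp_states(spec, 48)
    kdata, gt = ph.simulate_acquisition(spec, traj, states, seed=2)
    corrected = phase_correct(kdata, gt.translations)
    return spec, corrected, gt


class TestZeroFilled:
    def test_fully_sampled_static_roundtrip(self):
        spec = ph.default_phantom(amp_fh_mm=0, amp_lr_mm=0, nonrigid=0,
                                  nonrigid2_mm=0, shear_ap=0, noise_sd=0.0)
        traj = tj.full_trajectory(tj.GridSpec(32, 16), 4, rectangular=True)
        kdata, gt = ph.simulate_acquisition(spec, traj, np.zeros(4), seed=0)
        bins = BinWeights(np.ones((4, 1)), np.zeros(1), np.zeros(4, int), 0)
        zf = ops.zero_filled_recon(kdata, bins, gt.coils)[0]
        truth = ph.render_phantom(spec, 0.0)
        assert np.linalg.norm(zf - truth) / np.linalg.norm(truth) < 1e-6

    def test_undersampled_energy_deficit(self, moving_acquisition):
        spec, corrected, gt = moving_acquisition
        bins = bin_heartbeats(gt.translations, 4, 0.5)
        zf = ops.zero_filled_recon(corrected, bins, gt.coils)
        full = ph.render_phantom(spec, 0.0)
        assert np.linalg.norm(zf[bins.end_exp_bin]) < np.linalg.norm(full)

    def test_hard_bins_sum_to_pooled(self, moving_acquisition):
        _, corrected, gt = moving_acquisition
        bins = bin_heartbeats(gt.translations, 4, softness=0.0)
        per_bin = ops.zero_filled_recon(corrected, bins, gt.coils)
        pooled_bins = BinWeights(
            np.ones((48, 1)), np.zeros(1), np.zeros(48, int), 0
        )
        pooled = ops.zero_filled_recon(corrected, pooled_bins, gt.coils)[0]
        np.testing.assert_allclose(per_bin.sum(axis=0), pooled, atol=1e-10)


class TestCG:
    def test_identity_converges_in_one_iteration(self, rng):
        rhs = rng.normal(size=(4, 4, 4)) + 1j * rng.normal(size=(4, 4, 4))
        x, rep = ops.cg_solve(lambda v: v, rhs, n_iter=5, tol=1e-14)
        np.testing.assert_allclose(x, rhs, atol=1e-12)
        assert rep.n_iter <= 2

    def test_matches_dense_solve(self, tiny_motion_operator, rng):
        op = tiny_motion_operator
        mat = dense_matrix(op)
        a = mat.conj().T @ mat
        y = rng.normal(size=mat.shape[0]) + 1j * rng.normal(size=mat.shape[0])
        rhs = op.adjoint(op.unpack(y))
        x, rep = ops.cg_solve(op.normal, rhs, n_iter=200, tol=0.0)
        x_dense = np.linalg.solve(a, rhs.ravel())
        assert np.linalg.norm(x.ravel() - x_dense) / np.linalg.norm(x_dense) < 1e-6

    def test_returned_iterate_never_worse_than_start(self, tiny_motion_operator, rng):
        op = tiny_motion_operator
        rhs = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
        x0 = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
        x, rep = ops.cg_solve(op.normal, rhs, x0=x0, n_iter=3)
        r_start = np.linalg.norm(rhs - op.normal(x0))
        r_end = np.linalg.norm(rhs - op.normal(x))
        assert r_end <= r_start + 1e-12
        assert min(rep.residual_norms) == rep.residual_norms[rep.chosen_iterate]

    def test_nonfinite_rhs_rejected(self):
        rhs = np.full((2, 2, 2), np.nan, dtype=complex)
        with pytest.raises(ValueError):
            ops.cg_solve(lambda v: v, rhs)


class TestSense:
    def test_default_iterations(self):
        import inspect

        assert inspect.signature(ops.sense_recon).parameters["n_iter"].default == 10

    def test_fully_sampled_equals_coil_combination(self):
        spec = ph.default_phantom(amp_fh_mm=0, amp_lr_mm=0, nonrigid=0,
                                  nonrigid2_mm=0, shear_ap=0, noise_sd=0.0)
        traj = tj.full_trajectory(tj.GridSpec(32, 16), 4, rectangular=True)
        kdata, gt = ph.simulate_acquisition(spec, traj, np.zeros(4), seed=0)
        bins = BinWeights(np.ones((4, 1)), np.zeros(1), np.zeros(4, int), 0)
        x, _ = ops.sense_recon(kdata, gt.coils, bins, 0, n_iter=10)
        truth = ph.render_phantom(spec, 0.0)
        assert np.linalg.norm(x - truth) / np.linalg.norm(truth) < 1e-6

    def test_residual_decreases_with_iterations(self, moving_acquisition):
        _, corrected, gt = moving_acquisition
        bins = bin_heartbeats(gt.translations, 4, 0.5)
        _, reps1 = ops.sense_recon(corrected, gt.coils, bins, 0, n_iter=1)
        _, reps10 = ops.sense_recon(corrected, gt.coils, bins, 0, n_iter=10)
        assert reps10[0].residual_norms[-1] <= reps1[0].residual_norms[-1]
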