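import numpy as np
import pytest

from respmoco import autodiff as ad
from respmoco import trajectory as tj
from respmoco import phantom as ph
from respmoco.motion import RespTranslations, bin_heartbeats
from respmoco.networks import Denoiser, MotionEstimator
from respmoco.recon import ReconConfig, build_patch_context, reconstruct_patch_graph, _ifft1c
from respmoco import training as tr


class TestTrainConfig:
    def test_reference_defaults(self):
        cfg = tr.TrainConfig()
        assert (cfg.lambda1, cfg.lambda2, cfg.lambda3) == (100.0, 10.0, 1.0)
        assert cfg.epochs == 1600 and cfg.lr == 3e-4 and cfg.lr_halve_every == 400
        assert cfg.patch_x == 48

    def test_lr_halves_on_schedule(self):
        cfg = tr.TrainConfig()
        assert cfg.lr_at(0) == cfg.lr
        assert cfg.lr_at(399) == cfg.lr
        assert cfg.lr_at(400) == cfg.lr / 2
        assert cfg.lr_at(800) == cfg.lr / 4

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            tr.TrainConfig(lambda1=-1.0)


class TestCharbonnier:
    def test_approaches_absolute_value_for_large_arguments(self):
        x = ad.constant(np.array([3.0, -2.0]))
        val = tr.charbonnier(x, eps=1e-8).item()
        assert abs(val - 2.5) < 1e-6  # mean(|3|, |-2|)

    def test_quadratic_regime_below_eps(self):
        eps = 0.1
        small = 1e-3
        base = tr.charbonnier(ad.constant(np.zeros(1)), eps).item()
        val = tr.charbonnier(ad.constant(np.array([small])), eps).item()
        assert abs((val - base) - small ** 2 / (2 * eps)) < 1e-8


@pytest.fixture(scope="module")
def tiny_sample():
    """Small moving acquisition prepared as a training sample."""
    g = tj.GridSpec(16, 8)
    traj = tj.generate_caspr(g, 3, n_heartbeats=24, rng_seed=0, r_center=0.25)
    spec = ph.default_phantom(shape=(16, 16, 8), n_coils=2, noise_sd=0.02)
    states = ph.make_resp_states(spec, 24)
    kdata, gt = ph.simulate_acquisition(spec, traj, states, seed=1)
    t7 = tj.generate_caspr(g, 5, n_heartbeats=24, rng_seed=1, r_center=0.25)
    src = tj.measure_annulus_profile(traj, 10)
    tgt = tj.measure_annulus_profile(t7, 10)
    profile = tj.AnnulusProfile(
        tgt.boundaries,
        np.fmin(tgt.acquired_fraction, src.acquired_fraction),
        src.shutter_counts,
    )
    cfg = ReconConfig(patch_x=8, edge_discard=1, overlap=1, n_bins=2,
                      softness=0.5, dtype="float64")
    sample = tr.make_training_sample(kdata, gt, profile, 7, cfg, ph.heart_roi(spec))
    return kdata, profile, cfg, sample


class TestTrainingSample:
    def test_subset_of_source(self, tiny_sample):
        kdata, profile, _, sample = tiny_sample
        src = {tuple(r) for r in np.c_[kdata.traj.readouts, kdata.traj.heartbeat].tolist()}
        sub = np.c_[sample.kdata.traj.readouts, sample.kdata.traj.heartbeat]
        assert sample.kdata.traj.n_readouts < kdata.traj.n_readouts
        assert all(tuple(r) in src for r in sub.tolist())

    def test_deterministic_under_seed(self, tiny_sample):
        kdata, profile, cfg, _ = tiny_sample
        a = tr.subset_kdata(kdata, profile, 5)
        b = tr.subset_kdata(kdata, profile, 5)
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.traj.readouts, b.traj.readouts)

    def test_references_unit_scaled(self, tiny_sample):
        _, _, _, sample = tiny_sample
        assert abs(np.percentile(np.abs(sample.ref_end_exp), 99) - 1.0) < 1e-9


class TestTotalLoss:
    def test_reduces_to_kernel_norm_with_zero_weights(self, tiny_sample):
        _, _, recon_cfg, sample = tiny_sample
        mnet = MotionEstimator(levels=2, base_channels=2, seed=0, dtype="float64")
        dnet = Denoiser(levels=2, base_channels=2, seed=1, dtype="float64")
        cfg = tr.TrainConfig(lambda1=0.0, lambda2=0.0, lambda3=1.0, epochs=1, patch_x=8)
        ctx = build_patch_context(
            sample.hybrid, sample.op, sample.zf_bins, sample.sense_bins,
            sample.bins.end_exp_bin, 0, 8, "float64",
        )
        recon_pair, info = reconstruct_patch_graph(ctx, mnet, dnet, recon_cfg)
        ref = sample.bins.end_exp_bin
        ref_pair = ad.complex_to_pair(sample.ref_end_exp[0:8])
        mags = {b: np.abs(sample.ref_bins[b][0:8])
                for b in range(sample.ref_bins.shape[0]) if b != ref}
        total, comps = tr.total_loss(
            recon_pair, ref_pair, np.abs(sample.ref_end_exp[0:8]), mags,
            info["fields"], [mnet, dnet], cfg,
        )
        expected = mnet.unet.kernel_l2().item() + dnet.unet.kernel_l2().item()
        assert abs(total.item() - expected) < 1e-9
        assert comps["reg"] == pytest.approx(expected)

    def test_end_to_end_gradient_matches_finite_difference(self, tiny_sample):
        _, _, recon_cfg, sample = tiny_sample
        cfg = tr.TrainConfig(lambda1=100.0, lambda2=10.0, lambda3=1e-3,
                             epochs=1, patch_x=8)

        def loss_value(mnet, dnet, build_graph=True):
            ctx = build_patch_context(
                sample.hybrid, sample.op, sample.zf_bins, sample.sense_bins,
                sample.bins.end_exp_bin, 4, 12, "float64",
            )
            recon_pair, info = reconstruct_patch_graph(ctx, mnet, dnet, recon_cfg)
            ref = sample.bins.end_exp_bin
            mags = {b: np.abs(sample.ref_bins[b][4:12])
                    for b in range(sample.ref_bins.shape[0]) if b != ref}
            return tr.total_loss(
                recon_pair, ad.complex_to_pair(sample.ref_end_exp[4:12]),
                np.abs(sample.ref_end_exp[4:12]), mags, info["fields"],
                [mnet, dnet], cfg,
            )[0]

        mnet = MotionEstimator(levels=2, base_channels=2, seed=0, dtype="float64")
        dnet = Denoiser(levels=2, base_channels=2, seed=1, dtype="float64")
        # give the heads non-trivial weights so gradients flow everywhere
        rng = np.random.default_rng(3)
        for net in (mnet, dnet):
            for k, p in net.params.items():
                p.data = p.data + rng.normal(0, 0.01, p.data.shape)
        total = loss_value(mnet, dnet)
        total.backward()
        for name, p in [("m", mnet.params["down0.0.w"]), ("d", dnet.params["head.w"])]:
            idx = (0, 0, 1, 1, 1)
            g = p.grad[idx]
            eps = 1e-5
            orig = p.data[idx]
            p.data[idx] = orig + eps
            with ad.no_grad():
                fp = loss_value(mnet, dnet).item()
            p.data[idx] = orig - eps
            with ad.no_grad():
                fm = loss_value(mnet, dnet).item()
            p.data[idx] = orig
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - g) / (abs(fd) + abs(g) + 1e-12) < 1e-3, name


class TestTrainLoop:
    def test_short_run_produces_history_and_updates(self, tiny_sample):
        _, _, recon_cfg, sample = tiny_sample
        mnet = MotionEstimator(levels=2, base_channels=2, seed=0, dtype="float64")
        dnet = Denoiser(levels=2, base_channels=2, seed=1, dtype="float64")
        before = {k: p.data.copy() for k, p in mnet.params.items()}
        cfg = tr.TrainConfig(lambda3=1e-3, epochs=2, lr=1e-3, lr_halve_every=400,
                             patch_x=8, seed=0)
        history = tr.train([sample], mnet, dnet, recon_cfg, cfg)
        assert len(history) == 2
        assert all(np.isfinite(h["total"]) for h in history)
        changed = any(
            not np.array_equal(before[k], p.data) for k, p in mnet.params.items()
        )
        assert changed

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            tr.train([], None, None, None, tr.TrainConfig(epochs=1))

    def test_identity_baseline_error_is_mean_true_displacement(self, tiny_sample):
        _, _, _, sample = tiny_sample
        err = tr.motion_error_voxels(sample, None)
        ref = sample.bins.end_exp_bin
        x0, x1, y0, y1, z0, z1 = sample.heart_roi
        expected = np.mean([
            np.sqrt((sample.gt.bin_forward[b] ** 2).sum(axis=0))[x0:x1, y0:y1, z0:z1].mean()
            for b in range(sample.bins.n_bins) if b != ref
        ])
        assert err == pytest.approx(expected)
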