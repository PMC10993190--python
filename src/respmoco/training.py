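"""End-to-end training of the motion and denoising networks.

Training data is built the way the reference protocol builds it: a source
acquisition at low acceleration is *retrospectively subset* in k-space to
a higher-acceleration sampling-density profile (never re-simulated), so
every training readout was genuinely acquired; reference bin images are
the end-expiration reference warped to each bin by the ground-truth fields
(the role a conventional motion-corrected reconstruction of the source
data plays on patient data).

The composite loss is

    L = lambda1 * L_mot + lambda2 * L_recon + lambda3 * L_reg

with ``L_mot`` the Charbonnier distance between the end-expiration
reference and each remaining bin reference warped to end-expiration by the
estimated fields, plus a squared-gradient smoothness penalty on the
velocity fields; ``L_recon`` the Charbonnier distance between reference
and reconstruction; and ``L_reg`` the squared l2 norm of all convolution
kernels.  One optimization step per sample is taken each epoch on a
randomly selected readout-axis patch; the learning rate halves on a fixed
epoch interval.  Gradients flow through the unrolled CG, the warps and the
scaling-and-squaring integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .networks import Denoiser, MotionEstimator
from .phantom import GroundTruth, bin_ground_truth, reference_bin_images
from .rawdata import KSpaceData
from .recon import (
    ReconConfig,
    _ifft1c,
    build_patch_context,
    prepare_bins,
    reconstruct_patch_graph,
)
from .trajectory import AnnulusProfile, retrospective_undersample

__all__ = [
    "TrainConfig",
    "TrainingSample",
    "subset_kdata",
    "make_training_sample",
    "charbonnier",
    "total_loss",
    "Adam",
    "train",
]


@dataclass
class TrainConfig:
    """Loss weights and schedule; defaults follow the reference protocol.

    Full-scale values: lambda = (100, 10, 1), 1600 epochs, initial learning
    rate 3e-4 halved every 400 epochs, 48-voxel readout patches.  Scaled
    phantom runs override ``epochs``, ``patch_x``, ``lr`` and
    ``lambda3`` (the kernel-norm term is scale dependent: summed squared
    kernels of even a small network would otherwise dominate the scaled
    losses).
    """

    lambda1: float = 100.0
    lambda2: float = 10.0
    lambda3: float = 1.0
    epochs: int = 1600
    lr: float = 3e-4
    lr_halve_every: int = 400
    charbonnier_eps: float = 1e-3
    smooth_weight: float = 0.01
    patch_x: int = 48
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        return self.lr / (2.0 ** (epoch // self.lr_halve_every))


@dataclass
class TrainingSample:
    """One retrospectively undersampled acquisition with references."""

    kdata: KSpaceData  # subset, phase-corrected, intensity-normalized
    hybrid: np.ndarray  # corrected data after inverse FFT along k_x
    bins: object
    zf_bins: np.ndarray
    sense_bins: np.ndarray
    op: object
    ref_end_exp: np.ndarray  # complex, normalized
    ref_bins: np.ndarray  # (n_bins, ...) complex, normalized
    gt: GroundTruth
    heart_roi: tuple
    scale: float


def subset_kdata(kdata: KSpaceData, target_profile: AnnulusProfile, seed: int) -> KSpaceData:
    """Retrospective k-space subsetting: keep only rows whose phase-encode
    location survives the annulus-matched undersampling."""
    traj = kdata.traj
    sub = retrospective_undersample(traj, target_profile, rng_seed=seed)
    nz = traj.grid.n_kz
    key = (traj.heartbeat.astype(np.int64) * traj.grid.n_ky + traj.readouts[:, 0]) * nz \
        + traj.readouts[:, 1]
    sub_key = (sub.heartbeat.astype(np.int64) * traj.grid.n_ky + sub.readouts[:, 0]) * nz \
        + sub.readouts[:, 1]
    mask = np.isin(key, sub_key)
    return KSpaceData(
        data=kdata.data[:, mask, :],
        traj=type(traj)(traj.grid, traj.readouts[mask], traj.heartbeat[mask],
                        sub.nominal_accel, traj.r_center),
        voxel_mm=kdata.voxel_mm,
        resp_t_mm=kdata.resp_t_mm,
        inavs=kdata.inavs,
        coils=kdata.coils,
    )


def make_training_sample(
    kdata: KSpaceData,
    gt: GroundTruth,
    target_profile: AnnulusProfile,
    seed: int,
    recon_cfg: ReconConfig,
    heart_roi: tuple,
) -> TrainingSample:
    """Subset a low-acceleration acquisition and attach references.

    The per-bin reference images are the ground-truth end-expiration image
    warped to each bin (standing in for a conventional motion-corrected
    reconstruction of the source data); everything is normalized by the
    99th percentile of the reference magnitude so losses are on a unit
    scale.
    """
    sub = subset_kdata(kdata, target_profile, seed)
    corrected, bins, zf, sense, op = prepare_bins(sub, recon_cfg)
    gt_binned = bin_ground_truth(gt, bins)
    j_ref, refs = reference_bin_images(gt_binned)
    scale = float(np.percentile(np.abs(j_ref), 99)) or 1.0
    corrected.data = corrected.data / scale
    return TrainingSample(
        kdata=corrected,
        hybrid=_ifft1c(corrected.data, axis=2),
        bins=bins,
        zf_bins=zf / scale,
        sense_bins=sense / scale,
        op=op,
        ref_end_exp=j_ref / scale,
        ref_bins=refs / scale,
        gt=gt_binned,
        heart_roi=heart_roi,
        scale=scale,
    )


def charbonnier(x: ad.Tensor, eps: float) -> ad.Tensor:
    """Mean Charbonnier penalty sqrt(x^2 + eps^2)."""
    return ad.sqrt(x * x + eps * eps).mean()


def _grad_sq(v: ad.Tensor) -> ad.Tensor:
    """Mean squared forward-difference spatial gradient of a vector field."""
    total = None
    for ax in (1, 2, 3):
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d = v[tuple(sl_hi)] - v[tuple(sl_lo)]
        term = (d * d).mean()
        total = term if total is None else total + term
    return total


def total_loss(
    recon_pair: ad.Tensor,
    ref_pair: np.ndarray,
    ref_end_exp_mag: np.ndarray,
    ref_bin_mags: dict,
    fields: dict,
    nets: list,
    cfg: TrainConfig,
):
    """Composite training loss; returns (total Tensor, components dict).

    ``ref_bin_mags`` maps bin index -> magnitude reference of that bin;
    ``fields`` maps bin index -> (forward, inverse, velocity) Tensors from
    the motion network.  Bins are warped to the end-expiration phase by the
    inverse fields and compared against the end-expiration reference.
    """
    dt = recon_pair.data.dtype
    l_mot = None
    for b, mag in ref_bin_mags.items():
        warped = ad.warp(ad.constant(mag[None].astype(dt)), fields[b][1])
        term = charbonnier(ad.constant(ref_end_exp_mag[None].astype(dt)) - warped,
                           cfg.charbonnier_eps)
        term = term + _grad_sq(fields[b][2]) * cfg.smooth_weight
        l_mot = term if l_mot is None else l_mot + term
    if l_mot is None:
        l_mot = ad.constant(np.zeros((), dtype=dt))
    l_recon = charbonnier(recon_pair - ad.constant(ref_pair.astype(dt)), cfg.charbonnier_eps)
    l_reg = None
    for net in nets:
        term = net.unet.kernel_l2()
        l_reg = term if l_reg is None else l_reg + term
    total = l_mot * cfg.lambda1 + l_recon * cfg.lambda2 + l_reg * cfg.lambda3
    comps = {
        "mot": float(l_mot.data),
        "recon": float(l_recon.data),
        "reg": float(l_reg.data),
        "total": float(total.data),
    }
    if not np.isfinite(comps["total"]):
        raise FloatingPointError(f"non-finite loss: {comps}")
    return total, comps


class Adam:
    """Adaptive-moment first-order optimizer over named parameter dicts."""

    def __init__(self, params: dict, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def train_step(
    sample: TrainingSample,
    motion_net: MotionEstimator,
    denoiser: Denoiser,
    recon_cfg: ReconConfig,
    cfg: TrainConfig,
    x_start: int,
):
    """One optimization step on one readout-axis patch; returns components."""
    x0, x1 = x_start, x_start + cfg.patch_x
    ctx = build_patch_context(
        sample.hybrid, sample.op, sample.zf_bins, sample.sense_bins,
        sample.bins.end_exp_bin, x0, x1, motion_net.cfg.dtype,
    )
    recon_pair, info = reconstruct_patch_graph(ctx, motion_net, denoiser, recon_cfg)
    ref = sample.bins.end_exp_bin
    ref_pair = ad.complex_to_pair(sample.ref_end_exp[x0:x1])
    ref_mags = {
        b: np.abs(sample.ref_bins[b][x0:x1])
        for b in range(sample.ref_bins.shape[0])
        if b != ref
    }
    total, comps = total_loss(
        recon_pair, ref_pair, np.abs(sample.ref_end_exp[x0:x1]), ref_mags,
        info["fields"], [motion_net, denoiser], cfg,
    )
    total.backward()
    return comps


def train(
    samples: list[TrainingSample],
    motion_net: MotionEstimator,
    denoiser: Denoiser,
    recon_cfg: ReconConfig,
    cfg: TrainConfig,
):
    """Train both networks end to end; returns the per-epoch history.

    Each epoch takes one Adam step per sample on a random readout patch.
    Divergence (non-finite loss) aborts, restoring the last good
    parameters.
    """
    if not samples:
        raise ValueError("need at least one training sample")
    rng = np.random.default_rng(cfg.seed)
    params = {f"m/{k}": p for k, p in motion_net.params.items()}
    params.update({f"d/{k}": p for k, p in denoiser.params.items()})
    opt = Adam(params, lr=cfg.lr)
    history = []
    last_good = {k: p.data.copy() for k, p in params.items()}
    n_x = samples[0].hybrid.shape[2]
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        comps_sum = {"mot": 0.0, "recon": 0.0, "reg": 0.0, "total": 0.0}
        order = rng.permutation(len(samples))
        try:
            for i in order:
                start = int(rng.integers(0, n_x - cfg.patch_x + 1))
                opt.zero_grad()
                comps = train_step(samples[i], motion_net, denoiser, recon_cfg, cfg, start)
                opt.step()
                for k in comps_sum:
                    comps_sum[k] += comps[k] / len(samples)
        except FloatingPointError:
            for k, p in params.items():
                p.data = last_good[k]
            history.append({"epoch": epoch, "diverged": True, **comps_sum})
            break
        last_good = {k: p.data.copy() for k, p in params.items()}
        history.append({"epoch": epoch, "lr": opt.lr, **comps_sum})
    return history


# ---------------------------------------------------------------------------
# held-out evaluation helpers
# ---------------------------------------------------------------------------


def motion_error_voxels(sample: TrainingSample, motion_net: MotionEstimator | None):
    """Mean displacement error (voxels) in the heart ROI over non-ref bins.

    ``motion_net=None`` scores the identity (translational-only) baseline,
    i.e. the mean ground-truth residual displacement magnitude.
    """
    gt = sample.gt
    ref = sample.bins.end_exp_bin
    x0, x1, y0, y1, z0, z1 = sample.heart_roi
    errs = []
    for b in range(sample.bins.n_bins):
        if b == ref:
            continue
        true = gt.bin_forward[b]
        if motion_net is None:
            est = np.zeros_like(true)
        else:
            mf = motion_net.estimate(
                np.abs(sample.sense_bins[ref]), np.abs(sample.sense_bins[b])
            )
            est = mf.forward
        diff = est - true
        mag = np.sqrt((diff ** 2).sum(axis=0))
        errs.append(mag[x0:x1, y0:y1, z0:z1].mean())
    return float(np.mean(errs))
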