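"""Self-contained acceptance suite: seeded property checks over the stack.

Runs the analytic acceleration accounting, operator adjointness and
dense-matrix equivalence, the translational-correction round trip,
diffeomorphism checks, retrospective-undersampling density matching,
patch-recombination exactness and the zero-motion pipeline reduction; a
scaled-down train-and-recover experiment can be appended.  Every check
reports a measured value and a pass flag; the suite passes only if all
checks do.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from . import recon as rc
from . import trajectory as tj
from .motion import (
    BinWeights,
    MotionField,
    RespTranslations,
    bin_heartbeats,
    integrate_velocity,
    phase_correct,
    warp,
)
from .operators import EncodingOperator, sense_recon
from .phantom import default_phantom, make_resp_states, render_phantom, simulate_acquisition

__all__ = ["acceptance_suite", "effective_accels", "smooth_random_coils"]


def effective_accels(nominals=(3, 4, 7), grid=(200, 60), n_heartbeats=48, seed=0):
    """Effective rectangular-grid undersampling factor per nominal factor."""
    g = tj.GridSpec(*grid)
    out = {}
    for i, a in enumerate(nominals):
        t = tj.generate_caspr(g, a, n_heartbeats=n_heartbeats, rng_seed=seed + i)
        out[a] = tj.effective_accel_rectangular(t)
    return out


def smooth_random_coils(shape, n_coils, rng, sigma=1.5):
    """Random smooth RSS-normalized complex maps (well-conditioned fixtures)."""
    maps = np.stack(
        [
            ndi.gaussian_filter(rng.normal(size=shape), sigma)
            + 1j * ndi.gaussian_filter(rng.normal(size=shape), sigma)
            for _ in range(n_coils)
        ]
    )
    return maps / np.sqrt((np.abs(maps) ** 2).sum(axis=0))


def _two_bin_motion_operator(seed=0, shape=(4, 8, 8)):
    """Per-bin fully sampled two-bin operator with smooth non-rigid motion."""
    rng = np.random.default_rng(seed)
    g = tj.GridSpec(shape[1], shape[2])
    t1 = tj.full_trajectory(g, 1, rectangular=True)
    readouts = np.concatenate([t1.readouts, t1.readouts])
    hb = np.concatenate(
        [np.zeros(t1.n_readouts, np.int32), np.ones(t1.n_readouts, np.int32)]
    )
    coils = smooth_random_coils(shape, 3, rng)
    bins = bin_heartbeats(RespTranslations(np.array([[1.0, 0], [-1.0, 0]])), 2, 0.0)
    motion = [
        MotionField.from_velocity(
            np.stack([ndi.gaussian_filter(rng.normal(0, 1, shape), 2) * 1.5 for _ in range(3)])
        )
        for _ in range(2)
    ]
    return EncodingOperator(shape, coils, readouts, hb, bins, motion=motion,
                            adjoint_mode="exact")


def dense_matrix(op: EncodingOperator) -> np.ndarray:
    n = int(np.prod(op.volume_shape))
    cols = []
    for i in range(n):
        e = np.zeros(n, dtype=complex)
        e[i] = 1.0
        cols.append(op.pack(op.apply(e.reshape(op.volume_shape))))
    return np.array(cols).T


def acceptance_suite(seed: int = 0, include_training: bool = False) -> dict:
    """Run every property check; returns ``{'passed': bool, 'checks': {...}}``."""
    rng = np.random.default_rng(seed)
    checks = {}

    def record(name, value, ok):
        checks[name] = {"value": value, "passed": bool(ok)}

    # shutter area ratio
    ratio = tj.make_shutter(tj.GridSpec(200, 200)).mean()
    record("shutter_area_ratio", float(ratio), abs(ratio - np.pi / 4) / (np.pi / 4) < 0.005)

    # effective acceleration accounting
    eff = effective_accels(seed=seed)
    expected = {3: 3.8, 4: 5.1, 7: 8.9}
    for a, v in eff.items():
        record(f"effective_accel_nominal_{a}", round(v, 1), round(v, 1) == expected[a])

    # operator adjointness and dense equivalence
    op = _two_bin_motion_operator(seed=seed)
    x = rng.normal(size=op.volume_shape) + 1j * rng.normal(size=op.volume_shape)
    ex = op.apply(x)
    y = [rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape) for s in ex]
    lhs = sum(np.vdot(e, yy) for e, yy in zip(ex, y))
    rhs = np.vdot(x, op.adjoint(y))
    rel = abs(lhs - rhs) / abs(lhs)
    record("E_adjoint_relative_error", float(rel), rel < 1e-8)
    mat = dense_matrix(op)
    xe = op.pack(op.apply(x))
    dense_err = np.linalg.norm(mat @ x.ravel() - xe) / np.linalg.norm(xe)
    adj = op.adjoint(op.unpack(op.pack(y))).ravel()
    dense_adj_err = np.linalg.norm(mat.conj().T @ op.pack(y) - adj) / np.linalg.norm(adj)
    record("E_dense_match", float(max(dense_err, dense_adj_err)),
           max(dense_err, dense_adj_err) < 1e-10)

    # translational correction round trip
    rel = phase_correction_roundtrip(seed)
    record("phase_correction_roundtrip", float(rel), rel < 1e-3)

    # diffeomorphism
    vel = np.stack(
        [ndi.gaussian_filter(rng.normal(0, 1, (16, 16, 12)), 3) * 6 for _ in range(3)]
    )
    fwd, inv = integrate_velocity(vel, 6)
    comp = inv + warp(fwd, inv)
    mean_err = float(np.abs(comp).mean())
    record("inverse_consistency_voxels", mean_err, mean_err < 0.1)
    record("jacobian_positive", float(_min_jacobian(fwd)), _min_jacobian(fwd) > 0)

    # retrospective undersampling density match
    g = tj.GridSpec(200, 60)
    t4 = tj.generate_caspr(g, 4, n_heartbeats=48, rng_seed=seed)
    t7 = tj.generate_caspr(g, 7, n_heartbeats=48, rng_seed=seed + 100)
    prof = tj.measure_annulus_profile(t7, 20)
    sub = tj.retrospective_undersample(t4, prof, rng_seed=seed)
    src = set(map(tuple, np.c_[t4.readouts, t4.heartbeat].tolist()))
    subset_ok = all(tuple(r) in src for r in np.c_[sub.readouts, sub.heartbeat].tolist())
    m = tj.measure_annulus_profile(sub, 20)
    count_err = np.nanmax(
        np.abs(m.acquired_fraction - prof.acquired_fraction) * m.shutter_counts
    )
    record("retrospective_subset", bool(subset_ok), subset_ok)
    record("annulus_count_error", float(count_err), count_err <= 1.0)

    # patch plan partition of unity
    plan = rc.plan_patches(272, 48, 5, 4)
    const = [np.ones((e - s, 2, 2)) for s, e in plan.patches]
    exact = float(np.abs(rc.recombine(plan, const) - 1).max())
    record("patch_recombination_exact", exact, exact == 0.0)

    # zero-motion pipeline reduction
    rel = zero_motion_reduction(seed)
    record("zero_motion_reduction", float(rel), rel < 1e-6)

    if include_training:
        from .experiments import scaled_training_experiment

        res = scaled_training_experiment(seed=seed)
        record("motion_error_voxels", res["motion_error"], res["motion_error"] < 1.0)
        record("ssim_gain", res["ssim_gain"], res["ssim_gain"] >= 0.1)

    return {"passed": all(c["passed"] for c in checks.values()), "checks": checks}


def _min_jacobian(disp):
    grads = np.stack(
        [np.stack(np.gradient(disp[i], axis=(0, 1, 2))) for i in range(3)]
    )  # (3, 3, ...)
    jac = grads + np.eye(3).reshape(3, 3, 1, 1, 1)
    det = np.linalg.det(np.moveaxis(jac, (0, 1), (-2, -1)))
    interior = det[1:-1, 1:-1, 1:-1]
    return float(interior.min())


def phase_correction_roundtrip(seed=0) -> float:
    """Static smooth phantom under pure per-beat 2D translation, fully
    sampled: the corrected reconstruction against the mean-position render."""
    from .phantom import Ellipsoid, PhantomSpec

    spec = PhantomSpec(
        shape=(32, 32, 16), nonrigid=0.0, nonrigid2_mm=0.0, shear_ap=0.0,
        amp_fh_mm=6.0, amp_lr_mm=3.0, noise_sd=0.0, n_coils=1, coil_mode="uniform",
        primitives=[
            Ellipsoid((0, 0, 0), (5, 5, 4), 1.0, profile="gaussian"),
            Ellipsoid((-7, 5, 3), (4, 4, 3.5), 0.8 + 0.1j, profile="gaussian"),
            Ellipsoid((8, -5, -3), (4.5, 4, 3.5), 0.6 - 0.1j, profile="gaussian"),
        ],
    )
    n_beats = 8
    traj = tj.full_trajectory(tj.GridSpec(32, 16), n_beats, rectangular=True)
    states = (np.arange(n_beats) % 2).astype(float)  # alternate the extremes
    kdata, gt = simulate_acquisition(spec, traj, states, seed=seed)
    corrected = phase_correct(kdata, gt.translations)
    one = BinWeights(np.ones((n_beats, 1)), np.zeros(1), np.zeros(n_beats, int), 0)
    from .operators import zero_filled_recon

    # every rectangular-grid location is acquired exactly once across the
    # scan and the coils are RSS-normalized, so the zero-filled adjoint of
    # the corrected data is the reconstruction itself
    rec = zero_filled_recon(corrected, one, gt.coils)[0]
    target = render_phantom(spec, float(states.mean()))
    return float(np.linalg.norm(rec - target) / np.linalg.norm(target))


def zero_motion_reduction(seed=0) -> float:
    """Identity-network pipeline against pooled restarted CG-SENSE."""
    g = tj.GridSpec(32, 16)
    traj = tj.generate_caspr(g, 4, n_heartbeats=48, rng_seed=seed)
    spec = default_phantom(amp_fh_mm=0.0, amp_lr_mm=0.0, nonrigid=0.0, nonrigid2_mm=0.0,
                           shear_ap=0.0, noise_sd=1e-4, n_coils=4)
    states = make_resp_states(spec, 48)
    kd, gt = simulate_acquisition(spec, traj, states, seed=seed)
    cfg = rc.ReconConfig(patch_x=32, softness=0.0, n_bins=4, dtype="float64")
    vol, _ = rc.reconstruct(kd, None, None, cfg)
    corr = phase_correct(kd, RespTranslations(kd.resp_t_mm))
    one = BinWeights(np.ones((48, 1)), np.zeros(1), np.zeros(48, int), 0)
    op = EncodingOperator(
        corr.volume_shape, kd.coils, corr.traj.readouts, corr.traj.heartbeat, one
    )
    x0 = op.adjoint([corr.data])  # E*b, the pipeline's warm start
    ref, _ = sense_recon(corr, kd.coils, one, 0, n_iter=cfg.n_modl_iter * cfg.n_cg,
                         restart_every=cfg.n_cg, x0=x0)
    return float(np.linalg.norm(vol - ref) / np.linalg.norm(ref))
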