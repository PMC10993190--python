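"""Synthetic deforming thorax/heart phantom and k-space simulator.

The phantom is a set of analytic primitives (smooth-edged ellipsoids and
tubes) inside a torso, breathing under a parameterized respiratory model:
a bulk foot-head/left-right translation plus a smooth non-rigid component
in which the foot-head displacement is graded along the foot-head axis
(emulating diaphragm-driven motion, strongest inferiorly) with a mild
anterior-posterior shear.  The sequence is ECG-triggered to a quiescent
cardiac window, so no cardiac-phase motion is modelled.

Axis convention: ``x`` = foot-head (the fully sampled readout direction),
``y`` = left-right, ``z`` = anterior-posterior.  A motion state ``s`` in
[0, 1] scales the configured amplitudes; ``s = 0`` is end-expiration.

For each heartbeat the phantom is rendered at that heartbeat's motion
state, weighted by smooth complex coil sensitivities, transformed with a
unitary centered 3D FFT, and sampled along the heartbeat's spiral
interleaf over all ``k_x``, with i.i.d. circular complex Gaussian noise.
A low-resolution coronal 2D navigator image is emitted per heartbeat.
Because the deformation is analytic, exact ground truth is available:
per-heartbeat translations, per-bin forward/inverse residual deformation
fields (the part translational correction cannot remove), and reference
bin volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .motion import RespTranslations, warp
from .rawdata import KSpaceData
from .trajectory import Trajectory

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "GroundTruth",
    "default_phantom",
    "render_phantom",
    "simulate_coils",
    "make_resp_states",
    "simulate_acquisition",
    "simulate_inav",
    "fft3c",
    "ifft3c",
]


# ---------------------------------------------------------------------------
# unitary centered FFTs (the package-wide k-space convention)
# ---------------------------------------------------------------------------


def fft3c(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    """Unitary centered 3D FFT (DC at ``n//2`` on every axis)."""
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft3c(x: np.ndarray, axes=(-3, -2, -1)) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Smooth-edged ellipsoid: ``center_mm`` is relative to the volume center.

    ``profile='sigmoid'`` gives a soft-edged indicator (width set by the
    phantom's ``edge_mm``); ``profile='gaussian'`` gives a Gaussian blob
    with the semi-axes as per-axis standard deviations — strongly
    band-limited, used where Fourier-shift identities must hold tightly.
    """

    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    intensity: complex = 1.0 + 0.0j
    profile: str = "sigmoid"


@dataclass
class PhantomSpec:
    """Phantom geometry, respiration model and acquisition physics.

    ``amp_fh_mm``/``amp_lr_mm`` are the bulk translation amplitudes at full
    inspiration (motion state 1).  ``nonrigid`` grades the foot-head
    displacement linearly along x (value = fractional amplitude change from
    the volume center to the inferior edge), leaving a residual deformation
    after translational correction; ``shear_ap`` adds a mild z-dependent
    left-right shear.  ``edge_mm`` is the soft edge width of the primitives
    (keeps the phantom band-limited so shift/warp identities hold tightly).
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    primitives: list[Ellipsoid] = field(default_factory=list)
    amp_fh_mm: float = 10.0
    amp_lr_mm: float = 3.0
    nonrigid: float = 0.5
    nonrigid2_mm: float = 8.0
    shear_ap: float = 0.15
    period_beats: float = 8.0
    drift_per_beat: float = 0.002
    n_coils: int = 4
    coil_mode: str = "gaussian"
    noise_sd: float = 0.0
    edge_mm: float = 3.0
    heart_index: int = 1  # primitive treated as the heart (ROI anchor)

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_mm)


def default_phantom(**overrides) -> PhantomSpec:
    """Torso, heart, descending vessel and liver in a 32x32x16 volume."""
    spec = PhantomSpec(**overrides)
    if not spec.primitives:
        fov = spec.fov_mm
        spec.primitives = [
            Ellipsoid((0, 0, 0), tuple(0.42 * fov), 0.25 + 0.0j),  # torso
            Ellipsoid((-0.05 * fov[0], 0.08 * fov[1], 0.05 * fov[2]),
                      (0.17 * fov[0], 0.2 * fov[1], 0.22 * fov[2]), 1.0 + 0.15j),  # heart
            Ellipsoid((0.05 * fov[0], -0.22 * fov[1], -0.1 * fov[2]),
                      (0.3 * fov[0], 0.05 * fov[1], 0.1 * fov[2]), 0.8 - 0.1j),  # vessel
            Ellipsoid((0.28 * fov[0], -0.02 * fov[1], 0.0),
                      (0.14 * fov[0], 0.3 * fov[1], 0.3 * fov[2]), 0.6 + 0.05j),  # liver
        ]
    return spec


def heart_roi(spec: PhantomSpec, margin_voxels: int = 1):
    """Bounding box of the heart primitive as half-open voxel intervals."""
    p = spec.primitives[spec.heart_index]
    vox = np.asarray(spec.voxel_mm)
    center = np.asarray(spec.shape) / 2.0 + np.asarray(p.center_mm) / vox
    half = np.asarray(p.semiaxes_mm) / vox + margin_voxels
    lo = np.maximum(np.floor(center - half).astype(int), 0)
    hi = np.minimum(np.ceil(center + half).astype(int), spec.shape)
    return tuple(int(v) for pair in zip(lo, hi) for v in pair)


# ---------------------------------------------------------------------------
# respiration model
# ---------------------------------------------------------------------------


def make_resp_states(spec: PhantomSpec, n_heartbeats: int) -> np.ndarray:
    """Per-heartbeat motion state in [0, 1]: raised cosine plus slow drift."""
    t = np.arange(n_heartbeats, dtype=float)
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / spec.period_beats))
    s = s + spec.drift_per_beat * t
    return np.clip(s, 0.0, 1.0)


def _pullback_disp_vox(spec: PhantomSpec, state: float, coords_vox: np.ndarray) -> np.ndarray:
    """Displacement (voxels) subtracted from deformed-space coordinates.

    The rendered volume at state ``s`` is ``I_s(x) = I_0(x - d_s(x))``; the
    bulk part of ``d`` is the translation the navigators observe, the rest
    is the non-rigid residual.
    """
    vox = np.asarray(spec.voxel_mm)
    x = coords_vox[0] - spec.shape[0] / 2.0
    y = coords_vox[1] - spec.shape[1] / 2.0
    z = coords_vox[2] - spec.shape[2] / 2.0
    grade = 1.0 + spec.nonrigid * (x / (spec.shape[0] / 2.0))
    d = np.zeros_like(coords_vox)
    d[0] = state * spec.amp_fh_mm / vox[0] * grade
    # smooth large-scale deformation that translational correction cannot
    # remove (the navigators track the bulk term only); non-vanishing over
    # the heart so non-rigid estimation is genuinely exercised
    a2 = spec.nonrigid2_mm / vox[0]
    d[0] += state * a2 * np.cos(2 * np.pi * x / spec.shape[0] + np.pi / 3)
    d[1] = state * spec.amp_lr_mm / vox[1] + \
        state * spec.shear_ap * (z / max(spec.shape[2] / 2.0, 1.0)) * spec.amp_fh_mm / vox[1]
    d[1] += 0.5 * state * a2 * np.sin(2 * np.pi * y / spec.shape[1] + 1.0)
    return d


def bulk_translation_mm(spec: PhantomSpec, state) -> np.ndarray:
    """Bulk (FH, LR) translation at a motion state — what an iNAV sees."""
    state = np.asarray(state, dtype=float)
    return np.stack([state * spec.amp_fh_mm, state * spec.amp_lr_mm], axis=-1)


def residual_disp_vox(spec: PhantomSpec, state: float) -> np.ndarray:
    """Pullback displacement left after removing the bulk translation."""
    shape = spec.shape
    coords = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )
    d = _pullback_disp_vox(spec, state, coords)
    vox = np.asarray(spec.voxel_mm)
    d[0] -= state * spec.amp_fh_mm / vox[0]
    d[1] -= state * spec.amp_lr_mm / vox[1]
    return d


def render_phantom(spec: PhantomSpec, motion_state: float = 0.0) -> np.ndarray:
    """Analytic rasterization of the phantom at a motion state.

    Every voxel's coordinate is pulled back through the state's deformation
    and each primitive's indicator is evaluated there with a smooth
    (logistic) edge profile, so rendering is deterministic and alias-free.
    """
    shape = spec.shape
    vox = np.asarray(spec.voxel_mm)
    coords = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    )
    d = _pullback_disp_vox(spec, float(motion_state), coords)
    ref = coords - d  # voxel coords in the reference (end-expiration) frame
    mm = (ref - np.asarray(shape).reshape(3, 1, 1, 1) / 2.0) * vox.reshape(3, 1, 1, 1)
    out = np.zeros(shape, dtype=np.complex128)
    for p in spec.primitives:
        c = np.asarray(p.center_mm).reshape(3, 1, 1, 1)
        a = np.asarray(p.semiaxes_mm).reshape(3, 1, 1, 1)
        q2 = (((mm - c) / a) ** 2).sum(axis=0)
        if p.profile == "gaussian":
            out += p.intensity * np.exp(-0.5 * q2)
        else:
            # signed distance from the surface, approximately in mm
            dist = (np.sqrt(q2) - 1.0) * a.min()
            out += p.intensity / (1.0 + np.exp(np.clip(dist / (spec.edge_mm / 4.0), -60, 60)))
    return out


# ---------------------------------------------------------------------------
# coils
# ---------------------------------------------------------------------------


def simulate_coils(shape, n_coils: int, seed: int = 0, mode: str = "gaussian",
                   normalize: bool = True) -> np.ndarray:
    """Smooth complex coil sensitivity maps, (n_coils, nx, ny, nz).

    Gaussian-profile magnitudes centered on points around the y-z perimeter
    with a random low-order (linear) phase; with ``normalize`` the maps are
    scaled so the root-sum-of-squares is 1 everywhere.  ``mode='uniform'``
    returns flat all-ones maps (single-coil identity).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    shape = tuple(shape)
    if mode == "uniform":
        maps = np.ones((n_coils,) + shape, dtype=np.complex128)
        if normalize:
            maps /= np.sqrt(float(n_coils))
        return maps
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in shape], indexing="ij")
    maps = np.empty((n_coils,) + shape, dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.normal(0, 0.2)
        center = np.array([0.0, 1.3 * np.cos(ang), 1.3 * np.sin(ang)])
        r2 = sum((g - ctr) ** 2 for g, ctr in zip(grids, center))
        mag = np.exp(-r2 / (2 * 1.1 ** 2)) + 0.05
        lin = sum(rng.normal(0, 0.3) * g for g in grids)
        maps[c] = mag * np.exp(1j * (rng.uniform(0, 2 * np.pi) + lin))
    if normalize:
        rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
        maps /= rss
    return maps


# ---------------------------------------------------------------------------
# acquisition
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the simulator knows that a scanner would not.

    ``bin_forward``/``bin_inverse`` are per-bin residual deformation fields
    (voxel units) between the end-expiration reference frame and each bin's
    mean state, in the frame where translational motion is already removed.
    They are populated lazily by :func:`bin_ground_truth` once a binning is
    chosen.
    """

    spec: PhantomSpec
    states: np.ndarray
    translations: RespTranslations
    coils: np.ndarray
    reference: np.ndarray  # end-expiration (state 0) complex volume
    bin_states: np.ndarray | None = None
    bin_forward: np.ndarray | None = None
    bin_inverse: np.ndarray | None = None
    end_exp_bin: int = 0

    def rendered(self, state: float) -> np.ndarray:
        return render_phantom(self.spec, state)


def simulate_acquisition(
    spec: PhantomSpec, traj: Trajectory, resp_states: np.ndarray, seed: int = 0
):
    """Heartbeat-by-heartbeat multi-coil acquisition along a trajectory.

    Returns ``(KSpaceData, GroundTruth)``.  For each heartbeat the phantom
    is rendered at its motion state, coil weighted, FFT'd (unitary,
    centered) and sampled at the heartbeat's (ky, kz) readouts over all
    k_x; complex Gaussian noise of standard deviation ``noise_sd`` is added
    per sample.  2D iNAVs are simulated from the rendered volumes.
    """
    resp_states = np.asarray(resp_states, dtype=float)
    n_beats = traj.n_heartbeats
    if resp_states.size != n_beats:
        raise ValueError("resp_states length must equal trajectory heartbeats")
    if spec.shape[1] != traj.grid.n_ky or spec.shape[2] != traj.grid.n_kz:
        raise ValueError("trajectory grid does not match phantom volume")
    rng = np.random.default_rng(seed)
    coils = simulate_coils(spec.shape, spec.n_coils, seed=seed, mode=spec.coil_mode)
    n_read = traj.n_readouts
    data = np.zeros((spec.n_coils, n_read, spec.shape[0]), dtype=np.complex128)
    inavs = np.zeros((n_beats, spec.shape[0], spec.shape[1]), dtype=np.float64)
    for m in range(n_beats):
        vol = render_phantom(spec, resp_states[m])
        ks = fft3c(coils * vol[None])
        rows = np.flatnonzero(traj.heartbeat == m)
        pts = traj.readouts[rows]
        # readout rows run along k_x: take the (ky, kz) column for all k_x
        data[:, rows, :] = np.moveaxis(ks[:, :, pts[:, 0], pts[:, 1]], 2, 1)
        inavs[m] = simulate_inav(vol)
    if spec.noise_sd > 0:
        noise = rng.normal(0, spec.noise_sd, data.shape) + 1j * rng.normal(
            0, spec.noise_sd, data.shape
        )
        data = data + noise
    trans_mm = bulk_translation_mm(spec, resp_states)
    translations = RespTranslations(trans_mm - trans_mm.mean(axis=0))
    kdata = KSpaceData(
        data=data,
        traj=traj,
        voxel_mm=spec.voxel_mm,
        resp_t_mm=translations.t_mm,
        inavs=inavs,
        coils=coils,
    )
    gt = GroundTruth(
        spec=spec,
        states=resp_states,
        translations=translations,
        coils=coils,
        reference=render_phantom(spec, 0.0),
    )
    return kdata, gt


def simulate_inav(volume: np.ndarray, translation_mm=(0.0, 0.0), voxel_mm=(1.0, 1.0),
                  lowpass_sigma: float = 2.0) -> np.ndarray:
    """Low-resolution coronal projection navigator.

    Projects |volume| along the anterior-posterior axis, low-pass filters to
    roughly quarter resolution, and (optionally) shifts by a (FH, LR)
    translation in mm via Fourier interpolation.  Linear in the volume.
    """
    proj = np.abs(np.asarray(volume)).sum(axis=2)
    img = gaussian_filter(proj, lowpass_sigma, mode="nearest")
    t = np.asarray(translation_mm, dtype=float) / np.asarray(voxel_mm, dtype=float)
    if np.any(t != 0):
        k0 = np.fft.fftfreq(img.shape[0])[:, None]
        k1 = np.fft.fftfreq(img.shape[1])[None, :]
        img = np.real(np.fft.ifft2(np.fft.fft2(img) * np.exp(-2j * np.pi * (k0 * t[0] + k1 * t[1]))))
    return img


def bin_ground_truth(gt: GroundTruth, bins, n_fixed_point: int = 20) -> GroundTruth:
    """Attach per-bin residual deformation fields to a ground truth.

    The mean motion state of each bin's primary heartbeats defines the bin
    state.  The analytic pullback residual gives the forward field (warping
    the reference-frame image to the bin frame); the inverse is obtained by
    fixed-point iteration of ``u_inv(x) = -u_fwd(x + u_inv(x))``.
    """
    spec = gt.spec
    n_bins = bins.n_bins
    bin_states = np.array(
        [gt.states[bins.primary == b].mean() for b in range(n_bins)]
    )
    ref_state = bin_states[bins.end_exp_bin]
    fwd = np.zeros((n_bins, 3) + tuple(spec.shape))
    inv = np.zeros_like(fwd)
    r_ref = residual_disp_vox(spec, ref_state)
    for b in range(n_bins):
        # corrected bin image: J_s(x) = I_0(x - r_s(x) - const); the field
        # with warp(J_ref, u_b) ~= J_b is u_b = r_ref - r_b to first order
        u = r_ref - residual_disp_vox(spec, bin_states[b])
        fwd[b] = u
        v = -u.copy()
        for _ in range(n_fixed_point):
            v = -warp(u, v)
        inv[b] = v
    return replace(
        gt,
        bin_states=bin_states,
        bin_forward=fwd,
        bin_inverse=inv,
        end_exp_bin=int(bins.end_exp_bin),
    )


def reference_bin_images(gt: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """End-expiration reference image and per-bin warped references.

    Both live in the translational-motion-corrected frame (every heartbeat
    aligned to the mean position) that the reconstruction operates in.
    Mirrors the training-reference construction: the end-expiration image is
    warped to each remaining bin by the ground-truth forward fields.
    Returns ``(ref_end_exp, refs_per_bin)`` with shapes ``(nx,ny,nz)`` and
    ``(n_bins, nx, ny, nz)``.
    """
    if gt.bin_states is None:
        raise ValueError("call bin_ground_truth first")
    spec = gt.spec
    vox = np.asarray(spec.voxel_mm)
    states = gt.states
    bm_mm = bulk_translation_mm(spec, states).mean(axis=0)
    ref_state = gt.bin_states[gt.end_exp_bin]
    # exact pullback: J_ref(x) = I_0(x - r_ref(x) - bulk_mean)
    d = residual_disp_vox(spec, ref_state)
    d[0] += bm_mm[0] / vox[0]
    d[1] += bm_mm[1] / vox[1]
    j_ref = warp(gt.reference, -d)
    refs = np.stack([warp(j_ref, gt.bin_forward[b]) for b in range(gt.bin_forward.shape[0])])
    return j_ref, refs
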