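"""Respiratory motion model: iNAV registration, k-space phase-shift
correction, soft-gated binning, velocity-field integration and warping.

Translational respiratory motion is measured once per heartbeat from 2D
image navigators and removed in k-space: each sample is multiplied by
``exp(2*pi*i k.T_m)`` where ``T_m`` is the difference between the mean
motion position over the scan and the position at heartbeat ``m`` (so the
correction aligns every heartbeat to the mean position).  Heartbeats are
then sorted by foot-head position into equally populated respiratory bins
with soft-gating weights in [0, 1].

The residual non-rigid motion between bins is represented by a stationary
velocity field integrated to a diffeomorphic displacement via scaling and
squaring: the field is divided by 2**n and the resulting small displacement
composed with itself n times; integrating the negated velocity gives the
inverse field.  Images are resampled by trilinear interpolation,
``out(x) = in(x + d(x))`` with clamp-to-edge boundary handling, and the
exact adjoint of that linear map (transpose splatting) is available for
operator testing alongside the cheaper inverse-field warp used inside the
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .rawdata import KSpaceData

__all__ = [
    "RespTranslations",
    "BinWeights",
    "MotionField",
    "register_inavs",
    "phase_correct",
    "bin_heartbeats",
    "integrate_velocity",
    "warp",
    "warp_adjoint",
    "warp_grad_disp",
]


# ---------------------------------------------------------------------------
# trilinear interpolation kernels (shared by warping and its derivatives)
# ---------------------------------------------------------------------------


def _corner_weights(coords, shape):
    """Integer corners and weights for trilinear sampling with edge clamp."""
    idx0, idx1, frac = [], [], []
    for ax, n in enumerate(shape):
        c = np.clip(coords[ax], 0.0, n - 1.0)
        i0 = np.floor(c).astype(np.int64)
        i0 = np.minimum(i0, n - 2) if n > 1 else np.zeros_like(i0)
        i1 = np.minimum(i0 + 1, n - 1)
        idx0.append(i0)
        idx1.append(i1)
        frac.append((c - i0).astype(coords[ax].dtype))
    return idx0, idx1, frac


def _flat_index(ix, iy, iz, shape):
    return (ix * shape[1] + iy) * shape[2] + iz


def _gather(vol_flat, coords, shape):
    """Trilinear gather; vol_flat is (..., X*Y*Z), coords (3, N)."""
    (x0, y0, z0), (x1, y1, z1), (fx, fy, fz) = _corner_weights(coords, shape)
    out = 0
    for ix, wx in ((x0, 1 - fx), (x1, fx)):
        for iy, wy in ((y0, 1 - fy), (y1, fy)):
            for iz, wz in ((z0, 1 - fz), (z1, fz)):
                out = out + vol_flat[..., _flat_index(ix, iy, iz, shape)] * (wx * wy * wz)
    return out


def _scatter(val, coords, shape):
    """Transpose of :func:`_gather`: splat values to the grid."""
    (x0, y0, z0), (x1, y1, z1), (fx, fy, fz) = _corner_weights(coords, shape)
    lead = val.shape[:-1]
    out = np.zeros(lead + (shape[0] * shape[1] * shape[2],), dtype=val.dtype)
    flat2 = out.reshape(-1, out.shape[-1])
    val2 = val.reshape(-1, val.shape[-1])
    for ix, wx in ((x0, 1 - fx), (x1, fx)):
        for iy, wy in ((y0, 1 - fy), (y1, fy)):
            for iz, wz in ((z0, 1 - fz), (z1, fz)):
                idx = _flat_index(ix, iy, iz, shape)
                w = wx * wy * wz
                for c in range(flat2.shape[0]):
                    np.add.at(flat2[c], idx, val2[c] * w)
    return out.reshape(lead + tuple(shape))


def _base_coords(shape, dtype=np.float64):
    g = np.meshgrid(*[np.arange(n, dtype=dtype) for n in shape], indexing="ij")
    return np.stack([a.ravel() for a in g])


def warp(volume: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Resample ``volume`` at ``x + disp(x)`` (trilinear, edge clamped).

    ``volume`` may be real or complex with optional leading channel axes;
    ``disp`` is (3, nx, ny, nz) in voxel units.  Linear in ``volume``.
    """
    volume = np.asarray(volume)
    shape = volume.shape[-3:]
    coords = _base_coords(shape, dtype=np.float64) + disp.reshape(3, -1)
    flat = volume.reshape(volume.shape[:-3] + (-1,))
    out = _gather(flat, coords, shape)
    return out.reshape(volume.shape)


def warp_adjoint(volume: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`warp` with the same displacement."""
    volume = np.asarray(volume)
    shape = volume.shape[-3:]
    coords = _base_coords(shape, dtype=np.float64) + disp.reshape(3, -1)
    flat = volume.reshape(volume.shape[:-3] + (-1,))
    out = _scatter(flat, coords, shape)
    return out.reshape(volume.shape)


def warp_grad_disp(volume: np.ndarray, disp: np.ndarray, upstream: np.ndarray) -> np.ndarray:
    """Gradient of ``sum(upstream * warp(volume, disp))`` w.r.t. ``disp``.

    Real-valued volumes only (the reconstruction graph carries complex data
    as channel pairs).  Where a sample coordinate is clamped to the volume
    edge the derivative w.r.t. that displacement component is zero, matching
    the clamped forward map.  Returns an array shaped like ``disp``.
    """
    volume = np.asarray(volume)
    shape = volume.shape[-3:]
    coords = _base_coords(shape, dtype=np.float64) + disp.reshape(3, -1)
    unclamped = [
        (coords[ax] > 0.0) & (coords[ax] < shape[ax] - 1.0) for ax in range(3)
    ]
    (x0, y0, z0), (x1, y1, z1), (fx, fy, fz) = _corner_weights(coords, shape)
    flat = volume.reshape(volume.shape[:-3] + (-1,))
    up = upstream.reshape(upstream.shape[:-3] + (-1,))

    def corner(ix, iy, iz):
        return flat[..., _flat_index(ix, iy, iz, shape)]

    c000, c001 = corner(x0, y0, z0), corner(x0, y0, z1)
    c010, c011 = corner(x0, y1, z0), corner(x0, y1, z1)
    c100, c101 = corner(x1, y0, z0), corner(x1, y0, z1)
    c110, c111 = corner(x1, y1, z0), corner(x1, y1, z1)
    wy0, wy1, wz0, wz1 = 1 - fy, fy, 1 - fz, fz
    wx0, wx1 = 1 - fx, fx
    ddx = (c100 - c000) * (wy0 * wz0) + (c101 - c001) * (wy0 * wz1) \
        + (c110 - c010) * (wy1 * wz0) + (c111 - c011) * (wy1 * wz1)
    ddy = (c010 - c000) * (wx0 * wz0) + (c011 - c001) * (wx0 * wz1) \
        + (c110 - c100) * (wx1 * wz0) + (c111 - c101) * (wx1 * wz1)
    ddz = (c001 - c000) * (wx0 * wy0) + (c011 - c010) * (wx0 * wy1) \
        + (c101 - c100) * (wx1 * wy0) + (c111 - c110) * (wx1 * wy1)
    sum_axes = tuple(range(up.ndim - 1))
    g = np.stack(
        [
            (up * ddx).sum(axis=sum_axes) * unclamped[0],
            (up * ddy).sum(axis=sum_axes) * unclamped[1],
            (up * ddz).sum(axis=sum_axes) * unclamped[2],
        ]
    )
    return g.reshape(disp.shape)


# ---------------------------------------------------------------------------
# translational motion: iNAV registration and Eq.-style phase correction
# ---------------------------------------------------------------------------


@dataclass
class RespTranslations:
    """Per-heartbeat 2D translation, mm, (foot-head, left-right).

    ``t_mm[m]`` is the difference between the motion position at heartbeat
    ``m`` and the mean position over all heartbeats; under the negative-
    exponent forward DFT used throughout this package, multiplying k-space
    by ``exp(2*pi*i k.t_mm[m])`` aligns every heartbeat to the mean
    position.  The foot-head component doubles as the respiratory binning
    signal (smallest value = most expiratory for a phantom whose diaphragm
    displacement grows with inspiration).
    """

    t_mm: np.ndarray

    def __post_init__(self) -> None:
        self.t_mm = np.asarray(self.t_mm, dtype=float).reshape(-1, 2)

    @property
    def n_heartbeats(self) -> int:
        return self.t_mm.shape[0]

    @property
    def fh(self) -> np.ndarray:
        return self.t_mm[:, 0]


def register_inavs(inavs: np.ndarray, roi=None, pixel_mm=(1.0, 1.0)) -> RespTranslations:
    """Per-heartbeat 2D translation from an iNAV stack by template matching.

    Two-pass cross-correlation template matching: navigators are first
    registered to the first frame, the stack is then re-aligned and
    averaged into an unbiased mean template, and each navigator is
    registered to that template (correlating against the raw stack mean
    would shrink every estimate toward the mixture of respiratory
    positions).  Sub-pixel peaks come from local upsampled-DFT refinement
    of the cross-correlation.  The returned translations are re-referenced
    to zero mean over heartbeats.

    ``roi`` is ``(r0, r1, c0, c1)`` half-open; default full frame.
    """
    from skimage.registration import phase_cross_correlation

    inavs = np.asarray(inavs, dtype=np.float64)
    if inavs.ndim != 3 or inavs.shape[0] < 2:
        raise ValueError("need a stack of at least two 2D iNAVs")
    if roi is None:
        roi = (0, inavs.shape[1], 0, inavs.shape[2])
    r0, r1, c0, c1 = roi
    if np.ptp(inavs) == 0:
        raise ValueError("flat iNAVs: correlation undefined")

    def positions_vs(template):
        tpl = template[r0:r1, c0:c1]
        tpl = tpl - tpl.mean()
        pos = np.zeros((inavs.shape[0], 2))
        for m, img in enumerate(inavs):
            z = img[r0:r1, c0:c1]
            shift = phase_cross_correlation(
                tpl, z - z.mean(), upsample_factor=20, normalization=None
            )[0]
            pos[m] = -shift  # displacement of the navigator vs the template
        return pos

    pos = positions_vs(inavs[0])
    pos -= pos.mean(axis=0)
    aligned = np.stack([_fourier_shift2(img, -p) for img, p in zip(inavs, pos)])
    pos = positions_vs(aligned.mean(axis=0))
    pos = (pos - pos.mean(axis=0)) * np.asarray(pixel_mm, dtype=float)
    return RespTranslations(pos)


def _fourier_shift2(img: np.ndarray, shift) -> np.ndarray:
    k0 = np.fft.fftfreq(img.shape[0])[:, None]
    k1 = np.fft.fftfreq(img.shape[1])[None, :]
    ph = np.exp(-2j * np.pi * (k0 * shift[0] + k1 * shift[1]))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * ph))


def phase_correct(kdata: KSpaceData, translations: RespTranslations) -> KSpaceData:
    """Remove per-heartbeat translational motion by k-space phase shifts.

    Each sample at 2D k-position ``(k_x, k_y)`` (cycles/mm) of heartbeat
    ``m`` is multiplied by ``exp(2*pi*i (k_x, k_y).T_m)`` with ``T_m`` in mm.
    The factor has unit modulus, so magnitudes are preserved exactly.
    """
    if translations.n_heartbeats != kdata.traj.n_heartbeats:
        raise ValueError("translation count does not match trajectory heartbeats")
    kx = kdata.kx_cycles_per_mm()  # (n_x,)
    ky = kdata.ky_cycles_per_mm()  # (n_readouts,)
    t = translations.t_mm[kdata.traj.heartbeat]  # (n_readouts, 2)
    phase = np.exp(
        2j * np.pi * (kx[None, :] * t[:, 0:1] + (ky * t[:, 1])[:, None])
    )
    return KSpaceData(
        data=kdata.data * phase[None, :, :],
        traj=kdata.traj,
        voxel_mm=kdata.voxel_mm,
        resp_t_mm=kdata.resp_t_mm,
        inavs=kdata.inavs,
        coils=kdata.coils,
    )


# ---------------------------------------------------------------------------
# soft-gated respiratory binning
# ---------------------------------------------------------------------------


@dataclass
class BinWeights:
    """Soft-gating weight matrix, heartbeats x bins, entries in [0, 1]."""

    weights: np.ndarray
    bin_centers: np.ndarray
    primary: np.ndarray
    end_exp_bin: int

    @property
    def n_bins(self) -> int:
        return self.weights.shape[1]

    @property
    def n_heartbeats(self) -> int:
        return self.weights.shape[0]


def bin_heartbeats(
    translations: RespTranslations,
    n_bins: int = 4,
    softness: float = 0.5,
    end_exp_sign: float = -1.0,
) -> BinWeights:
    """Sort heartbeats into equally populated foot-head bins with soft gating.

    Heartbeats are sorted by foot-head position and split into ``n_bins``
    groups whose sizes differ by at most one (the primary assignment).  The
    soft weight of heartbeat ``i`` in bin ``b`` is
    ``exp(-(d_ib / (softness * w_b))**2)`` with ``d_ib`` the distance to the
    bin center and ``w_b`` the bin half-width; the weight in the primary bin
    is 1, so ``softness -> 0`` recovers hard gating.  The end-expiration bin
    is the one whose center is extremal in the direction ``end_exp_sign``
    (negative under the position-minus-mean convention of
    :class:`RespTranslations` for a diaphragm displacement that grows with
    inspiration; configurable because the convention is scanner-dependent).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    fh = translations.fh
    n = fh.size
    if n < n_bins:
        raise ValueError("fewer heartbeats than bins")
    order = np.argsort(fh, kind="stable")
    primary = np.empty(n, dtype=np.int64)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        primary[chunk] = b
    centers = np.array([fh[primary == b].mean() for b in range(n_bins)])
    halfwidth = np.array(
        [max(np.abs(fh[primary == b] - centers[b]).max(), 1e-9) for b in range(n_bins)]
    )
    d = np.abs(fh[:, None] - centers[None, :])
    if softness <= 0:
        w = np.zeros((n, n_bins))
    else:
        w = np.exp(-((d / (softness * halfwidth[None, :])) ** 2))
    w[np.arange(n), primary] = 1.0
    end_exp = int(np.argmax(end_exp_sign * centers))
    return BinWeights(w, centers, primary, end_exp)


# ---------------------------------------------------------------------------
# diffeomorphic displacement fields
# ---------------------------------------------------------------------------


@dataclass
class MotionField:
    """Stationary velocity field and its integrated displacement fields.

    All fields are (3, nx, ny, nz) in voxel units; ``forward`` maps the
    reference frame to the moving frame under ``out(x) = ref(x + d(x))``
    and ``inverse`` is the integration of the negated velocity.
    """

    velocity: np.ndarray
    forward: np.ndarray
    inverse: np.ndarray
    n_squaring_steps: int = 6

    @classmethod
    def from_velocity(cls, velocity: np.ndarray, n_steps: int = 6) -> "MotionField":
        fwd, inv = integrate_velocity(velocity, n_steps)
        return cls(velocity, fwd, inv, n_steps)

    @classmethod
    def identity(cls, shape) -> "MotionField":
        z = np.zeros((3, *shape))
        return cls(z, z.copy(), z.copy())


def integrate_velocity(velocity: np.ndarray, n_steps: int = 6):
    """Exponentiate a stationary velocity field by scaling and squaring.

    ``phi = v / 2**n`` followed by ``n`` self-compositions
    ``phi <- phi + phi(x + phi)``; the inverse displacement integrates
    ``-v``.  Returns ``(forward, inverse)`` displacement fields.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    velocity = np.asarray(velocity, dtype=np.float64)
    if not np.isfinite(velocity).all():
        raise ValueError("non-finite velocity field")

    def expmap(v):
        phi = v / (2.0 ** n_steps)
        for _ in range(n_steps):
            phi = phi + warp(phi, phi)
        return phi

    return expmap(velocity), expmap(-velocity)
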