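"""Encoding operator E = U F S M and the solvers built on it.

``E`` maps a single reference-frame complex volume to the soft-gated
multi-bin multi-coil sample vector: for each respiratory bin the volume is
warped to the bin frame (M), multiplied by each coil sensitivity (S),
transformed with the unitary centered 3D FFT (F) and sampled at the bin's
acquired (ky, kz) locations with the bin's soft-gating weight (U).  Samples
acquired multiple times are kept as separate rows, so re-acquired center
readouts accumulate naturally in the adjoint.

Soft weights enter both E and its adjoint, so the normal operator E*E
carries the weights squared (the weighted-least-squares reading of soft
gating), while the right-hand side E*b applies them once to the raw data.

Two adjoints of the warp are available: the cheap inverse-field warp the
reconstruction uses, and the exact transpose (splatting) under which
<E rho, y> = <rho, E* y> holds to machine precision — the mode used by the
operator test-harness and the normal-equation theory.

The conjugate-gradient solver records residual norms per call and returns
the iterate with the smallest normal-equation residual (the warm start is
a candidate), so a data-consistency step can never increase the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motion import BinWeights, MotionField, warp, warp_adjoint
from .phantom import fft3c, ifft3c
from .rawdata import KSpaceData

__all__ = [
    "EncodingOperator",
    "CGReport",
    "apply_E",
    "apply_E_adjoint",
    "zero_filled_recon",
    "cg_solve",
    "sense_recon",
]


@dataclass
class CGReport:
    """Residual-norm trace of one conjugate-gradient call."""

    residual_norms: list = field(default_factory=list)
    n_iter: int = 0
    final_relative_residual: float = np.nan
    chosen_iterate: int = 0


class EncodingOperator:
    """Motion-corrected multi-bin SENSE encoding for one acquisition.

    Parameters
    ----------
    volume_shape : (nx, ny, nz)
    coils : complex (n_coils, nx, ny, nz)
    readouts, heartbeat : trajectory arrays ((N, 2) int and (N,) int)
    bin_weights : :class:`~respmoco.motion.BinWeights` or an (H, n_bins)
        weight matrix; expanded to per-readout weights via the heartbeat
        index.  Rows with weight below ``weight_threshold`` are dropped
        from a bin.
    motion : sequence of per-bin :class:`~respmoco.motion.MotionField`
        (displacements from the reference frame to each bin), or None for
        identity motion.
    adjoint_mode : 'paper' warps by the inverse field in the adjoint;
        'exact' uses the transpose splat.
    """

    def __init__(
        self,
        volume_shape,
        coils,
        readouts,
        heartbeat,
        bin_weights,
        motion=None,
        adjoint_mode: str = "paper",
        weight_threshold: float = 1e-8,
    ):
        self.volume_shape = tuple(volume_shape)
        self.coils = np.asarray(coils)
        if self.coils.shape[1:] != self.volume_shape:
            raise ValueError("coil maps do not match volume shape")
        if adjoint_mode not in ("paper", "exact"):
            raise ValueError("adjoint_mode must be 'paper' or 'exact'")
        self.adjoint_mode = adjoint_mode
        readouts = np.asarray(readouts)
        heartbeat = np.asarray(heartbeat)
        W = bin_weights.weights if isinstance(bin_weights, BinWeights) else np.asarray(bin_weights)
        self.n_bins = W.shape[1]
        self.motion = motion
        if motion is not None and len(motion) != self.n_bins:
            raise ValueError("need one motion field per bin")
        w_rows = W[heartbeat]  # (N, n_bins)
        self.rows: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        self.flat_loc: list[np.ndarray] = []
        ny, nz = self.volume_shape[1], self.volume_shape[2]
        for b in range(self.n_bins):
            keep = np.flatnonzero(w_rows[:, b] > weight_threshold)
            self.rows.append(keep)
            self.weights.append(w_rows[keep, b])
            pts = readouts[keep]
            self.flat_loc.append(pts[:, 0].astype(np.int64) * nz + pts[:, 1].astype(np.int64))

    # -- factor applications -------------------------------------------------

    def _warp_to_bin(self, rho, b):
        if self.motion is None:
            return rho
        return warp(rho, self.motion[b].forward)

    def _warp_to_ref(self, vol, b):
        if self.motion is None:
            return vol
        if self.adjoint_mode == "paper":
            return warp(vol, self.motion[b].inverse)
        return warp_adjoint(vol, self.motion[b].forward)

    # -- E and E* ------------------------------------------------------------

    def apply(self, rho: np.ndarray) -> list[np.ndarray]:
        """E rho: per-bin weighted samples, each (n_coils, n_rows_b, nx)."""
        nx, ny, nz = self.volume_shape
        out = []
        for b in range(self.n_bins):
            vol = self._warp_to_bin(rho, b)
            ks = fft3c(self.coils * vol[None])
            flat = ks.reshape(ks.shape[0], nx, ny * nz)
            samp = flat[:, :, self.flat_loc[b]]  # (nc, nx, rows)
            out.append(np.moveaxis(samp, 2, 1) * self.weights[b][None, :, None])
        return out

    def adjoint(self, samples: list[np.ndarray]) -> np.ndarray:
        """E* y for per-bin sample blocks shaped like :meth:`apply` output."""
        nx, ny, nz = self.volume_shape
        rho = np.zeros(self.volume_shape, dtype=np.complex128)
        for b in range(self.n_bins):
            y = samples[b]
            nc = y.shape[0]
            grid = np.zeros((ny * nz, nc, nx), dtype=np.complex128)
            contrib = np.moveaxis(y * self.weights[b][None, :, None], 1, 0)  # (rows, nc, nx)
            np.add.at(grid, self.flat_loc[b], contrib)
            ks = np.moveaxis(grid, 0, 2).reshape(nc, nx, ny, nz)
            vol = (np.conj(self.coils) * ifft3c(ks)).sum(axis=0)
            rho = rho + self._warp_to_ref(vol, b)
        return rho

    def normal(self, rho: np.ndarray) -> np.ndarray:
        return self.adjoint(self.apply(rho))

    # -- bookkeeping ---------------------------------------------------------

    def data_vector(self, kdata_rows: np.ndarray) -> list[np.ndarray]:
        """Raw (unweighted) per-bin sample blocks from full data rows."""
        return [kdata_rows[:, self.rows[b], :] for b in range(self.n_bins)]

    def rhs(self, kdata_rows: np.ndarray) -> np.ndarray:
        """E* b with the weights applied once to the raw data."""
        b_blocks = self.data_vector(kdata_rows)
        # adjoint() multiplies by the weights internally; feed raw data
        return self.adjoint(b_blocks)

    def residual_norm(self, rho: np.ndarray, kdata_rows: np.ndarray) -> float:
        """Weighted data-space residual ||W(A rho - b)||."""
        model = self.apply(rho)  # already W A rho
        raw = self.data_vector(kdata_rows)
        sq = 0.0
        for b in range(self.n_bins):
            diff = model[b] - self.weights[b][None, :, None] * raw[b]
            sq += float(np.vdot(diff, diff).real)
        return np.sqrt(sq)

    def pack(self, samples: list[np.ndarray]) -> np.ndarray:
        return np.concatenate([s.ravel() for s in samples])

    def unpack(self, vec: np.ndarray) -> list[np.ndarray]:
        out, ofs = [], 0
        nx = self.volume_shape[0]
        for b in range(self.n_bins):
            nc = self.coils.shape[0]
            n = nc * len(self.rows[b]) * nx
            out.append(vec[ofs : ofs + n].reshape(nc, len(self.rows[b]), nx))
            ofs += n
        return out


def apply_E(rho: np.ndarray, op: EncodingOperator) -> list[np.ndarray]:
    return op.apply(rho)


def apply_E_adjoint(samples: list[np.ndarray], op: EncodingOperator) -> np.ndarray:
    return op.adjoint(samples)


def zero_filled_recon(kdata: KSpaceData, bins: BinWeights, coils: np.ndarray) -> np.ndarray:
    """Per-bin motion-free zero-filled image S* F^-1 U^T b.

    Re-acquired readouts (the k-space center is revisited every heartbeat)
    are averaged by the location's total acquisition count over the scan,
    so the zero-filled image is a proper projection of the fully sampled
    one — its energy never exceeds it — and disjoint hard bins sum to the
    pooled zero-filled image.  The least-squares operator adjoint, in
    contrast, keeps duplicate rows separate.

    Returns (n_bins, nx, ny, nz) complex volumes — the framework input.
    """
    op = EncodingOperator(
        kdata.volume_shape, coils, kdata.traj.readouts, kdata.traj.heartbeat, bins, motion=None
    )
    nx, ny, nz = kdata.volume_shape
    traj = kdata.traj
    all_loc = traj.readouts[:, 0].astype(np.int64) * nz + traj.readouts[:, 1].astype(np.int64)
    counts = np.bincount(all_loc, minlength=ny * nz).astype(float)
    vols = []
    for b in range(op.n_bins):
        y = kdata.data[:, op.rows[b], :]  # (nc, rows, nx)
        nc = y.shape[0]
        grid = np.zeros((ny * nz, nc, nx), dtype=np.complex128)
        contrib = np.moveaxis(y * op.weights[b][None, :, None], 1, 0)
        np.add.at(grid, op.flat_loc[b], contrib)
        grid /= np.maximum(counts, 1.0)[:, None, None]
        ks = np.moveaxis(grid, 0, 2).reshape(nc, nx, ny, nz)
        vols.append((np.conj(coils) * ifft3c(ks)).sum(axis=0))
    return np.stack(vols)


def _single_bin(op: EncodingOperator, b: int) -> EncodingOperator:
    """View of one bin of an operator (shares arrays, no motion change)."""
    view = EncodingOperator.__new__(EncodingOperator)
    view.volume_shape = op.volume_shape
    view.coils = op.coils
    view.adjoint_mode = op.adjoint_mode
    view.n_bins = 1
    view.motion = None if op.motion is None else [op.motion[b]]
    view.rows = [op.rows[b]]
    view.weights = [op.weights[b]]
    view.flat_loc = [op.flat_loc[b]]
    return view


def cg_solve(normal_op, rhs: np.ndarray, x0: np.ndarray | None = None, n_iter: int = 3,
             tol: float = 0.0) -> tuple[np.ndarray, CGReport]:
    """Conjugate gradients on ``A x = rhs`` for Hermitian PSD ``A``.

    ``normal_op`` is a callable applying ``A``.  Iterates from the warm
    start ``x0``; stops after ``n_iter`` iterations or when the relative
    residual falls below ``tol``.  Returns the iterate with the smallest
    recorded residual norm (the warm start included), so the residual of
    the result never exceeds that of the start.
    """
    if not np.isfinite(rhs).all():
        raise ValueError("non-finite right-hand side")
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - normal_op(x)
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rhs_norm = float(np.linalg.norm(rhs)) or 1.0
    report = CGReport(residual_norms=[np.sqrt(rs)])
    best_x, best_r, best_i = x.copy(), np.sqrt(rs), 0
    for it in range(n_iter):
        if np.sqrt(rs) / rhs_norm <= tol:
            break
        ap = normal_op(p)
        denom = float(np.vdot(p, ap).real)
        if denom <= 0:
            break
        alpha = rs / denom
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = float(np.vdot(r, r).real)
        report.residual_norms.append(np.sqrt(rs_new))
        report.n_iter = it + 1
        if np.sqrt(rs_new) < best_r:
            best_x, best_r, best_i = x.copy(), np.sqrt(rs_new), it + 1
        beta = rs_new / rs
        p = r + beta * p
        rs = rs_new
    report.final_relative_residual = best_r / rhs_norm
    report.chosen_iterate = best_i
    return best_x, report


def sense_recon(
    kdata: KSpaceData,
    coils: np.ndarray,
    bins: BinWeights,
    bin_index: int,
    n_iter: int = 10,
    restart_every: int | None = None,
    x0: np.ndarray | None = None,
):
    """Iterative SENSE reconstruction of one respiratory bin (M = identity).

    Solves ``E_b* E_b rho = E_b* b`` by CG, 10 iterations by default; with
    ``restart_every`` the CG is run in warm-started chunks of that many
    iterations (the iteration structure of the unrolled reconstruction).
    Returns ``(volume, [CGReport, ...])``.
    """
    op = EncodingOperator(
        kdata.volume_shape, coils, kdata.traj.readouts, kdata.traj.heartbeat, bins, motion=None
    )
    single = _single_bin(op, bin_index)
    rhs = single.adjoint([kdata.data[:, op.rows[bin_index], :]])
    reports = []
    x = np.zeros_like(rhs) if x0 is None else x0
    chunk = n_iter if restart_every is None else restart_every
    done = 0
    while done < n_iter:
        n = min(chunk, n_iter - done)
        x, rep = cg_solve(single.normal, rhs, x0=x, n_iter=n)
        reports.append(rep)
        done += n
    return x, reports
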