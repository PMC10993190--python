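"""Variable-density spiral-profile Cartesian phase-encode trajectories.

A 3D Cartesian whole-heart acquisition reads a fully sampled ``k_x`` line at
each of a set of phase-encode locations in the ``k_y``-``k_z`` plane.  The
locations acquired within one heartbeat form a spiral-like interleaf;
successive interleaves are rotated by the golden angle.  An elliptical
shutter omits the corners of the rectangular phase-encode grid (saving a
factor of 4/pi of samples) and a small disc around DC is always fully
covered over the scan.

This module generates such trajectories, measures their acceleration both
against the shutter interior (nominal) and against the full rectangular grid
(effective), and implements the density-preserving retrospective
undersampling used to build training data: the plane is segmented into
elliptic annuli and, within each annulus, a random subset of the acquired
readouts is retained so the per-annulus acquisition fraction matches a
target profile.  The retained readouts are a strict subset of the source
acquisition, so no synthetic k-space ever enters training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GOLDEN_ANGLE_RAD = np.pi * (3.0 - np.sqrt(5.0))  # ~111.25 degrees

__all__ = [
    "GridSpec",
    "Trajectory",
    "AnnulusProfile",
    "make_shutter",
    "elliptical_radius",
    "generate_caspr",
    "full_trajectory",
    "effective_accel_rectangular",
    "measure_annulus_profile",
    "retrospective_undersample",
]


@dataclass(frozen=True)
class GridSpec:
    """Phase-encode grid in the ky-kz plane, DC at ``(n_ky//2, n_kz//2)``."""

    n_ky: int
    n_kz: int

    def __post_init__(self) -> None:
        if self.n_ky < 8 or self.n_kz < 8:
            raise ValueError("phase-encode grid must be at least 8x8")

    @property
    def center(self) -> tuple[int, int]:
        return (self.n_ky // 2, self.n_kz // 2)


@dataclass
class Trajectory:
    """Ordered phase-encode readouts grouped into per-heartbeat interleaves.

    ``readouts`` is an ``(N, 2)`` int array of (ky, kz) indices and
    ``heartbeat`` an ``(N,)`` int array assigning each readout to a
    contiguous heartbeat index ``0..n_heartbeats-1``.  One interleaf is
    acquired per heartbeat, so the interleaf id equals the heartbeat index.
    """

    grid: GridSpec
    readouts: np.ndarray
    heartbeat: np.ndarray
    nominal_accel: float = 1.0
    r_center: float = 0.0

    def __post_init__(self) -> None:
        self.readouts = np.asarray(self.readouts, dtype=np.int32).reshape(-1, 2)
        self.heartbeat = np.asarray(self.heartbeat, dtype=np.int32).reshape(-1)
        if self.readouts.shape[0] != self.heartbeat.shape[0]:
            raise ValueError("readouts and heartbeat arrays disagree in length")

    @property
    def n_readouts(self) -> int:
        return int(self.readouts.shape[0])

    @property
    def n_heartbeats(self) -> int:
        return int(self.heartbeat.max()) + 1 if self.n_readouts else 0

    @property
    def interleaf(self) -> np.ndarray:
        return self.heartbeat

    def unique_locations(self) -> np.ndarray:
        """Unique acquired (ky, kz) locations, lexicographically sorted."""
        return np.unique(self.readouts, axis=0)

    def readouts_of_beat(self, m: int) -> np.ndarray:
        return self.readouts[self.heartbeat == m]

    def validate(self) -> None:
        ky, kz = self.readouts[:, 0], self.readouts[:, 1]
        if ky.min() < 0 or kz.min() < 0 or ky.max() >= self.grid.n_ky or kz.max() >= self.grid.n_kz:
            raise ValueError("readout outside grid")
        shutter = make_shutter(self.grid)
        if not shutter[ky, kz].all():
            raise ValueError("readout outside elliptical shutter")
        # no duplicate location within one heartbeat
        key = (self.heartbeat.astype(np.int64) * self.grid.n_ky + ky) * self.grid.n_kz + kz
        if np.unique(key).size != key.size:
            raise ValueError("duplicate (ky,kz) within a heartbeat")


@dataclass
class AnnulusProfile:
    """Per-annulus acquired fraction over equal-width elliptic annuli.

    ``boundaries`` holds ``n_annuli + 1`` strictly increasing radii in
    normalized elliptical coordinates spanning [0, 1]; ``acquired_fraction``
    is the fraction of shutter locations within each annulus that were
    acquired (NaN where an annulus contains no shutter point).
    """

    boundaries: np.ndarray
    acquired_fraction: np.ndarray
    shutter_counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_annuli(self) -> int:
        return len(self.acquired_fraction)


def make_shutter(grid: GridSpec) -> np.ndarray:
    """Boolean mask of the inscribed ellipse: True inside (inclusive)."""
    r = elliptical_radius(grid)
    return r <= 1.0


def elliptical_radius(grid: GridSpec) -> np.ndarray:
    """Normalized elliptical radius of every grid point (DC -> 0)."""
    cy, cz = grid.center
    ky = np.arange(grid.n_ky)[:, None]
    kz = np.arange(grid.n_kz)[None, :]
    return np.sqrt(((ky - cy) / (grid.n_ky / 2.0)) ** 2 + ((kz - cz) / (grid.n_kz / 2.0)) ** 2)


def _point_radius(grid: GridSpec, pts: np.ndarray) -> np.ndarray:
    cy, cz = grid.center
    return np.sqrt(
        ((pts[:, 0] - cy) / (grid.n_ky / 2.0)) ** 2 + ((pts[:, 1] - cz) / (grid.n_kz / 2.0)) ** 2
    )


def _flat(grid: GridSpec, pts: np.ndarray) -> np.ndarray:
    return pts[:, 0].astype(np.int64) * grid.n_kz + pts[:, 1].astype(np.int64)


def generate_caspr(
    grid: GridSpec,
    nominal_accel: float,
    n_heartbeats: int,
    readouts_per_beat: int | None = None,
    r_center: float = 0.12,
    rng_seed: int = 0,
    beta: float = 2.0,
    gamma: float = 2.0,
    n_turns: float = 1.5,
) -> Trajectory:
    """Generate a variable-density spiral-profile Cartesian trajectory.

    Each heartbeat acquires one Archimedean spiral arm in normalized
    elliptical coordinates (angle increasing monotonically with radius,
    successive arms rotated by the golden angle) with radial sample spacing
    growing linearly with radius, so sampling density falls off towards the
    shutter edge.  The DC point is acquired every heartbeat and the disc of
    radius ``r_center`` is covered over the scan (distributed round-robin
    across heartbeats), emulating a fully sampled k-space center.

    The total number of *unique* acquired locations is forced to exactly
    ``round(count(shutter) / nominal_accel)``: after the spiral arms are
    laid down, surplus locations are removed (outer-radius-first by the
    retention law) or missing ones added (sampled from the same law), so the
    nominal acceleration is met to within rounding.
    """
    if nominal_accel < 1:
        raise ValueError("nominal_accel must be >= 1")
    shutter = make_shutter(grid)
    n_shutter = int(shutter.sum())
    budget = int(round(n_shutter / nominal_accel))

    radius = elliptical_radius(grid)
    center_pts = np.argwhere(shutter & (radius <= r_center))
    if center_pts.shape[0] > budget:
        raise ValueError(
            f"fully sampled center disc (r_center={r_center}) needs "
            f"{center_pts.shape[0]} locations but the acquisition budget is {budget}"
        )
    if readouts_per_beat is None:
        readouts_per_beat = max(1, int(np.ceil(budget / n_heartbeats)))
    if abs(n_heartbeats * readouts_per_beat - budget) > readouts_per_beat + n_heartbeats:
        raise ValueError(
            "n_heartbeats * readouts_per_beat must approximate the acquisition budget "
            f"({n_heartbeats}x{readouts_per_beat} vs {budget})"
        )

    rng = np.random.default_rng(rng_seed)
    cy, cz = grid.center
    ay, az = grid.n_ky / 2.0, grid.n_kz / 2.0

    # retention probability of the variable-density law, used both for arm
    # thinning and for budget correction
    def density(r: np.ndarray) -> np.ndarray:
        p = (1.0 + beta * np.maximum(r - r_center, 0.0)) ** (-gamma)
        return np.where(r <= r_center, 1.0, p)

    per_beat: list[np.ndarray] = []
    dc = np.array(grid.center, dtype=np.int64)
    n_arm_candidates = max(readouts_per_beat * 3, 8)
    for m in range(n_heartbeats):
        theta0 = m * GOLDEN_ANGLE_RAD
        # radial positions with spacing growing linearly with radius:
        # r(u) ~ sqrt-free warp u**(1+q); denser near center
        u = (np.arange(n_arm_candidates) + 0.5) / n_arm_candidates
        r = u ** (1.0 + 0.8)
        keep = rng.random(n_arm_candidates) < density(r)
        # thin by the density law but always keep an inner sample
        keep[0] = True
        r = r[keep]
        theta = theta0 + 2.0 * np.pi * n_turns * r  # angle monotone in radius
        ky = np.rint(cy + r * ay * np.cos(theta)).astype(np.int64)
        kz = np.rint(cz + r * az * np.sin(theta)).astype(np.int64)
        pts = np.stack([ky, kz], axis=1)
        # round-robin share of the fully sampled center disc
        share = center_pts[m % max(n_heartbeats, 1) :: n_heartbeats]
        pts = np.concatenate([dc[None, :], share, pts], axis=0)
        inside = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] < grid.n_ky)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] < grid.n_kz)
        )
        pts = pts[inside]
        pts = pts[shutter[pts[:, 0], pts[:, 1]]]
        # dedupe within the heartbeat, keep acquisition (radial) order
        _, first = np.unique(_flat(grid, pts), return_index=True)
        pts = pts[np.sort(first)]
        # trim the arm to its nominal length (keep center share + innermost)
        n_keep = readouts_per_beat + 1 + share.shape[0]
        per_beat.append(pts[:n_keep])

    traj = _assemble(grid, per_beat, nominal_accel, r_center)
    traj = _enforce_budget(traj, budget, density, rng, protected_radius=r_center)
    traj.validate()
    return traj


def _assemble(
    grid: GridSpec, per_beat: list[np.ndarray], nominal_accel: float, r_center: float
) -> Trajectory:
    readouts = np.concatenate(per_beat, axis=0)
    heartbeat = np.concatenate(
        [np.full(len(p), m, dtype=np.int32) for m, p in enumerate(per_beat)]
    )
    return Trajectory(grid, readouts, heartbeat, nominal_accel, r_center)


def _enforce_budget(traj, budget, density, rng, protected_radius):
    """Add or remove unique locations so their count equals the budget."""
    grid = traj.grid
    shutter = make_shutter(grid)
    uniq = traj.unique_locations()
    n = uniq.shape[0]
    if n > budget:
        r = _point_radius(grid, uniq)
        removable = r > protected_radius
        idx = np.flatnonzero(removable)
        # remove preferentially where the density law retains least
        w = 1.0 - density(r[idx])
        w = w + 1e-6
        drop = rng.choice(idx, size=n - budget, replace=False, p=w / w.sum())
        drop_keys = set(_flat(grid, uniq[drop]).tolist())
        keep = np.array(
            [k not in drop_keys for k in _flat(grid, traj.readouts)], dtype=bool
        )
        traj = Trajectory(
            grid, traj.readouts[keep], traj.heartbeat[keep], traj.nominal_accel, traj.r_center
        )
    elif n < budget:
        acquired = np.zeros((grid.n_ky, grid.n_kz), dtype=bool)
        acquired[uniq[:, 0], uniq[:, 1]] = True
        cand = np.argwhere(shutter & ~acquired)
        w = density(_point_radius(grid, cand)) + 1e-6
        add = cand[
            rng.choice(cand.shape[0], size=budget - n, replace=False, p=w / w.sum())
        ]
        beats = rng.integers(0, traj.n_heartbeats, size=add.shape[0])
        readouts = np.concatenate([traj.readouts, add.astype(np.int32)], axis=0)
        heartbeat = np.concatenate([traj.heartbeat, beats.astype(np.int32)])
        # restore per-beat grouping order
        order = np.argsort(heartbeat, kind="stable")
        traj = Trajectory(
            grid, readouts[order], heartbeat[order], traj.nominal_accel, traj.r_center
        )
    return traj


def full_trajectory(grid: GridSpec, n_heartbeats: int = 1, rectangular: bool = False) -> Trajectory:
    """Fully sampled trajectory, each location acquired exactly once.

    Covers the shutter interior, or with ``rectangular`` the whole ky-kz
    grid including the corners the shutter would omit (needed for exact
    FFT round-trip identities).  Locations are dealt round-robin to
    heartbeats in radius order.
    """
    if rectangular:
        pts = np.argwhere(np.ones((grid.n_ky, grid.n_kz), dtype=bool))
    else:
        pts = np.argwhere(make_shutter(grid))
    order = np.argsort(_point_radius(grid, pts), kind="stable")
    pts = pts[order]
    heartbeat = np.arange(pts.shape[0]) % n_heartbeats
    order = np.argsort(heartbeat, kind="stable")
    return Trajectory(grid, pts[order].astype(np.int32), heartbeat[order].astype(np.int32), 1.0)


def effective_accel_rectangular(traj: Trajectory) -> float:
    """Undersampling factor relative to the full rectangular ky-kz grid."""
    n_unique = traj.unique_locations().shape[0]
    if n_unique == 0:
        raise ValueError("empty trajectory")
    return traj.grid.n_ky * traj.grid.n_kz / n_unique


def measure_annulus_profile(traj: Trajectory, n_annuli: int = 20) -> AnnulusProfile:
    """Fraction of shutter locations acquired in each elliptic annulus.

    Annulus boundaries are equally spaced in normalized elliptical radius;
    fractions are computed on unique acquired locations.  An annulus with no
    shutter point reports NaN.
    """
    if n_annuli < 2:
        raise ValueError("n_annuli must be >= 2")
    grid = traj.grid
    boundaries = np.linspace(0.0, 1.0, n_annuli + 1)
    radius = elliptical_radius(grid)
    shutter = make_shutter(grid)
    ann_of = _annulus_index(radius, n_annuli)
    shutter_counts = np.bincount(ann_of[shutter], minlength=n_annuli)

    uniq = traj.unique_locations()
    r_u = _point_radius(grid, uniq)
    acq_counts = np.bincount(_annulus_index(r_u, n_annuli), minlength=n_annuli)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(shutter_counts > 0, acq_counts / np.maximum(shutter_counts, 1), np.nan)
    return AnnulusProfile(boundaries, frac, shutter_counts)


def _annulus_index(r, n_annuli: int) -> np.ndarray:
    """Annulus of a normalized radius: half-open bins, outermost inclusive."""
    idx = np.floor(np.asarray(r) * n_annuli).astype(np.int64)
    return np.clip(idx, 0, n_annuli - 1)


def retrospective_undersample(
    traj: Trajectory, target_profile: AnnulusProfile, rng_seed: int = 0
) -> Trajectory:
    """Subset a trajectory so per-annulus fractions match a target profile.

    Within each annulus a random subset of the acquired locations is
    retained (all of their readouts, heartbeat assignment untouched) so the
    acquired fraction matches the target within one readout.  Annuli whose
    target fraction is 1 are left untouched.  The result is a strict subset
    of the source readouts; it is an error for any annulus to require more
    locations than the source acquired there.
    """
    grid = traj.grid
    n_annuli = target_profile.n_annuli
    source = measure_annulus_profile(traj, n_annuli)
    rng = np.random.default_rng(rng_seed)

    uniq = traj.unique_locations()
    ann_u = _annulus_index(_point_radius(grid, uniq), n_annuli)
    keep_keys: list[np.ndarray] = []
    for a in range(n_annuli):
        in_a = uniq[ann_u == a]
        n_src = in_a.shape[0]
        if n_src == 0:
            continue
        tgt_frac = target_profile.acquired_fraction[a]
        if np.isnan(tgt_frac):
            tgt_frac = source.acquired_fraction[a]
        n_tgt = int(round(tgt_frac * source.shutter_counts[a]))
        if n_tgt > n_src:
            raise ValueError(
                f"annulus {a}: target needs {n_tgt} locations but source acquired {n_src}"
            )
        if n_tgt >= n_src:
            keep_keys.append(_flat(grid, in_a))
        else:
            sel = rng.choice(n_src, size=n_tgt, replace=False)
            keep_keys.append(_flat(grid, in_a[sel]))
    kept = set(np.concatenate(keep_keys).tolist()) if keep_keys else set()
    mask = np.array([k in kept for k in _flat(grid, traj.readouts)], dtype=bool)
    out = Trajectory(
        grid,
        traj.readouts[mask],
        traj.heartbeat[mask],
        nominal_accel=traj.nominal_accel,
        r_center=traj.r_center,
    )
    return out
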