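"""Quantitative evaluation: ROI error metrics and group statistics.

Reconstructions are compared against a co-registered reference inside a
cuboid region of interest around the heart.  Both magnitudes are
normalized by the reference's 99th percentile within the ROI (and clipped
to [0, 1]), making the metrics invariant to global intensity scaling of
the reconstruction; MSE is the mean squared difference and SSIM the
standard Gaussian-window structural similarity with data range 1 on the
3D ROI.  Group differences between two reconstruction methods are
assessed with a two-sided paired-samples t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = ["RoiBox", "EvalResult", "roi_metrics", "paired_ttest"]


@dataclass(frozen=True)
class RoiBox:
    """Cuboid ROI, 0-based half-open voxel intervals."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0 or self.z1 <= self.z0:
            raise ValueError("empty ROI")

    def crop(self, vol: np.ndarray) -> np.ndarray:
        return vol[self.x0 : self.x1, self.y0 : self.y1, self.z0 : self.z1]

    @classmethod
    def from_tuple(cls, t) -> "RoiBox":
        return cls(*[int(v) for v in t])


@dataclass
class EvalResult:
    """Per-case metrics plus the paired comparison of two methods."""

    mse_a: list
    ssim_a: list
    mse_b: list
    ssim_b: list
    t_mse: float = np.nan
    p_mse: float = np.nan
    t_ssim: float = np.nan
    p_ssim: float = np.nan


def roi_metrics(recon: np.ndarray, reference: np.ndarray, roi: RoiBox | tuple):
    """(MSE, SSIM) of a reconstruction against a reference within an ROI.

    Magnitudes are taken; the reconstruction is first intensity-matched to
    the reference by the ratio of ROI means (making the metrics invariant
    to global scaling of the reconstruction without biasing the noise
    level), then both volumes are normalized by the reference's 99th
    percentile inside the ROI and clipped to [0, 1]; SSIM uses Gaussian
    windows with data range 1.
    """
    if recon.shape != reference.shape:
        raise ValueError("volumes must share a grid")
    if not isinstance(roi, RoiBox):
        roi = RoiBox.from_tuple(roi)
    a = np.abs(roi.crop(recon)).astype(np.float64)
    r = np.abs(roi.crop(reference)).astype(np.float64)
    if min(a.shape) < 7:
        raise ValueError("ROI too small for windowed SSIM")
    scale_r = np.percentile(r, 99)
    if scale_r <= 0 or a.mean() <= 0:
        raise ValueError("degenerate ROI: empty volume")
    a = a * (r.mean() / a.mean())
    a = np.clip(a / scale_r, 0.0, 1.0)
    r = np.clip(r / scale_r, 0.0, 1.0)
    mse = float(np.mean((a - r) ** 2))
    ssim = float(
        structural_similarity(r, a, data_range=1.0, gaussian_weights=True, win_size=7)
    )
    return mse, ssim


def paired_ttest(a, b):
    """Two-sided paired-samples t-test; returns ``(t, p)``.

    Zero variance of the paired differences makes the statistic
    degenerate; a warning is issued and ``(0, 1)`` or ``(inf, 0)`` is
    returned depending on whether the mean difference is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized groups of at least 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero variance of paired differences; t-test degenerate")
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.inf) * np.sign(d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
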