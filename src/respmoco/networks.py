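"""The two learnable components of the reconstruction.

* A diffeomorphic respiratory motion-estimation network: a fully
  convolutional 3D U-Net taking a pair of magnitude bin images (reference
  end-expiration bin and one moving bin) on a 2x-downsampled grid and
  regressing a stationary velocity field, which is integrated by scaling
  and squaring into forward/inverse diffeomorphic displacements and
  upsampled (with the displacement values doubled) back to full
  resolution.
* A denoising 3D U-Net acting on the real/imaginary channel pair of the
  data-consistency output, with a residual connection so the network
  learns a correction.

Both velocity and correction heads are zero-initialized: at initialization
the motion network returns exactly the identity field and the denoiser is
exactly the identity map, so the untrained framework reduces to
translational-only correction plus plain data consistency.

Architectures follow a conventional levels/channels contract (3 levels,
16/32/64 channels at full scale) and are fully configurable; behaviour,
not architecture, is what the test-suite pins down.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .motion import MotionField

__all__ = [
    "UNetConfig",
    "UNet3D",
    "MotionEstimator",
    "Denoiser",
    "estimate_motion",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class UNetConfig:
    in_channels: int
    out_channels: int
    levels: int = 3
    base_channels: int = 16
    kernel: int = 3
    leak: float = 0.1
    zero_init_head: bool = True
    seed: int = 0
    dtype: str = "float32"


class UNet3D:
    """Fully convolutional 3D U-Net with average-pool down/linear-up sampling.

    Two convolutions per level with leaky-ReLU activations, channel count
    doubling per level, skip connections by concatenation, and a final
    (optionally zero-initialized) convolution head.
    """

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        self.params: dict[str, ad.Tensor] = {}
        rng = np.random.default_rng(cfg.seed)
        dt = np.dtype(cfg.dtype)
        k = cfg.kernel

        def conv_param(name, cin, cout, zero=False):
            if zero:
                w = np.zeros((cout, cin, k, k, k), dtype=dt)
            else:
                std = np.sqrt(2.0 / (cin * k ** 3))
                w = rng.normal(0, std, (cout, cin, k, k, k)).astype(dt)
            self.params[name + ".w"] = ad.parameter(w)
            self.params[name + ".b"] = ad.parameter(np.zeros(cout, dtype=dt))

        chans = [cfg.base_channels * 2 ** l for l in range(cfg.levels)]
        cin = cfg.in_channels
        for l, c in enumerate(chans):
            conv_param(f"down{l}.0", cin, c)
            conv_param(f"down{l}.1", c, c)
            cin = c
        for l in range(cfg.levels - 2, -1, -1):
            c = chans[l]
            conv_param(f"up{l}.0", chans[l + 1] + c, c)
            conv_param(f"up{l}.1", c, c)
        conv_param("head", chans[0], cfg.out_channels, zero=cfg.zero_init_head)

    def _conv(self, name, x):
        return ad.conv3d(x, self.params[name + ".w"], self.params[name + ".b"])

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        cfg = self.cfg
        for ax, n in enumerate(x.shape[1:]):
            if n % (2 ** (cfg.levels - 1)) != 0:
                raise ValueError(
                    f"spatial axis {ax} (size {n}) not divisible by {2 ** (cfg.levels - 1)}"
                )
        skips = []
        for l in range(cfg.levels):
            x = ad.leaky_relu(self._conv(f"down{l}.0", x), cfg.leak)
            x = ad.leaky_relu(self._conv(f"down{l}.1", x), cfg.leak)
            if l < cfg.levels - 1:
                skips.append(x)
                x = ad.avg_pool2(x)
        for l in range(cfg.levels - 2, -1, -1):
            x = ad.upsample2(x)
            x = ad.concat([x, skips[l]], axis=0)
            x = ad.leaky_relu(self._conv(f"up{l}.0", x), cfg.leak)
            x = ad.leaky_relu(self._conv(f"up{l}.1", x), cfg.leak)
        return self._conv("head", x)

    # -- parameter plumbing --------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state) -> None:
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=v.data.dtype, copy=True)

    def kernel_l2(self) -> ad.Tensor:
        """Squared l2 norm of all convolution kernel parameters."""
        total = None
        for name, p in self.params.items():
            if name.endswith(".w"):
                term = (p * p).sum()
                total = term if total is None else total + term
        return total


class MotionEstimator:
    """Velocity-field regression between bin images, integrated in-graph.

    ``fields`` builds the differentiable graph from two full-resolution
    magnitude images: joint max-normalization, 2x average-pool downsampling,
    U-Net velocity, scaling-and-squaring integration of +v and -v, and
    trilinear 2x upsampling with the displacement doubled.
    """

    def __init__(self, levels: int = 2, base_channels: int = 8, n_squaring: int = 6,
                 seed: int = 0, dtype: str = "float32"):
        self.cfg = UNetConfig(
            in_channels=2, out_channels=3, levels=levels, base_channels=base_channels,
            zero_init_head=True, seed=seed, dtype=dtype,
        )
        self.unet = UNet3D(self.cfg)
        self.n_squaring = n_squaring

    @property
    def params(self):
        return self.unet.params

    def fields(self, ref_mag: np.ndarray, mov_mag: np.ndarray):
        """-> (forward, inverse, velocity) Tensors; fields full-res (3,X,Y,Z)."""
        dt = np.dtype(self.cfg.dtype)
        scale = max(float(np.max(ref_mag)), float(np.max(mov_mag)), 1e-12)
        pair = np.stack([ref_mag, mov_mag]).astype(dt) / dt.type(scale)
        x = ad.avg_pool2(ad.constant(pair))
        v = self.unet(x)
        fwd = _integrate(v, self.n_squaring)
        inv = _integrate(v * (-1.0), self.n_squaring)
        up = lambda d: ad.upsample2(d) * 2.0
        return up(fwd), up(inv), v

    def estimate(self, ref_mag: np.ndarray, mov_mag: np.ndarray) -> MotionField:
        with ad.no_grad():
            fwd, inv, v = self.fields(ref_mag, mov_mag)
        return MotionField(
            velocity=v.data.astype(np.float64),
            forward=fwd.data.astype(np.float64),
            inverse=inv.data.astype(np.float64),
            n_squaring_steps=self.n_squaring,
        )


def _integrate(v: ad.Tensor, n_steps: int) -> ad.Tensor:
    phi = v * (1.0 / 2.0 ** n_steps)
    for _ in range(n_steps):
        phi = phi + ad.warp(phi, phi)
    return phi


class Denoiser:
    """Residual denoising U-Net on the real/imaginary channel pair."""

    def __init__(self, levels: int = 2, base_channels: int = 8, seed: int = 1,
                 dtype: str = "float32"):
        self.cfg = UNetConfig(
            in_channels=2, out_channels=2, levels=levels, base_channels=base_channels,
            zero_init_head=True, seed=seed, dtype=dtype,
        )
        self.unet = UNet3D(self.cfg)

    @property
    def params(self):
        return self.unet.params

    def __call__(self, pair: ad.Tensor) -> ad.Tensor:
        if not np.isfinite(pair.data).all():
            raise ValueError("non-finite denoiser input")
        return pair + self.unet(pair)


def estimate_motion(ref_bin: np.ndarray, moving_bin: np.ndarray,
                    net: MotionEstimator) -> MotionField:
    """Full-resolution diffeomorphic field between two magnitude bin images."""
    if ref_bin.shape != moving_bin.shape:
        raise ValueError("bin images must share a grid")
    return net.estimate(np.abs(ref_bin), np.abs(moving_bin))


def denoise(volume: np.ndarray, net: Denoiser) -> np.ndarray:
    """Apply the denoiser to a complex volume (outside the training graph)."""
    pair = ad.complex_to_pair(np.asarray(volume, dtype=np.complex128)).astype(
        np.dtype(net.cfg.dtype)
    )
    with ad.no_grad():
        out = net(ad.constant(pair))
    return ad.pair_to_complex(out.data.astype(np.float64))


def save_checkpoint(path, motion_net: MotionEstimator, denoiser: Denoiser,
                    extra: dict | None = None) -> None:
    arrays = {f"motion/{k}": v for k, v in motion_net.unet.state_dict().items()}
    arrays.update({f"denoiser/{k}": v for k, v in denoiser.unet.state_dict().items()})
    meta = {
        "motion_cfg": asdict(motion_net.cfg),
        "n_squaring": motion_net.n_squaring,
        "denoiser_cfg": asdict(denoiser.cfg),
        "extra": extra or {},
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[MotionEstimator, Denoiser, dict]:
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        mcfg, dcfg = meta["motion_cfg"], meta["denoiser_cfg"]
        mnet = MotionEstimator(
            levels=mcfg["levels"], base_channels=mcfg["base_channels"],
            n_squaring=meta["n_squaring"], seed=mcfg["seed"], dtype=mcfg["dtype"],
        )
        dnet = Denoiser(
            levels=dcfg["levels"], base_channels=dcfg["base_channels"],
            seed=dcfg["seed"], dtype=dcfg["dtype"],
        )
        mnet.unet.load_state_dict({k[len("motion/"):]: f[k] for k in f.files if k.startswith("motion/")})
        dnet.unet.load_state_dict({k[len("denoiser/"):]: f[k] for k in f.files if k.startswith("denoiser/")})
    return mnet, dnet, meta.get("extra", {})
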