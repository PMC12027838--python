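"""Dual-stream generator: shared encoder, global/local latent streams with
independent perturbations, a contrastive projection head, and a dual-path
decoder with skip connections.

The generator is image-conditioned: the latent code of a real image is
extracted by the encoder, perturbed per stream, and decoded back to an image.
The global stream is rendered at coarse resolution and smoothly upsampled, so
it carries the low-spatial-frequency structure; the local stream refines
full-resolution detail through encoder skip connections.  The output image is
``sigmoid(global_component + local_component)`` — the two stream contributions
add pre-activation, and the bounded activation keeps intensities in [0, 1]
while staying differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .serialize import load_arrays, save_module

__all__ = ["GeneratorConfig", "LatentCode", "Embedding", "GeneratorOutput", "DualStreamGenerator"]


@dataclass
class GeneratorConfig:
    image_size: int = 64
    base_channels: int = 8
    latent_dim: int = 100       # total d = d_global + d_local
    global_dim: int = 50
    proj_dim: int = 32

    def __post_init__(self):
        if self.global_dim < 1 or self.latent_dim - self.global_dim < 1:
            raise ValueError("both latent streams need dimension >= 1")
        n = self.image_size
        if n < 32 or (n & (n - 1)) != 0:
            raise ValueError("image_size must be a power of two >= 32")

    @property
    def local_dim(self) -> int:
        return self.latent_dim - self.global_dim


@dataclass
class LatentCode:
    """Encoder latent split into the two generator streams."""

    global_part: Tensor
    local_part: Tensor

    @property
    def total_dim(self) -> int:
        return self.global_part.shape[-1] + self.local_part.shape[-1]

    def full(self) -> Tensor:
        return nn.concat([self.global_part, self.local_part], axis=1)


@dataclass
class Embedding:
    """Projection-head output used by the contrastive latent loss."""

    values: Tensor


@dataclass
class GeneratorOutput:
    image: Tensor               # (N,1,H,W) in [0,1]
    global_component: Tensor    # pre-activation global-stream contribution
    local_component: Tensor     # pre-activation local-stream contribution
    latent: LatentCode

    @property
    def images(self) -> np.ndarray:
        """Generated images as an (N, H, W) array."""
        return self.image.data[:, 0]


def _as_batch(x) -> np.ndarray:
    """Coerce pixels (H,W), (N,H,W) or (N,1,H,W) to (N,1,H,W) float64."""
    a = np.asarray(getattr(x, "pixels", x), dtype=np.float64)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    elif a.ndim != 4:
        raise ValueError(f"cannot interpret pixel array of shape {a.shape}")
    return a


def _blur_kernel() -> np.ndarray:
    k = np.array([1.0, 4.0, 6.0, 4.0, 1.0])
    k2 = np.outer(k, k)
    return (k2 / k2.sum()).reshape(1, 1, 5, 5)


class DualStreamGenerator(nn.Module):
    """Encoder + CLP projection head + dual-path decoder."""

    def __init__(self, config: GeneratorConfig | None = None, seed: int = 0):
        self.config = config or GeneratorConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x6E0]))
        c = self.config.base_channels
        d = self.config.latent_dim
        n = self.config.image_size
        self._coarse = n // 8

        # encoder: full-res feature map then three stride-2 stages
        self.enc0 = nn.Conv2d(1, c, 3, rng)
        self.enc1 = nn.Conv2d(c, 2 * c, 3, rng, stride=2)
        self.enc2 = nn.Conv2d(2 * c, 4 * c, 3, rng, stride=2)
        self.enc3 = nn.Conv2d(4 * c, 4 * c, 3, rng, stride=2)
        self.enc_fc = nn.Linear(4 * c * self._coarse ** 2, d, rng)

        # projection head (two affine layers with a nonlinearity)
        self.proj1 = nn.Linear(d, 64, rng)
        self.proj2 = nn.Linear(64, self.config.proj_dim, rng)

        # global reconstruction path: coarse render + smooth upsampling
        self.glob_fc = nn.Linear(self.config.global_dim, 4 * c * self._coarse ** 2, rng)
        self.glob_conv = nn.Conv2d(4 * c, 2 * c, 3, rng)
        self.glob_out = nn.Conv2d(2 * c, 1, 3, rng)
        # start at the logit of typical tissue brightness so early training
        # refines structure instead of a global brightness shift
        self.glob_out.bias.data[:] = -1.4
        self._blur = Tensor(_blur_kernel())  # fixed, non-trainable

        # local refinement path with encoder skips
        self.loc_fc = nn.Linear(self.config.local_dim, 4 * c * self._coarse ** 2, rng)
        self.dec2 = nn.Conv2d(4 * c + 4 * c, 2 * c, 3, rng)   # 16x16, skip from enc2
        self.dec1 = nn.Conv2d(2 * c + 2 * c, c, 3, rng)       # 32x32, skip from enc1
        self.dec0 = nn.Conv2d(c + c, c, 3, rng)               # 64x64, skip from enc0
        self.loc_out = nn.Conv2d(c, 1, 3, rng)

    # -- operations -----------------------------------------------------------
    def encode_with_skips(self, x) -> tuple[LatentCode, list[Tensor]]:
        a = _as_batch(x)
        if a.shape[-1] != self.config.image_size or a.shape[-2] != self.config.image_size:
            raise ValueError(
                f"expected {self.config.image_size}^2 input, got {a.shape[-2:]}"
            )
        t = Tensor(a)
        s0 = self.enc0(t).leaky_relu()
        s1 = self.enc1(s0).leaky_relu()
        s2 = self.enc2(s1).leaky_relu()
        s3 = self.enc3(s2).leaky_relu()
        z = self.enc_fc(s3.reshape(s3.shape[0], -1))
        dg = self.config.global_dim
        return LatentCode(global_part=z[:, :dg], local_part=z[:, dg:]), [s0, s1, s2]

    def encode(self, x) -> LatentCode:
        z, _ = self.encode_with_skips(x)
        return z

    def perturb(self, z: LatentCode, sigma_global: float, sigma_local: float,
                seed: int) -> LatentCode:
        if sigma_global < 0 or sigma_local < 0:
            raise ValueError("perturbation scales must be >= 0")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x9E2]))
        g = z.global_part
        l = z.local_part
        if sigma_global > 0:
            g = g + Tensor(rng.normal(0.0, sigma_global, size=g.shape))
        else:
            rng.normal(size=g.shape)  # keep the stream layout seed-stable
        if sigma_local > 0:
            l = l + Tensor(rng.normal(0.0, sigma_local, size=l.shape))
        return LatentCode(global_part=g, local_part=l)

    def project(self, z: LatentCode) -> Embedding:
        h = self.proj1(z.full()).leaky_relu()
        return Embedding(values=self.proj2(h))

    def _smooth_upsample(self, x: Tensor, stages: int) -> Tensor:
        bias = Tensor(np.zeros(1))
        for _ in range(stages):
            x = F.upsample_nearest(x, 2)
            x = F.conv2d(x, self._blur, bias, stride=1, pad=2)
        return x

    def decode(self, z_global: Tensor, z_local: Tensor,
               skips: list[Tensor]) -> tuple[Tensor, Tensor]:
        c = self.config.base_channels
        m = self._coarse
        n_batch = z_global.shape[0]

        g = self.glob_fc(z_global).leaky_relu().reshape(n_batch, 4 * c, m, m)
        g = self.glob_conv(g).leaky_relu()
        g = self.glob_out(g)
        global_pre = self._smooth_upsample(g, stages=3)

        h = self.loc_fc(z_local).leaky_relu().reshape(n_batch, 4 * c, m, m)
        h = F.upsample_nearest(h, 2)
        h = self.dec2(nn.concat([h, skips[2]], axis=1)).leaky_relu()
        h = F.upsample_nearest(h, 2)
        h = self.dec1(nn.concat([h, skips[1]], axis=1)).leaky_relu()
        h = F.upsample_nearest(h, 2)
        h = self.dec0(nn.concat([h, skips[0]], axis=1)).leaky_relu()
        local_pre = self.loc_out(h)
        return global_pre, local_pre

    def generate(self, x, sigma_global: float, sigma_local: float,
                 seed: int) -> GeneratorOutput:
        z, skips = self.encode_with_skips(x)
        zp = self.perturb(z, sigma_global, sigma_local, seed)
        global_pre, local_pre = self.decode(zp.global_part, zp.local_part, skips)
        image = (global_pre + local_pre).sigmoid()
        return GeneratorOutput(image=image, global_component=global_pre,
                               local_component=local_pre, latent=zp)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        save_module(path, self, self.config)

    @classmethod
    def load(cls, path) -> "DualStreamGenerator":
        config, params = load_arrays(path)
        model = cls(GeneratorConfig(**config))
        model.load_state_dict(params)
        return model
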