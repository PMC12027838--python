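"""The three adversarial critics.

* ``ClassifierD1`` — global critic and tumor classifier: softmax over the four
  classes, applied to real and generated images alike.  Its penultimate
  feature vector doubles as the feature extractor for the FID-like metric, and
  a fresh clone of its architecture is the downstream classifier in the
  augmentation-utility evaluation.
* ``PatchCriticD2`` — PatchGAN-style local critic: a 16x16 grid of realness
  probabilities, each depending on an ~18-pixel receptive field.
* ``FourierCriticD3`` — scalar realness score computed on the DC-centered
  log-magnitude spectrum, enforcing frequency-statistics consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor
from .serialize import load_arrays, save_module

__all__ = [
    "CriticConfig", "SpectrumMap", "spectral_transform", "raw_spectrum",
    "ClassifierD1", "PatchCriticD2", "FourierCriticD3",
]


@dataclass
class CriticConfig:
    image_size: int = 64
    base_channels: int = 8
    n_classes: int = 4


@dataclass
class SpectrumMap:
    """DC-centered log-magnitude spectrum, log(1 + |F(x)|)."""

    magnitude: Tensor  # (N,1,H,W)


def _as_batch(x) -> np.ndarray:
    a = np.asarray(getattr(x, "pixels", x), dtype=np.float64)
    if a.ndim == 2:
        a = a[None, None]
    elif a.ndim == 3:
        a = a[:, None]
    elif a.ndim != 4:
        raise ValueError(f"cannot interpret pixel array of shape {a.shape}")
    return a


def _as_tensor_batch(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(_as_batch(x))


def raw_spectrum(x) -> np.ndarray:
    """Unnormalized complex 2-D DFT of the trailing two axes (not shifted)."""
    return np.fft.fft2(_as_batch(x), axes=(-2, -1))


def spectral_transform(x) -> SpectrumMap:
    """Differentiable DC-centered log-magnitude spectrum of an image batch."""
    return SpectrumMap(magnitude=F.spectral_logmag(_as_tensor_batch(x)))


class _CriticBase(nn.Module):
    config_cls = CriticConfig

    def save(self, path) -> None:
        save_module(path, self, self.config)

    @classmethod
    def load(cls, path):
        config, params = load_arrays(path)
        model = cls(CriticConfig(**config))
        model.load_state_dict(params)
        return model

    def _check_size(self, t: Tensor) -> None:
        n = self.config.image_size
        if t.shape[-2:] != (n, n):
            raise ValueError(f"expected {n}x{n} input, got {t.shape[-2:]}")


class ClassifierD1(_CriticBase):
    """Global discriminator / 4-class tumor classifier (softmax output)."""

    FEATURE_DIM = 64

    def __init__(self, config: CriticConfig | None = None, seed: int = 0):
        self.config = config or CriticConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD1]))
        c = self.config.base_channels
        n = self.config.image_size
        self.conv1 = nn.Conv2d(1, c, 3, rng, stride=2)
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng, stride=2)
        self.conv3 = nn.Conv2d(2 * c, 4 * c, 3, rng, stride=2)
        # flattened (not pooled) head: lesion position is class-discriminative
        self.fc_feat = nn.Linear(4 * c * (n // 8) ** 2, self.FEATURE_DIM, rng)
        self.fc = nn.Linear(self.FEATURE_DIM, self.config.n_classes, rng)

    def features(self, x) -> Tensor:
        """Penultimate feature vector, (N, 64); also the FID-like embedding."""
        t = _as_tensor_batch(x)
        self._check_size(t)
        h = self.conv1(t).leaky_relu()
        h = self.conv2(h).leaky_relu()
        h = self.conv3(h).leaky_relu()
        return self.fc_feat(h.reshape(h.shape[0], -1)).leaky_relu()

    def logits(self, x) -> Tensor:
        return self.fc(self.features(x))

    def log_probs(self, x) -> Tensor:
        return F.log_softmax(self.logits(x), axis=1)

    def classify(self, x) -> Tensor:
        """Class probabilities (N, c); rows sum to 1."""
        return self.log_probs(x).exp()


class PatchCriticD2(_CriticBase):
    """Local patch critic: sigmoid realness score per receptive-field patch.

    For 64x64 inputs the score grid is 16x16 and each score's receptive field
    spans 18x18 input pixels.
    """

    def __init__(self, config: CriticConfig | None = None, seed: int = 0):
        self.config = config or CriticConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD2]))
        c = 2 * self.config.base_channels
        self.conv1 = nn.Conv2d(1, c, 4, rng, stride=2, pad=1)
        self.conv2 = nn.Conv2d(c, 2 * c, 4, rng, stride=2, pad=1)
        self.conv3 = nn.Conv2d(2 * c, 1, 3, rng, stride=1, pad=1)

    def score_map(self, x) -> Tensor:
        """Patch realness probabilities in (0,1), shape (N, 1, H/4, W/4)."""
        t = _as_tensor_batch(x)
        self._check_size(t)
        h = self.conv1(t).leaky_relu()
        h = self.conv2(h).leaky_relu()
        return self.conv3(h).sigmoid()


class FourierCriticD3(_CriticBase):
    """Frequency-domain critic: scalar realness score from a SpectrumMap."""

    def __init__(self, config: CriticConfig | None = None, seed: int = 0):
        self.config = config or CriticConfig()
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xD3]))
        c = self.config.base_channels
        self.conv1 = nn.Conv2d(1, c, 3, rng, stride=2)
        self.conv2 = nn.Conv2d(c, 2 * c, 3, rng, stride=2)
        self.fc = nn.Linear(2 * c, 1, rng)

    def score(self, spectrum: SpectrumMap) -> Tensor:
        """Realness probability in (0,1) per image, shape (N, 1)."""
        t = spectrum.magnitude
        self._check_size(t)
        h = self.conv1(t).leaky_relu()
        h = self.conv2(h).leaky_relu()
        return self.fc(h.mean(axis=(2, 3))).sigmoid()
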