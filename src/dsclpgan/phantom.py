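"""Synthetic T1-weighted contrast-enhanced brain-slice phantoms.

Each phantom is an elliptical "brain" with smooth random texture and a
low-frequency intensity bias field, plus — for the three tumor classes — one
bright Gaussian-profile lesion whose size and placement follow a loose
radiological analogy:

* class 1 (meningioma-analog): medium lesion near the brain rim,
* class 2 (glioma-analog): large diffuse lesion with an irregular boundary,
* class 3 (pituitary-analog): small lesion near the brain center,
* class 0: no lesion.

Lesions are brighter than surrounding tissue, emulating contrast enhancement.
Everything is deterministic given (spec, label, seed); datasets derive one
independent substream per sample from a single integer seed, so sample i's
pixels do not depend on how many samples were drawn before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["ImageSample", "PhantomSpec", "make_phantom", "make_dataset", "lesion_threshold"]

CLASS_NAMES = {0: "no tumor", 1: "meningioma", 2: "glioma", 3: "pituitary"}

_BRAIN_BASE = 0.35          # mean tissue intensity
_TEXTURE_AMP = 0.08         # smooth texture amplitude
_BACKGROUND = 0.02          # air intensity
_LESION_AMP = 0.55          # lesion peak above tissue


@dataclass
class ImageSample:
    """One grayscale image with class label; pixel values in [0, 1]."""

    pixels: np.ndarray
    label: int
    id: str

    def validate(self) -> "ImageSample":
        p = self.pixels
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"pixels must be square 2-D, got shape {p.shape}")
        n = p.shape[0]
        if n < 32 or (n & (n - 1)) != 0:
            raise ValueError(f"image size must be a power of two >= 32, got {n}")
        if not np.isfinite(p).all():
            raise ValueError("pixels contain non-finite values")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.label not in (0, 1, 2, 3):
            raise ValueError(f"label must be in {{0,1,2,3}}, got {self.label}")
        return self


@dataclass
class PhantomSpec:
    """Geometry, contrast and sampling parameters for phantom generation."""

    image_size: int = 64
    brain_axes: tuple[float, float] = (0.42, 0.36)   # semi-axes, fraction of image
    lesion_radius_range: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (4.0, 6.0), 2: (6.0, 11.0), 3: (2.0, 3.2)}
    )
    # per-class radial placement as fraction of the brain ellipse (lo, hi)
    lesion_center_prior: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.78, 0.90), 2: (0.0, 0.50), 3: (0.0, 0.15)}
    )
    noise_sigma: float = 0.02
    intensity_bias_amp: float = 0.06
    class_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self) -> "PhantomSpec":
        n = self.image_size
        if n < 32 or (n & (n - 1)) != 0:
            raise ValueError(f"image_size must be a power of two >= 32, got {n}")
        probs = np.asarray(self.class_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 nonnegative entries summing to 1")
        b_px = min(self.brain_axes) * n
        for cls, (lo, hi) in self.lesion_radius_range.items():
            if not (0 < lo <= hi):
                raise ValueError(f"lesion radius range for class {cls} must be positive")
            if hi >= b_px:
                raise ValueError(f"lesion radius for class {cls} exceeds brain axis")
        if self.noise_sigma < 0 or self.intensity_bias_amp < 0:
            raise ValueError("noise_sigma and intensity_bias_amp must be >= 0")
        return self


def lesion_threshold(spec: PhantomSpec) -> float:
    """Upper bound on lesion-free tissue intensity.

    Tissue base + texture amplitude + bias-field amplitude + a 4-sigma noise
    allowance.  Pixels above this value belong to a lesion; class-0 images
    stay entirely below it.
    """
    return _BRAIN_BASE + _TEXTURE_AMP + spec.intensity_bias_amp + 4.0 * spec.noise_sigma


def _smooth_field(rng: np.random.Generator, n: int, blur: float) -> np.ndarray:
    """Zero-mean unit-amplitude smooth random field."""
    f = gaussian_filter(rng.normal(size=(n, n)), sigma=blur, mode="wrap")
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def make_phantom(spec: PhantomSpec, label: int, seed: int) -> ImageSample:
    """Render one phantom. Deterministic for a given (spec, label, seed)."""
    spec.validate()
    if label not in (0, 1, 2, 3):
        raise ValueError(f"label must be in {{0,1,2,3}}, got {label}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, label]))
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0
    a_px = spec.brain_axes[0] * n
    b_px = spec.brain_axes[1] * n
    brain = ((xx - cx) / a_px) ** 2 + ((yy - cy) / b_px) ** 2 <= 1.0

    img = np.full((n, n), _BACKGROUND)
    texture = _smooth_field(rng, n, blur=n / 12) * _TEXTURE_AMP
    # separable low-frequency bias field (scanner shading analog)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    bias = spec.intensity_bias_amp * (
        np.cos(2 * np.pi * xx / n + phase[0]) * np.cos(2 * np.pi * yy / n + phase[1])
    )
    img[brain] = _BRAIN_BASE + texture[brain] + bias[brain]

    if label != 0:
        r_lo, r_hi = spec.lesion_radius_range[label]
        radius = rng.uniform(r_lo, r_hi)
        u_lo, u_hi = spec.lesion_center_prior[label]
        u = rng.uniform(u_lo, u_hi)
        theta = rng.uniform(0, 2 * np.pi)
        ly = cy + u * b_px * np.sin(theta)
        lx = cx + u * a_px * np.cos(theta)
        r2 = (xx - lx) ** 2 + (yy - ly) ** 2
        profile = _LESION_AMP * np.exp(-r2 / (2.0 * (radius / 2.0) ** 2))
        if label == 2:  # irregular boundary for the glioma-analog
            modulation = 1.0 + 0.5 * _smooth_field(rng, n, blur=radius / 2.0)
            profile = profile * np.clip(modulation, 0.0, None)
        img = img + profile * brain

    img = img + rng.normal(0.0, spec.noise_sigma, size=(n, n))
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(pixels=img, label=label, id=f"phantom-s{seed}-c{label}").validate()


def make_dataset(spec: PhantomSpec, n: int, seed: int) -> list[ImageSample]:
    """Draw n phantoms with labels i.i.d. from ``spec.class_probs``.

    Sample i uses the substream derived from (seed, i), so its content is
    independent of dataset length and position.
    """
    spec.validate()
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    label_rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xBEEF]))
    labels = label_rng.choice(4, size=n, p=np.asarray(spec.class_probs, dtype=float))
    samples = []
    for i, label in enumerate(labels):
        sub_seed = int(
            np.random.SeedSequence([seed & 0x7FFFFFFF, i]).generate_state(1)[0] & 0x7FFFFFFF
        )
        s = make_phantom(spec, int(label), sub_seed)
        s.id = f"phantom-{seed}-{i:05d}"
        samples.append(s)
    return samples
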