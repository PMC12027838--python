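"""Image-quality and augmentation-diversity metrics.

SSIM follows the windowed luminance/contrast/structure form with an 11x11
Gaussian window (sigma = 1.5), constants C1 = (0.01 L)^2 and C2 = (0.03 L)^2
at dynamic range L = 1, averaged over valid window positions.  PSNR is
10 log10(1/MSE) capped at 100 dB for identical images.  The Frechet distance
is computed on sample moments of pluggable feature embeddings; without
Inception weights it is an "FID-like" score, not comparable to published FID
numbers.  The diversity harness retrains a small classifier (clone of the D1
architecture) at each augmentation diversity level — level k appends k
generated variants per training image — and reports held-out accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.signal import convolve2d

from .discriminators import ClassifierD1, CriticConfig
from .losses import nll_from_log_probs
from .nn import Adam
from .phantom import ImageSample

__all__ = [
    "MetricReport", "LatentSeparation", "ssim", "psnr", "fid",
    "latent_distance", "diversity_eval", "d1_feature_extractor",
    "random_feature_extractor",
]

PSNR_CAP_DB = 100.0


@dataclass
class LatentSeparation:
    between: float   # mean distance between group centroids
    within: float    # mean distance of embeddings to their group centroid
    separation: float  # between - within, reported raw (may be negative)


@dataclass
class MetricReport:
    ssim: float | None = None
    psnr_db: float | None = None
    fid: float | None = None
    latent: LatentSeparation | None = None
    accuracy_by_diversity: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "ssim": self.ssim,
            "psnr_db": self.psnr_db,
            "fid": self.fid,
            "accuracy_by_diversity": {str(k): v for k, v in self.accuracy_by_diversity.items()},
        }
        if self.latent is not None:
            d["latent"] = {
                "between": self.latent.between,
                "within": self.latent.within,
                "separation": self.latent.separation,
            }
        return d


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    w = np.outer(g, g)
    return w / w.sum()


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(getattr(a, "pixels", a), dtype=np.float64)
    b = np.asarray(getattr(b, "pixels", b), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError("expected 2-D pixel grids")
    return a, b


def ssim(a, b, window_size: int = 11, sigma: float = 1.5) -> float:
    """Mean structural similarity over valid Gaussian-window positions."""
    a, b = _check_pair(a, b)
    if min(a.shape) < window_size:
        raise ValueError(f"image smaller than the {window_size}x{window_size} window")
    w = _gaussian_window(window_size, sigma)
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    mu_a = convolve2d(a, w, mode="valid")
    mu_b = convolve2d(b, w, mode="valid")
    var_a = convolve2d(a * a, w, mode="valid") - mu_a ** 2
    var_b = convolve2d(b * b, w, mode="valid") - mu_b ** 2
    cov = convolve2d(a * b, w, mode="valid") - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def psnr(a, b, cap_db: float = PSNR_CAP_DB) -> float:
    """Peak signal-to-noise ratio in dB for unit dynamic range."""
    a, b = _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return cap_db
    return min(cap_db, float(10.0 * np.log10(1.0 / mse)))


def fid(features_a, features_b, ridge: float | None = None) -> float:
    """Frechet distance between Gaussian fits of two feature sets.

    ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}) on sample moments.
    """
    fa = np.atleast_2d(np.asarray(features_a, dtype=np.float64))
    fb = np.atleast_2d(np.asarray(features_b, dtype=np.float64))
    if fa.shape[1] != fb.shape[1]:
        raise ValueError("feature dimensions differ")
    dim = fa.shape[1]
    if min(fa.shape[0], fb.shape[0]) <= dim and not ridge:
        raise ValueError(
            f"need > {dim} samples per set for a nonsingular covariance; "
            "pass ridge=<eps> to regularize"
        )
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    sig_a = np.atleast_2d(np.cov(fa, rowvar=False))
    sig_b = np.atleast_2d(np.cov(fb, rowvar=False))
    if ridge:
        sig_a = sig_a + ridge * np.eye(dim)
        sig_b = sig_b + ridge * np.eye(dim)
    covmean = scipy.linalg.sqrtm(sig_a @ sig_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    d2 = float(np.sum((mu_a - mu_b) ** 2) + np.trace(sig_a + sig_b - 2.0 * covmean))
    return max(d2, 0.0)


def d1_feature_extractor(d1: ClassifierD1) -> Callable[[np.ndarray], np.ndarray]:
    """Frozen penultimate-layer features of a (typically trained) D1."""

    def extract(images: np.ndarray) -> np.ndarray:
        return d1.features(images).data

    return extract


def random_feature_extractor(seed: int = 0,
                             config: CriticConfig | None = None) -> Callable:
    """Fixed-seed untrained CNN features — the fallback FID-like embedding."""
    return d1_feature_extractor(ClassifierD1(config, seed=seed))


def latent_distance(groups: Mapping[object, np.ndarray] | Sequence[np.ndarray]) -> LatentSeparation:
    """Between-group centroid distance minus within-group spread.

    ``groups`` maps a group key (e.g. source image or class) to an (m, p)
    array of embeddings.  The separation is reported raw, without clipping.
    """
    if isinstance(groups, Mapping):
        arrays = [np.atleast_2d(np.asarray(g, dtype=np.float64)) for g in groups.values()]
    else:
        arrays = [np.atleast_2d(np.asarray(g, dtype=np.float64)) for g in groups]
    if len(arrays) < 2:
        raise ValueError("latent_distance needs at least two groups")
    centroids = np.array([g.mean(axis=0) for g in arrays])
    k = len(centroids)
    between = float(np.mean(
        [np.linalg.norm(centroids[i] - centroids[j]) for i in range(k) for j in range(i + 1, k)]
    ))
    spreads = np.concatenate(
        [np.linalg.norm(g - c, axis=1) for g, c in zip(arrays, centroids)]
    )
    within = float(spreads.mean())
    return LatentSeparation(between=between, within=within, separation=between - within)


def _pixels(samples: Sequence[ImageSample]) -> np.ndarray:
    return np.stack([s.pixels for s in samples])


def train_classifier(images: np.ndarray, labels: np.ndarray, seed: int,
                     steps: int = 400, batch_size: int = 16, lr: float = 1e-3,
                     config: CriticConfig | None = None) -> ClassifierD1:
    """Train a fresh D1-architecture classifier; deterministic given seed.

    The budget is a fixed number of uniformly-sampled batches rather than
    epochs, so the comparison across diversity levels is matched in
    optimization effort: duplicating the training set (identity augmentation)
    leaves the sampled batch distribution — and hence the expected training
    trajectory — unchanged.
    """
    clf = ClassifierD1(config, seed=seed)
    opt = Adam(clf.parameters(), lr=lr, beta1=0.9, beta2=0.999)
    n = images.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xC1F]))
    for _ in range(steps):
        idx = rng.choice(n, size=min(batch_size, n), replace=False)
        opt.zero_grad()
        loss = nll_from_log_probs(clf.log_probs(images[idx]), labels[idx])
        loss.backward()
        opt.step()
    return clf


def classifier_accuracy(clf: ClassifierD1, images: np.ndarray, labels: np.ndarray,
                        batch_size: int = 64) -> float:
    correct = 0
    for start in range(0, images.shape[0], batch_size):
        chunk = images[start : start + batch_size]
        pred = np.argmax(clf.logits(chunk).data, axis=1)
        correct += int((pred == labels[start : start + chunk.shape[0]]).sum())
    return correct / images.shape[0]


def diversity_eval(train: Sequence[ImageSample], test: Sequence[ImageSample],
                   generator: Callable[[np.ndarray, int], np.ndarray],
                   levels: Sequence[int], seed: int,
                   classifier_steps: int = 400) -> dict[int, float]:
    """Held-out accuracy of a fresh classifier at each diversity level.

    ``generator(images, variant_seed)`` must return one variant per input
    image; level k appends k variant sets per original.  Level 0 is the
    no-augmentation baseline.  Labels are inherited from the source images.
    """
    if not train or not test:
        raise ValueError("train and test sets must be nonempty")
    if any(lv < 0 for lv in levels):
        raise ValueError("diversity levels must be >= 0")
    x_train, y_train = _pixels(train), np.array([s.label for s in train])
    x_test, y_test = _pixels(test), np.array([s.label for s in test])
    out: dict[int, float] = {}
    for level in levels:
        xs, ys = [x_train], [y_train]
        for k in range(level):
            variant_seed = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, 0xA06, level, k])
                .generate_state(1)[0] & 0x7FFFFFFF
            )
            xs.append(np.clip(generator(x_train, variant_seed), 0.0, 1.0))
            ys.append(y_train)
        clf = train_classifier(np.concatenate(xs), np.concatenate(ys),
                               seed=seed, steps=classifier_steps)
        out[int(level)] = classifier_accuracy(clf, x_test, y_test)
    return out
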