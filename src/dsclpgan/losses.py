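"""Scalar training objectives.

The contrastive latent projection (CLP) loss is InfoNCE over temperature-scaled
cosine similarities:

    L = -log[ exp(cos(a, p)/tau) / ( exp(cos(a, p)/tau) + sum_j exp(cos(a, n_j)/tau) ) ]

with the positive term included in the denominator.  The classification loss
is cross-entropy over the four tumor classes; the patch and frequency
adversarial losses use the standard discriminator form (minus-log on both the
real and the one-minus-fake terms) and the non-saturating generator form.
Logarithms of probabilities apply a floor of 1e-12 for numeric safety; the
CLP loss is evaluated exactly in log space (shifted log-sum-exp), so extreme
temperatures do not truncate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generator import Embedding
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "LossWeights", "LossReport",
    "clp_loss", "clp_loss_inbatch", "classification_loss", "nll_from_log_probs",
    "patch_adv_loss", "freq_adv_loss", "total_loss",
]

_EPS = 1e-12


@dataclass
class LossWeights:
    lambda_cls: float = 1.0
    lambda_adv: float = 1.0
    lambda_freq: float = 1.0
    lambda_clp: float = 1.0

    def __post_init__(self):
        vals = (self.lambda_cls, self.lambda_adv, self.lambda_freq, self.lambda_clp)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class LossReport:
    """Scalar loss terms for one batch, one adversarial side."""

    side: str
    clp: float
    cls: float
    adv_patch: float
    adv_freq: float
    total: float
    tau: float

    def as_dict(self) -> dict:
        return {
            "side": self.side, "clp": self.clp, "cls": self.cls,
            "adv_patch": self.adv_patch, "adv_freq": self.adv_freq,
            "total": self.total, "tau": self.tau,
        }


def _values(e) -> Tensor:
    t = e.values if isinstance(e, Embedding) else as_tensor(e)
    norm = float(np.linalg.norm(t.data))
    if norm == 0.0:
        raise ValueError("zero-norm embedding has undefined cosine similarity")
    return t


def _safe_log(t: Tensor) -> Tensor:
    return t.clip(_EPS, np.inf).log()


def _cosine(a: Tensor, b: Tensor) -> Tensor:
    dot = (a * b).sum()
    return dot / ((a * a).sum().sqrt() * (b * b).sum().sqrt())


def clp_loss(anchor, positive, negatives, tau: float) -> Tensor:
    """Contrastive latent projection loss for one anchor/positive pair.

    Invariant to positive rescaling of any embedding (cosine similarity).
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    negatives = list(negatives)
    if not negatives:
        raise ValueError("clp_loss needs at least one negative")
    a = _values(anchor)
    sims = [_cosine(a, _values(positive))] + [_cosine(a, _values(n)) for n in negatives]
    scaled = [s * (1.0 / tau) for s in sims]
    # exact log-sum-exp so extreme temperatures stay finite and unfloored
    m = max(float(s.data) for s in scaled)
    acc = (scaled[0] - m).exp()
    for s in scaled[1:]:
        acc = acc + (s - m).exp()
    return acc.log() + m - scaled[0]


def clp_loss_inbatch(view1: Tensor, view2: Tensor, tau: float) -> Tensor:
    """Mean CLP loss over a batch with in-batch negatives.

    Row i of ``view1`` and ``view2`` embed two perturbations of the same
    image; for each anchor ``view1[i]`` the positive is ``view2[i]`` and the
    negatives are ``view2[j]`` for every other image j in the batch.
    """
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    v1, v2 = as_tensor(view1), as_tensor(view2)
    n = v1.shape[0]
    if n < 2:
        raise ValueError("in-batch CLP needs batch size >= 2")
    n1 = v1 / (v1 * v1).sum(axis=1, keepdims=True).sqrt()
    n2 = v2 / (v2 * v2).sum(axis=1, keepdims=True).sqrt()
    sims = (n1 @ n2.transpose(1, 0)) * (1.0 / tau)   # (n, n)
    idx = np.arange(n)
    pos = sims[idx, idx]
    m = sims.data.max(axis=1, keepdims=True)  # logsumexp shift, constant
    lse = (sims - m).exp().sum(axis=1).log() + m[:, 0]
    return (lse - pos).mean()


def classification_loss(probs, labels) -> Tensor:
    """Cross-entropy -sum_i y_i log p_i with one-hot ground truth.

    Accepts one probability vector with an int label, or a batch (N, c) with
    an int array; the batch version averages over samples.
    """
    p = as_tensor(probs)
    if p.ndim == 1:
        p = p.reshape(1, -1)
        labels = np.array([labels])
    labels = np.asarray(labels, dtype=int)
    c = p.shape[1]
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"labels must lie in [0, {c - 1}]")
    picked = p[np.arange(p.shape[0]), labels]
    return -_safe_log(picked).mean()


def nll_from_log_probs(log_probs: Tensor, labels) -> Tensor:
    """Numerically stable cross-entropy from log-probabilities (training path)."""
    labels = np.asarray(labels, dtype=int)
    return -(log_probs[np.arange(log_probs.shape[0]), labels]).mean()


def _adv_loss(real_scores, fake_scores, side: str) -> Tensor:
    if side not in ("discriminator", "generator"):
        raise ValueError(f"side must be 'discriminator' or 'generator', got {side!r}")
    fake = as_tensor(fake_scores)
    if fake.data.size == 0:
        raise ValueError("empty score batch")
    if side == "generator":
        return -_safe_log(fake).mean()
    real = as_tensor(real_scores)
    if real.data.size == 0:
        raise ValueError("empty score batch")
    return -_safe_log(real).mean() - _safe_log(1.0 - fake).mean()


def patch_adv_loss(real_maps, fake_maps, side: str) -> Tensor:
    """Adversarial loss on the local critic's patch score maps."""
    return _adv_loss(real_maps, fake_maps, side)


def freq_adv_loss(real_scores, fake_scores, side: str) -> Tensor:
    """Adversarial loss on the Fourier critic's scalar scores."""
    return _adv_loss(real_scores, fake_scores, side)


def total_loss(clp, cls, adv_patch, adv_freq, weights: LossWeights, side: str,
               tau: float = 0.5) -> tuple[Tensor, LossReport]:
    """Lambda-weighted aggregate objective for one side of the game.

    Returns the differentiable total and a scalar report.  Fails fast with
    the offending term's name if any component is non-finite.
    """
    if side not in ("discriminator", "generator"):
        raise ValueError(f"side must be 'discriminator' or 'generator', got {side!r}")
    parts = {"clp": clp, "cls": cls, "adv_patch": adv_patch, "adv_freq": adv_freq}
    for name, value in parts.items():
        v = value.data if isinstance(value, Tensor) else value
        if not np.isfinite(v).all():
            raise FloatingPointError(f"loss term {name!r} is non-finite on side {side!r}")
    clp_t, cls_t = as_tensor(clp), as_tensor(cls)
    patch_t, freq_t = as_tensor(adv_patch), as_tensor(adv_freq)
    total = (weights.lambda_cls * cls_t + weights.lambda_adv * patch_t
             + weights.lambda_freq * freq_t + weights.lambda_clp * clp_t)
    report = LossReport(
        side=side, clp=float(clp_t.data), cls=float(cls_t.data),
        adv_patch=float(patch_t.data), adv_freq=float(freq_t.data),
        total=float(total.data), tau=tau,
    )
    return total, report
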