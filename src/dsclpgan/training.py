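"""Adversarial training loop.

Each step performs one joint discriminator update (D1 classification on real
images, D2 patch and D3 frequency adversarial terms, lambda-weighted) followed
by one generator update (non-saturating patch and frequency adversarial terms,
classification of generated images, the contrastive latent projection loss
over two perturbed views, and an L1 reconstruction anchor to the source
image).  Optimization uses Adam with beta1 = 0.5, beta2 = 0.999 and learning
rate 1e-4.  Two named presets are shipped: ``paper`` (batch 64, 50 epochs, the
full-scale reference protocol) and ``desk`` (batch 16, 5 epochs) for CPU-scale
runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .discriminators import (ClassifierD1, CriticConfig, FourierCriticD3,
                             PatchCriticD2, spectral_transform)
from .generator import DualStreamGenerator, GeneratorConfig
from .losses import (LossReport, LossWeights, clp_loss_inbatch, freq_adv_loss,
                     nll_from_log_probs, patch_adv_loss, total_loss)
from .metrics import psnr, ssim
from .nn import Adam
from .nn.tensor import Tensor
from .phantom import ImageSample

__all__ = ["TrainConfig", "TrainState", "train_step", "fit", "augment_dataset",
           "generator_fn", "PRESETS"]


@dataclass
class TrainConfig:
    image_size: int = 64
    base_channels: int = 8
    latent_dim: int = 100
    global_dim: int = 50
    proj_dim: int = 32
    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    tau: float = 0.5
    lambda_cls: float = 1.0
    lambda_adv: float = 1.0
    lambda_freq: float = 1.0
    lambda_clp: float = 1.0
    recon_weight: float = 1.0
    sigma_global: float = 0.1
    sigma_local: float = 0.1
    weight_decay: float = 0.0
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not (0 <= self.adam_beta1 < 1 and 0 <= self.adam_beta2 < 1):
            raise ValueError("Adam betas must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (CLP needs an in-batch negative)")

    @property
    def loss_weights(self) -> LossWeights:
        return LossWeights(self.lambda_cls, self.lambda_adv,
                           self.lambda_freq, self.lambda_clp)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(image_size=self.image_size,
                               base_channels=self.base_channels,
                               latent_dim=self.latent_dim,
                               global_dim=self.global_dim,
                               proj_dim=self.proj_dim)

    def critic_config(self) -> CriticConfig:
        return CriticConfig(image_size=self.image_size,
                            base_channels=self.base_channels)


PRESETS: dict[str, dict] = {
    # full-scale reference protocol: latent 100, batch 64, 50 epochs, lr 1e-4
    "paper": {},
    # CPU desk scale
    "desk": {"batch_size": 16, "epochs": 5},
}


def make_config(preset: str = "desk", **overrides) -> TrainConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return TrainConfig(**{**PRESETS[preset], **overrides})


def config_from_yaml(text: str) -> TrainConfig:
    """Parse a flat YAML mapping into a TrainConfig, rejecting unknown keys."""
    import yaml

    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config YAML must be a flat mapping")
    preset = raw.pop("preset", "desk")
    known = {f.name for f in dataclasses.fields(TrainConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return make_config(preset, **raw)


@dataclass
class TrainState:
    generator: DualStreamGenerator
    d1: ClassifierD1
    d2: PatchCriticD2
    d3: FourierCriticD3
    opt_g: Adam
    opt_d: Adam
    step: int = 0

    @classmethod
    def initialize(cls, config: TrainConfig) -> "TrainState":
        gen = DualStreamGenerator(config.generator_config(), seed=config.seed)
        d1 = ClassifierD1(config.critic_config(), seed=config.seed)
        d2 = PatchCriticD2(config.critic_config(), seed=config.seed)
        d3 = FourierCriticD3(config.critic_config(), seed=config.seed)
        opt_g = Adam(gen.parameters(), lr=config.learning_rate,
                     beta1=config.adam_beta1, beta2=config.adam_beta2,
                     weight_decay=config.weight_decay)
        opt_d = Adam(d1.parameters() + d2.parameters() + d3.parameters(),
                     lr=config.learning_rate,
                     beta1=config.adam_beta1, beta2=config.adam_beta2,
                     weight_decay=config.weight_decay)
        return cls(gen, d1, d2, d3, opt_g, opt_d)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.generator.save(directory / "generator.npz")
        self.d1.save(directory / "d1.npz")
        self.d2.save(directory / "d2.npz")
        self.d3.save(directory / "d3.npz")
        np.savez(directory / "optim.npz", step=self.step,
                 g_t=self.opt_g.t, d_t=self.opt_d.t,
                 **{f"g_m/{i}": m for i, m in enumerate(self.opt_g.m)},
                 **{f"g_v/{i}": v for i, v in enumerate(self.opt_g.v)},
                 **{f"d_m/{i}": m for i, m in enumerate(self.opt_d.m)},
                 **{f"d_v/{i}": v for i, v in enumerate(self.opt_d.v)})

    @classmethod
    def load(cls, directory, config: TrainConfig) -> "TrainState":
        directory = Path(directory)
        state = cls.initialize(config)
        state.generator = DualStreamGenerator.load(directory / "generator.npz")
        state.d1 = ClassifierD1.load(directory / "d1.npz")
        state.d2 = PatchCriticD2.load(directory / "d2.npz")
        state.d3 = FourierCriticD3.load(directory / "d3.npz")
        state.opt_g = Adam(state.generator.parameters(), lr=config.learning_rate,
                           beta1=config.adam_beta1, beta2=config.adam_beta2,
                           weight_decay=config.weight_decay)
        state.opt_d = Adam(state.d1.parameters() + state.d2.parameters()
                           + state.d3.parameters(), lr=config.learning_rate,
                           beta1=config.adam_beta1, beta2=config.adam_beta2,
                           weight_decay=config.weight_decay)
        with np.load(directory / "optim.npz") as arc:
            state.step = int(arc["step"])
            state.opt_g.t = int(arc["g_t"])
            state.opt_d.t = int(arc["d_t"])
            state.opt_g.m = [arc[f"g_m/{i}"] for i in range(len(state.opt_g.m))]
            state.opt_g.v = [arc[f"g_v/{i}"] for i in range(len(state.opt_g.v))]
            state.opt_d.m = [arc[f"d_m/{i}"] for i in range(len(state.opt_d.m))]
            state.opt_d.v = [arc[f"d_v/{i}"] for i in range(len(state.opt_d.v))]
        return state


def _step_seed(config_seed: int, step: int, tag: int) -> int:
    ss = np.random.SeedSequence([config_seed & 0x7FFFFFFF, 0x57E9, step, tag])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def train_step(batch: Sequence[ImageSample], state: TrainState,
               config: TrainConfig) -> tuple[LossReport, LossReport]:
    """One discriminator update then one generator update on a batch."""
    if len(batch) < 2:
        raise ValueError("train_step needs a batch of >= 2 samples")
    x = np.stack([s.pixels for s in batch])
    labels = np.array([s.label for s in batch])
    gen, d1, d2, d3 = state.generator, state.d1, state.d2, state.d3
    step = state.step
    try:
        # one shared generator forward: encode, two perturbed views, decode
        gen.zero_grad()
        z, skips = gen.encode_with_skips(x)
        z1 = gen.perturb(z, config.sigma_global, config.sigma_local,
                         seed=_step_seed(config.seed, step, 1))
        z2 = gen.perturb(z, config.sigma_global, config.sigma_local,
                         seed=_step_seed(config.seed, step, 2))
        clp = clp_loss_inbatch(gen.project(z1).values, gen.project(z2).values,
                               config.tau)
        out_g, out_l = gen.decode(z1.global_part, z1.local_part, skips)
        image = (out_g + out_l).sigmoid()
        fake_pixels = image.data.copy()  # detached: D must not move G

        # ---- discriminator side -------------------------------------------
        state.opt_d.zero_grad()
        cls_d = nll_from_log_probs(d1.log_probs(x), labels)
        adv_patch_d = patch_adv_loss(d2.score_map(x), d2.score_map(fake_pixels),
                                     side="discriminator")
        adv_freq_d = freq_adv_loss(d3.score(spectral_transform(x)),
                                   d3.score(spectral_transform(fake_pixels)),
                                   side="discriminator")
        # CLP depends only on generator parameters; it enters the D report as
        # a constant so the weighted-sum identity of the aggregate loss holds.
        clp_const = Tensor(clp.data.copy())
        total_d, report_d = total_loss(clp_const, cls_d, adv_patch_d, adv_freq_d,
                                       config.loss_weights, side="discriminator",
                                       tau=config.tau)
        total_d.backward()
        state.opt_d.step()

        # ---- generator side -----------------------------------------------
        state.opt_g.zero_grad()
        d1.zero_grad(); d2.zero_grad(); d3.zero_grad()
        cls_g = nll_from_log_probs(d1.log_probs(image), labels)
        adv_patch_g = patch_adv_loss(None, d2.score_map(image), side="generator")
        adv_freq_g = freq_adv_loss(None, d3.score(spectral_transform(image)),
                                   side="generator")
        total_g, report_g = total_loss(clp, cls_g, adv_patch_g, adv_freq_g,
                                       config.loss_weights, side="generator",
                                       tau=config.tau)
        recon = (image - Tensor(x[:, None])).abs().mean()
        final_g = total_g + config.recon_weight * recon
        report_g.total = float(final_g.data)
        final_g.backward()
        state.opt_g.step()
    except FloatingPointError as err:
        raise FloatingPointError(f"aborting at step {step}: {err}") from err
    state.step += 1
    return report_d, report_g


def _validation_scores(state: TrainState, val: Sequence[ImageSample],
                       batch_size: int = 32) -> tuple[float, float]:
    """Mean SSIM/PSNR between inputs and their zero-noise reconstructions."""
    ssims, psnrs = [], []
    pixels = np.stack([s.pixels for s in val])
    for start in range(0, pixels.shape[0], batch_size):
        chunk = pixels[start : start + batch_size]
        recon = state.generator.generate(chunk, 0.0, 0.0, seed=0).images
        for orig, rec in zip(chunk, recon):
            ssims.append(ssim(orig, rec))
            psnrs.append(psnr(orig, rec))
    return float(np.mean(ssims)), float(np.mean(psnrs))


def fit(dataset: Sequence[ImageSample], config: TrainConfig,
        out_dir=None, resume_from=None) -> tuple[TrainState, list[dict]]:
    """Train on a dataset; returns the final state and per-epoch history.

    A seed-fixed 10% split is held out for validation SSIM/PSNR.  When
    ``out_dir`` is given, per-epoch checkpoints and a JSON-lines history are
    written there; ``resume_from`` restarts from a saved state directory.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5F17]))
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(config.val_fraction * len(dataset))))
    val = [dataset[i] for i in order[:n_val]]
    train = [dataset[i] for i in order[n_val:]]
    if len(train) < 2:
        raise ValueError("dataset too small for a train/validation split")

    state = (TrainState.load(resume_from, config) if resume_from
             else TrainState.initialize(config))
    history: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    val_ssim, val_psnr = _validation_scores(state, val)
    history.append({"epoch": 0, "val_ssim": val_ssim, "val_psnr": val_psnr})

    for epoch in range(1, config.epochs + 1):
        ep_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xE9, epoch])
        )
        perm = ep_rng.permutation(len(train))
        d_reports, g_reports = [], []
        for start in range(0, len(train), config.batch_size):
            idx = perm[start : start + config.batch_size]
            if idx.size < 2:
                continue
            rd, rg = train_step([train[i] for i in idx], state, config)
            d_reports.append(rd)
            g_reports.append(rg)
            if out_path is not None:
                with open(out_path / "losses.jsonl", "a") as fh:
                    for r in (rd, rg):
                        fh.write(json.dumps({"step": state.step - 1,
                                             **r.as_dict()}) + "\n")
        val_ssim, val_psnr = _validation_scores(state, val)
        entry = {
            "epoch": epoch,
            "val_ssim": val_ssim,
            "val_psnr": val_psnr,
            "d_total": float(np.mean([r.total for r in d_reports])),
            "g_total": float(np.mean([r.total for r in g_reports])),
            "clp": float(np.mean([r.clp for r in g_reports])),
            "cls": float(np.mean([r.cls for r in d_reports])),
            "adv_patch": float(np.mean([r.adv_patch for r in d_reports])),
            "adv_freq": float(np.mean([r.adv_freq for r in d_reports])),
        }
        history.append(entry)
        if out_path is not None:
            state.save(out_path / f"epoch-{epoch:03d}")
            with open(out_path / "history.jsonl", "a") as fh:
                fh.write(json.dumps(entry) + "\n")
    return state, history


def augment_dataset(dataset: Sequence[ImageSample], state: TrainState,
                    level: int, seed: int,
                    sigma_global: float = 0.1, sigma_local: float = 0.1,
                    batch_size: int = 32) -> list[ImageSample]:
    """Append ``level`` generated variants per input; labels are inherited."""
    if level < 0:
        raise ValueError("level must be >= 0")
    out = list(dataset)
    if level == 0:
        return out
    pixels = np.stack([s.pixels for s in dataset])
    for k in range(level):
        variant_seed = _step_seed(seed, k, 0xA9)
        for start in range(0, pixels.shape[0], batch_size):
            chunk = pixels[start : start + batch_size]
            gen_out = state.generator.generate(
                chunk, sigma_global, sigma_local, seed=variant_seed + start
            )
            for j, img in enumerate(gen_out.images):
                src = dataset[start + j]
                out.append(ImageSample(pixels=np.clip(img, 0.0, 1.0),
                                       label=src.label,
                                       id=f"{src.id}/aug-{k}").validate())
    return out


def generator_fn(state: TrainState, sigma_global: float = 0.1,
                 sigma_local: float = 0.1, batch_size: int = 32):
    """Adapt a trained state to the ``generator(images, seed)`` callable that
    the diversity harness expects."""

    def run(images: np.ndarray, seed: int) -> np.ndarray:
        chunks = []
        for start in range(0, images.shape[0], batch_size):
            chunk = images[start : start + batch_size]
            chunks.append(state.generator.generate(
                chunk, sigma_global, sigma_local, seed=seed + start).images)
        return np.concatenate(chunks)

    return run
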