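"""Loss objectives against closed forms and explicit brute-force oracles."""

import math

import numpy as np
import pytest

from dsclpgan.losses import (LossWeights, classification_loss, clp_loss,
                             clp_loss_inbatch, freq_adv_loss, patch_adv_loss,
                             total_loss)
from dsclpgan.nn.tensor import Tensor


def cosine(a, b):
    return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))


def clp_oracle(anchor, positive, negatives, tau):
    """Explicit-loop InfoNCE: the denominator enumerates the positive term
    plus every negative term."""
    pos = math.exp(cosine(anchor, positive) / tau)
    denom = pos
    for n in negatives:
        denom += math.exp(cosine(anchor, n) / tau)
    return -math.log(pos / denom)


class TestClpLoss:
    def test_uniform_similarity_returns_log_k(self):
        # anchor equidistant from positive and 3 negatives -> -log(1/4)
        a = np.array([1.0, 0.0, 0.0])
        others = [np.array([0.5, 1.0, 0.0])] * 4
        for tau in (0.05, 0.5, 1.0, 5.0):
            loss = clp_loss(a, others[0], others[1:], tau=tau).item()
            assert loss == pytest.approx(math.log(4), abs=1e-12)

    def test_orthogonal_negative_closed_form(self):
        a = np.array([1.0, 0.0])
        loss = clp_loss(a, a, [np.array([0.0, 1.0])], tau=1.0).item()
        assert loss == pytest.approx(math.log(1 + math.exp(-1)), abs=1e-12)
        assert loss == pytest.approx(0.3133, abs=1e-4)

    def test_matches_brute_force_oracle_on_random_batches(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            dim = int(rng.integers(2, 65))
            n_neg = int(rng.integers(1, 32))
            tau = float(rng.choice([0.05, 0.5, 1.0, 5.0]))
            a = rng.normal(size=dim)
            p = rng.normal(size=dim)
            negs = [rng.normal(size=dim) for _ in range(n_neg)]
            ours = clp_loss(a, p, negs, tau=tau).item()
            assert ours == pytest.approx(clp_oracle(a, p, negs, tau), abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=8)
        p = rng.normal(size=8)
        negs = [rng.normal(size=8) for _ in range(3)]
        base = clp_loss(a, p, negs, tau=0.5).item()
        scaled = clp_loss(10.0 * a, 0.01 * p, [3.0 * n for n in negs], tau=0.5).item()
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_monotone_in_similarities(self):
        """Decreasing in cos(anchor, positive); increasing in each negative."""
        def loss(cp, cns, tau=0.5):
            num = math.exp(cp / tau)
            return -math.log(num / (num + sum(math.exp(c / tau) for c in cns)))

        # realized through embeddings: rotate positive/negative toward anchor
        a = np.array([1.0, 0.0])
        def emb(c):  # unit vector at cosine c from the anchor
            return np.array([c, math.sqrt(1 - c * c)])

        l_lo = clp_loss(a, emb(0.2), [emb(0.1), emb(-0.3)], tau=0.5).item()
        l_hi = clp_loss(a, emb(0.4), [emb(0.1), emb(-0.3)], tau=0.5).item()
        assert l_hi < l_lo
        l_neg_lo = clp_loss(a, emb(0.2), [emb(0.1), emb(-0.3)], tau=0.5).item()
        l_neg_hi = clp_loss(a, emb(0.2), [emb(0.3), emb(-0.3)], tau=0.5).item()
        assert l_neg_hi > l_neg_lo
        assert loss(0.4, [0.1]) < loss(0.2, [0.1])  # oracle agrees on direction

    def test_lower_temperature_sharpens_near_similarity_ties(self):
        """With the positive barely ahead of a negative, the loss gradient
        w.r.t. the positive similarity scales like 1/tau; the sharpening is a
        near-tie property (far from the tie the softmax saturates)."""
        a = np.array([1.0, 0.0])
        def emb(c):
            return np.array([c, math.sqrt(1 - c * c)])
        negs = [emb(0.30)]
        eps = 1e-4
        d_tau1 = (clp_loss(a, emb(0.35 + eps), negs, tau=1.0).item()
                  - clp_loss(a, emb(0.35 - eps), negs, tau=1.0).item()) / (2 * eps)
        d_tau01 = (clp_loss(a, emb(0.35 + eps), negs, tau=0.1).item()
                   - clp_loss(a, emb(0.35 - eps), negs, tau=0.1).item()) / (2 * eps)
        assert abs(d_tau01) > abs(d_tau1)

    def test_validation_errors(self):
        a = np.ones(3)
        with pytest.raises(ValueError, match="temperature"):
            clp_loss(a, a, [a], tau=0.0)
        with pytest.raises(ValueError, match="zero-norm"):
            clp_loss(np.zeros(3), a, [a], tau=1.0)
        with pytest.raises(ValueError, match="negative"):
            clp_loss(a, a, [], tau=1.0)

    def test_inbatch_matches_per_sample_oracle(self):
        rng = np.random.default_rng(3)
        n, p = 6, 8
        v1 = rng.normal(size=(n, p))
        v2 = rng.normal(size=(n, p))
        ours = clp_loss_inbatch(Tensor(v1), Tensor(v2), tau=0.5).item()
        expected = np.mean([
            clp_oracle(v1[i], v2[i], [v2[j] for j in range(n) if j != i], 0.5)
            for i in range(n)
        ])
        assert ours == pytest.approx(expected, abs=1e-9)


class TestClassificationLoss:
    def test_perfect_prediction_is_zero(self):
        probs = np.array([0.0, 1.0, 0.0, 0.0])
        assert classification_loss(probs, 1).item() <= 1e-6

    def test_uniform_prediction_is_log4(self):
        probs = np.full(4, 0.25)
        for label in range(4):
            assert classification_loss(probs, label).item() == pytest.approx(
                math.log(4), abs=1e-12)

    def test_against_naive_summation_oracle(self):
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        one_hot = np.array([1.0, 0.0, 0.0, 0.0])
        oracle = -sum(one_hot[i] * math.log(probs[i]) for i in range(4))
        assert classification_loss(probs, 0).item() == pytest.approx(oracle, abs=1e-9)
        assert classification_loss(probs, 0).item() == pytest.approx(0.3567, abs=1e-4)

    def test_batch_averages_and_label_range(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]])
        got = classification_loss(probs, np.array([0, 2])).item()
        assert got == pytest.approx((-math.log(0.7) + math.log(4)) / 2, abs=1e-9)
        with pytest.raises(ValueError, match="labels"):
            classification_loss(probs, np.array([0, 4]))


@pytest.mark.parametrize("adv", [patch_adv_loss, freq_adv_loss])
class TestAdversarialLosses:
    def test_ignorant_critic_discriminator_loss(self, adv):
        half = np.full((3, 4), 0.5)
        got = adv(half, half, side="discriminator").item()
        assert got == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_confident_critic_approaches_zero(self, adv):
        real = np.full((2, 4), 0.999)
        fake = np.full((2, 4), 0.001)
        assert adv(real, fake, side="discriminator").item() <= 1e-2

    def test_generator_side_non_saturating(self, adv):
        fake = np.full((5,), 0.5)
        assert adv(None, fake, side="generator").item() == pytest.approx(
            math.log(2), abs=1e-12)

    def test_empty_batch_and_bad_side_raise(self, adv):
        with pytest.raises(ValueError, match="empty"):
            adv(np.ones(0), np.ones(0), side="discriminator")
        with pytest.raises(ValueError, match="side"):
            adv(np.ones(3) * 0.5, np.ones(3) * 0.5, side="critic")


class TestTotalLoss:
    def test_single_term(self):
        weights = LossWeights(0.0, 0.0, 0.0, 1.0)
        total, report = total_loss(0.5, 0.0, 0.0, 0.0, weights, side="generator")
        assert total.item() == pytest.approx(0.5)
        assert report.total == pytest.approx(0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0, 0.0)

    def test_weighted_sum_of_components(self):
        components = (0.3133, 0.3567, 1.3863, 1.3863)  # clp, cls, patch, freq
        total, report = total_loss(*components, LossWeights(), side="discriminator")
        assert total.item() == pytest.approx(sum(components), abs=1e-9)
        assert total.item() == pytest.approx(3.4426, abs=1e-4)
        # weighted-sum identity of the report
        w = LossWeights(2.0, 1.0, 0.5, 1.0)
        total2, r2 = total_loss(*components, w, side="discriminator")
        expect = (w.lambda_clp * r2.clp + w.lambda_cls * r2.cls
                  + w.lambda_adv * r2.adv_patch + w.lambda_freq * r2.adv_freq)
        assert r2.total == pytest.approx(expect, abs=1e-6)

    def test_linear_in_each_lambda(self):
        components = (0.4, 0.3, 0.2, 0.1)
        base, _ = total_loss(*components, LossWeights(1, 1, 1, 1), side="generator")
        doubled, _ = total_loss(*components, LossWeights(2, 1, 1, 1), side="generator")
        assert doubled.item() - base.item() == pytest.approx(0.3, abs=1e-12)

    def test_nan_component_fails_fast_naming_term(self):
        with pytest.raises(FloatingPointError, match="adv_freq"):
            total_loss(0.1, 0.1, 0.1, float("nan"), LossWeights(), side="generator")


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_clp_scale_invariance_property(seed):
    """Rescaling any embedding by a positive constant never changes the loss."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=6)
    p = rng.normal(size=6)
    negs = [rng.normal(size=6) for _ in range(3)]
    scales = rng.uniform(0.01, 100.0, size=5)
    base = clp_loss(a, p, negs, tau=0.5).item()
    scaled = clp_loss(scales[0] * a, scales[1] * p,
                      [s * n for s, n in zip(scales[2:], negs)], tau=0.5).item()
    assert scaled == pytest.approx(base, abs=1e-9)
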