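"""Metric implementations against closed forms and explicit sliding-window /
pairwise-loop oracles."""

import numpy as np
import pytest

from dsclpgan.metrics import (PSNR_CAP_DB, fid, latent_distance, psnr, ssim,
                              diversity_eval, random_feature_extractor)
from dsclpgan.phantom import make_dataset


def ssim_window_oracle(a, b, win=11, sigma=1.5):
    """Explicit per-window loop with Gaussian weights over valid positions."""
    ax = np.arange(win) - (win - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    h, wd = a.shape
    vals = []
    for i in range(h - win + 1):
        for j in range(wd - win + 1):
            pa = a[i:i + win, j:j + win]
            pb = b[i:i + win, j:j + win]
            mu_a = (w * pa).sum()
            mu_b = (w * pb).sum()
            va = (w * pa * pa).sum() - mu_a ** 2
            vb = (w * pb * pb).sum() - mu_b ** 2
            cov = (w * pa * pb).sum() - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


class TestSsim:
    def test_identity_is_exactly_one(self):
        x = np.random.default_rng(0).uniform(0, 1, (32, 32))
        assert ssim(x, x) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (32, 32))
        b = rng.uniform(0, 1, (32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-9)

    def test_matches_sliding_window_oracle(self):
        a = np.linspace(0, 1, 16 * 16).reshape(16, 16)  # fixed ramp
        b = 0.5 * a + 0.1
        assert ssim(a, b) == pytest.approx(ssim_window_oracle(a, b), abs=1e-6)

    def test_matches_skimage_cross_check(self):
        from skimage.metrics import structural_similarity

        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (64, 64))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        ref = structural_similarity(a, b, win_size=11, gaussian_weights=True,
                                    sigma=1.5, data_range=1.0,
                                    use_sample_covariance=False)
        assert ssim(a, b) == pytest.approx(ref, abs=1e-7)

    def test_bounded_and_discriminates_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.uniform(0, 1, (16, 16))
            b = rng.uniform(0, 1, (16, 16))
            v = ssim(a, b)
            assert -1.0 <= v <= 1.0
            assert v < 1.0  # equals one only for identical inputs

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            ssim(np.zeros((16, 16)), np.zeros((32, 32)))


class TestPsnr:
    def test_identity_returns_cap(self):
        x = np.random.default_rng(0).uniform(0, 1, (16, 16))
        assert psnr(x, x) == PSNR_CAP_DB

    def test_uniform_shift_closed_form(self):
        a = np.full((32, 32), 0.4)
        assert psnr(a, a + 0.1) == pytest.approx(20.0, abs=1e-9)

    def test_halving_mse_adds_three_db(self):
        a = np.zeros((32, 32))
        d1 = psnr(a, a + 0.2)
        d2 = psnr(a, a + 0.2 / np.sqrt(2))
        assert d2 - d1 == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_strictly_decreasing_on_noise_ladder(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.3, 0.7, (32, 32))
        values = [psnr(a, a + eps) for eps in (0.01, 0.02, 0.05, 0.1, 0.2)]
        assert all(x > y for x, y in zip(values, values[1:]))


class TestFid:
    def test_identical_sets_give_zero(self):
        feats = np.random.default_rng(0).normal(size=(200, 8))
        assert fid(feats, feats) == pytest.approx(0.0, abs=1e-6)

    def test_one_dimensional_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=(10_000, 1))
        b = rng.normal(1.0, 1.0, size=(10_000, 1))
        # exact moments: (mu1-mu2)^2 + (s1-s2)^2 = 1
        assert fid(a, b) == pytest.approx(1.0, abs=0.1)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = rng.normal(size=(50, 4))
            b = rng.normal(loc=rng.normal(), size=(50, 4))
            ab, ba = fid(a, b), fid(b, a)
            assert ab >= 0
            assert ab == pytest.approx(ba, abs=1e-6)

    def test_too_few_samples_advises_ridge(self):
        feats = np.random.default_rng(3).normal(size=(5, 8))
        with pytest.raises(ValueError, match="ridge"):
            fid(feats, feats)
        assert fid(feats, feats, ridge=1e-6) == pytest.approx(0.0, abs=1e-6)


class TestLatentDistance:
    def test_identical_embeddings_give_zero(self):
        g = np.tile(np.array([1.0, 2.0]), (5, 1))
        out = latent_distance({"a": g, "b": g.copy()})
        assert out.between == 0.0
        assert out.within == 0.0

    def test_degenerate_clusters(self):
        a = np.tile(np.array([0.0, 0.0]), (4, 1))
        b = np.tile(np.array([2.0, 0.0]), (4, 1))
        out = latent_distance({"a": a, "b": b})
        assert out.between == pytest.approx(2.0)
        assert out.within == pytest.approx(0.0)
        assert out.separation == pytest.approx(2.0)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(size=(rng.integers(3, 9), 6)) for k in range(4)}
        out = latent_distance(groups)
        cents = {k: g.mean(axis=0) for k, g in groups.items()}
        keys = list(groups)
        between = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                between.append(np.linalg.norm(cents[keys[i]] - cents[keys[j]]))
        within = []
        for k in keys:
            for row in groups[k]:
                within.append(np.linalg.norm(row - cents[k]))
        assert out.between == pytest.approx(np.mean(between), abs=1e-9)
        assert out.within == pytest.approx(np.mean(within), abs=1e-9)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            latent_distance({"a": np.zeros((3, 2))})


class TestDiversityEval:
    def test_level_zero_determinism_and_self_consistency(self, default_spec):
        train = make_dataset(default_spec, 40, seed=31)
        test = make_dataset(default_spec, 24, seed=32)
        ident = lambda imgs, seed: imgs
        a = diversity_eval(train, test, ident, levels=[0, 0], seed=3,
                           classifier_steps=30)
        b = diversity_eval(train, test, ident, levels=[0], seed=3,
                           classifier_steps=30)
        assert a[0] == b[0]

    def test_rejects_empty_sets_and_negative_levels(self, default_spec):
        ds = make_dataset(default_spec, 4, seed=1)
        ident = lambda imgs, seed: imgs
        with pytest.raises(ValueError, match="nonempty"):
            diversity_eval([], ds, ident, levels=[0], seed=0)
        with pytest.raises(ValueError, match=">= 0"):
            diversity_eval(ds, ds, ident, levels=[-1], seed=0)


def test_random_feature_extractor_is_reproducible():
    ex1 = random_feature_extractor(seed=9)
    ex2 = random_feature_extractor(seed=9)
    imgs = np.random.default_rng(0).uniform(0, 1, (4, 64, 64))
    assert np.array_equal(ex1(imgs), ex2(imgs))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_ssim_bounded_and_symmetric_property(seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, (16, 16))
    b = rng.uniform(0, 1, (16, 16))
    v = ssim(a, b)
    assert -1.0 <= v <= 1.0
    assert v == pytest.approx(ssim(b, a), abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fid_nonnegative_and_symmetric_property(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(30, 3))
    b = rng.normal(loc=rng.normal(), scale=abs(rng.normal()) + 0.5, size=(30, 3))
    assert fid(a, b) >= 0
    assert fid(a, b) == pytest.approx(fid(b, a), abs=1e-6)
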