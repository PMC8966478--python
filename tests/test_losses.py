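"""Loss-term oracles: every training loss equals a direct recomputation of
its defining formula, and the optimization steps touch only their own network."""

import numpy as np
import pytest

from neurocf import nn
from neurocf.gan import Discriminator, GanConfig, Generator
from neurocf.training import (
    CagTrainConfig,
    LossWeights,
    TrainState,
    classifier_guidance_loss,
    discriminator_step,
    domain_loss_fake,
    domain_loss_real,
    generator_step,
    gradient_penalty,
    reconstruction_loss,
    train_cag,
    wasserstein_terms,
)


class ScoreOnly:
    """Critic stub whose realness score is a fixed function of the input."""

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, x):
        return self.fn(x)


class LinearCritic:
    """D_src(x) = <w, x> per sample (flattened); used for closed-form checks."""

    def __init__(self, w):
        self.w = nn.Tensor(np.asarray(w, dtype=np.float64))

    def __call__(self, x):
        flat = x.reshape((x.shape[0], -1))
        return flat @ self.w


class FixedDomainHead:
    """Discriminator stub with constant domain probabilities."""

    def __init__(self, probs):
        self.logp = np.log(np.asarray(probs, dtype=np.float64))

    def __call__(self, x):
        n = x.shape[0]
        return (nn.Tensor(np.zeros(n)),
                nn.Tensor(np.tile(self.logp, (n, 1))))


class TestWassersteinTerms:
    def test_constant_critic_gap_zero(self):
        critic = ScoreOnly(lambda x: nn.Tensor(np.full(x.shape[0], 3.3)))
        _, _, lw = wasserstein_terms(critic, np.zeros((4, 1, 2, 2)),
                                     np.ones((4, 1, 2, 2)))
        assert lw.item() == 0.0

    def test_single_pair(self):
        scores = iter([np.array([2.0]), np.array([0.5])])
        critic = ScoreOnly(lambda x: nn.Tensor(next(scores)))
        r, f, lw = wasserstein_terms(critic, np.zeros((1, 1, 1, 1)),
                                     np.zeros((1, 1, 1, 1)))
        assert (r.item(), f.item(), lw.item()) == (2.0, 0.5, 1.5)

    def test_hand_arithmetic_batches(self):
        scores = iter([np.array([1.0, 3.0]), np.array([0.0, 2.0])])
        critic = ScoreOnly(lambda x: nn.Tensor(next(scores)))
        _, _, lw = wasserstein_terms(critic, np.zeros((2, 1, 1, 1)),
                                     np.zeros((2, 1, 1, 1)))
        assert lw.item() == pytest.approx(1.0)

    def test_empty_batch_rejected(self):
        critic = ScoreOnly(lambda x: nn.Tensor(np.zeros(x.shape[0])))
        with pytest.raises(ValueError, match="empty"):
            wasserstein_terms(critic, np.zeros((0, 1, 1, 1)), np.zeros((1, 1, 1, 1)))


class TestGradientPenalty:
    def test_unit_norm_linear_critic_zero_penalty(self):
        w = np.zeros(8)
        w[0] = 1.0  # ||w|| = 1
        gp = gradient_penalty(LinearCritic(w),
                              np.random.default_rng(0).uniform(size=(3, 1, 2, 4)),
                              np.random.default_rng(1).uniform(size=(3, 1, 2, 4)),
                              np.random.default_rng(2))
        assert gp.item() == pytest.approx(0.0, abs=1e-12)

    def test_norm_three_linear_critic_penalty_four(self):
        w = np.zeros(8)
        w[:9] = 1.0
        w = w / np.linalg.norm(w) * 3.0  # ||w|| = 3 -> (3-1)^2 = 4
        gp = gradient_penalty(LinearCritic(w),
                              np.random.default_rng(3).uniform(size=(5, 1, 2, 4)),
                              np.random.default_rng(4).uniform(size=(5, 1, 2, 4)),
                              np.random.default_rng(5))
        assert gp.item() == pytest.approx(4.0, rel=1e-10)

    def test_autodiff_gradient_matches_finite_differences(self):
        # input gradient of a small random conv critic vs central differences
        cfg = GanConfig(input_shape=(8, 8), K=2, base_channels=2, seed=0)
        disc = Discriminator(cfg)
        for p in disc.parameters():
            p.data = p.data.astype(np.float64)
        x0 = np.random.default_rng(6).uniform(size=(1, 1, 8, 8))

        def score(arr):
            with nn.no_grad():
                s, _ = disc(nn.Tensor(arr))
            return float(s.data[0])

        xt = nn.Tensor(x0, requires_grad=True)
        s, _ = disc(xt)
        (g,) = nn.grad(s.sum(), [xt])
        num = np.zeros_like(x0)
        eps = 1e-6
        for i in range(8):
            for j in range(8):
                xp, xm = x0.copy(), x0.copy()
                xp[0, 0, i, j] += eps
                xm[0, 0, i, j] -= eps
                num[0, 0, i, j] = (score(xp) - score(xm)) / (2 * eps)
        denom = max(np.abs(num).max(), 1e-12)
        assert np.abs(g.data - num).max() / denom < 1e-4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            gradient_penalty(LinearCritic(np.ones(4)), np.zeros((2, 1, 2, 2)),
                             np.zeros((3, 1, 2, 2)), np.random.default_rng(0))


@pytest.mark.parametrize(
    "probs,label,expected",
    [
        ([1.0 - 6e-13] + [1e-13] * 6, 0, 0.0),
        ([1 / 7] * 7, 3, np.log(7)),
        ([0.5, 0.5 / 6 * np.ones(6)], 0, np.log(2)),
    ],
)
def test_domain_loss_real_crossentropy_values(probs, label, expected):
    flat = np.hstack([np.atleast_1d(p) for p in probs])
    disc = FixedDomainHead(flat / flat.sum())
    loss = domain_loss_real(disc, np.zeros((4, 1, 2, 2)), [label] * 4)
    assert loss.item() == pytest.approx(expected, abs=1e-6)


def test_domain_loss_fake_equals_real_formula_on_generated_maps(tiny_ds, tiny_gan_cfg):
    gen = Generator(tiny_gan_cfg, tiny_ds.mask)
    disc = Discriminator(tiny_gan_cfg)
    x = tiny_ds.values_array()[:4][:, None].astype(np.float32)
    targets = np.array([0, 1, 2, 1])
    loss = domain_loss_fake(disc, gen, x, targets)
    # oracle: generate, then apply the real-map formula directly
    with nn.no_grad():
        fake = gen(nn.Tensor(x), targets).data
    oracle = domain_loss_real(disc, fake, targets)
    assert loss.item() == pytest.approx(oracle.item(), abs=1e-6)


class TestReconstructionLoss:
    def test_identity_generator_zero(self, identity_gen, tiny_ds):
        x = tiny_ds.values_array()[:3]
        loss = reconstruction_loss(identity_gen, x, [0, 1, 2], [1, 2, 0])
        assert loss.item() == 0.0

    def test_constant_shift_generator_two_delta(self, tiny_ds):
        from conftest import ConstantShiftGenerator

        delta = 0.07
        gen = ConstantShiftGenerator(tiny_ds.mask, delta, K=3)
        x = tiny_ds.values_array()[:2]
        loss = reconstruction_loss(gen, x, [0, 1], [1, 0])
        assert loss.item() == pytest.approx(2 * delta, rel=1e-6)

    def test_matches_brute_force_formula(self, tiny_ds, tiny_gan_cfg):
        gen = Generator(tiny_gan_cfg, tiny_ds.mask)
        x = tiny_ds.values_array()[:3][:, None].astype(np.float32)
        c = np.array([1, 2, 0])
        cp = np.array([0, 0, 1])
        loss = reconstruction_loss(gen, x, c, cp)
        with nn.no_grad():
            recon = gen(gen(nn.Tensor(x), c), cp).data
        n_mask = tiny_ds.mask.sum()
        oracle = float(np.abs(x - recon).sum() / (3 * n_mask))
        assert loss.item() == pytest.approx(oracle, abs=1e-6)


@pytest.mark.parametrize(
    "p_target,expected",
    [(1.0, 0.0), (1 / 7, np.log(7)), (0.25, np.log(4))],
)
def test_classifier_guidance_crossentropy_values(p_target, expected):
    K = 7

    class FixedClf:
        def log_probs(self, x):
            probs = np.full(K, (1 - p_target) / (K - 1))
            probs[2] = p_target
            return nn.Tensor(np.tile(np.log(probs), (x.shape[0], 1)))

    loss = classifier_guidance_loss(FixedClf(), np.zeros((5, 1, 2, 2)), [2] * 5)
    assert loss.item() == pytest.approx(expected, abs=1e-6)


# -- optimization steps ----------------------------------------------------


@pytest.fixture()
def train_state(tiny_ds, tiny_gan_cfg):
    from neurocf.classifier import ClassifierConfig, build_classifier

    clf = build_classifier(
        ClassifierConfig(input_shape=(16, 16), K=3,
                         conv_blocks=[(4, 3, 2), (8, 3, 2)], fc_widths=[8], seed=0)
    )
    gen = Generator(tiny_gan_cfg, tiny_ds.mask)
    disc = Discriminator(tiny_gan_cfg)
    return TrainState(gen, disc, clf, LossWeights(),
                      CagTrainConfig(batch_size=4, seed=0))


def _snapshot(module):
    return [p.data.copy() for p in module.parameters()]


def _changed(before, module):
    return any(not np.array_equal(b, p.data)
               for b, p in zip(before, module.parameters()))


class TestSteps:
    def test_discriminator_step_touches_only_discriminator(self, train_state, tiny_ds):
        x = tiny_ds.values_array()[:4]
        y = tiny_ds.labels_array()[:4]
        g0, d0, c0 = (_snapshot(train_state.gen), _snapshot(train_state.disc),
                      _snapshot(train_state.clf))
        report = discriminator_step(train_state, x, y)
        assert _changed(d0, train_state.disc)
        assert not _changed(g0, train_state.gen)
        assert not _changed(c0, train_state.clf)
        assert all(np.isfinite(v) for v in report.values())

    def test_generator_step_touches_only_generator(self, train_state, tiny_ds):
        x = tiny_ds.values_array()[:4]
        y = tiny_ds.labels_array()[:4]
        g0, d0, c0 = (_snapshot(train_state.gen), _snapshot(train_state.disc),
                      _snapshot(train_state.clf))
        report = generator_step(train_state, x, y)
        assert _changed(g0, train_state.gen)
        assert not _changed(d0, train_state.disc)
        assert not _changed(c0, train_state.clf)
        assert all(np.isfinite(v) for v in report.values())
        assert "Lcnn" in report  # computed even when unweighted

    def test_rec_only_objective_decreases_on_fixed_batch(self, tiny_ds, tiny_gan_cfg):
        from neurocf.classifier import ClassifierConfig, build_classifier

        clf = build_classifier(
            ClassifierConfig(input_shape=(16, 16), K=3,
                             conv_blocks=[(4, 3, 2)], fc_widths=[8], seed=0)
        )
        gen = Generator(tiny_gan_cfg, tiny_ds.mask)
        disc = Discriminator(tiny_gan_cfg)
        weights = LossWeights(lambda_gp=0.0, lambda_cls=0.0, lambda_rec=10.0,
                              lambda_cnn=0.0)
        state = TrainState(gen, disc, clf, weights,
                           CagTrainConfig(batch_size=4, lr=5e-4, seed=0))
        x = tiny_ds.values_array()[:4]
        y = tiny_ds.labels_array()[:4]
        first = generator_step(state, x, y)["Lrec"]
        for _ in range(49):
            last = generator_step(state, x, y)["Lrec"]
        assert last < first


def test_scalar_linear_critic_moves_toward_larger_gap(tiny_ds):
    # 1-parameter critic D(x) = w * mean(x): with gp = cls = 0, minimizing
    # -(Lwass) moves w along sign(mean_real - mean_fake)
    class ScalarCritic(nn.Module):
        def __init__(self):
            self.w = nn.Parameter(np.array(0.0), dtype=np.float64)

        def forward(self, x):
            return (x.mean(axis=(1, 2, 3)) * self.w,
                    nn.Tensor(np.zeros((x.shape[0], 3))))

    real = tiny_ds.values_array()[:4]
    fake = np.zeros_like(real)
    critic = ScalarCritic()
    _, _, lwass = wasserstein_terms(critic, real, fake)
    ld = -lwass
    ld.backward()
    grad = critic.w.grad
    gap_direction = real.mean() - fake.mean()  # positive here
    assert gap_direction > 0
    assert grad < 0  # gradient descent increases w, widening the gap


class TestTrainCag:
    def test_smoke_run_history_finite(self, tiny_ds):
        from neurocf.classifier import ClassifierConfig, build_classifier

        clf = build_classifier(
            ClassifierConfig(input_shape=(16, 16), K=3,
                             conv_blocks=[(4, 3, 2)], fc_widths=[8], seed=0)
        )
        gen, disc, history = train_cag(
            clf, tiny_ds,
            LossWeights(),
            CagTrainConfig(batch_size=4, gen_steps=3,
                           critic_steps_per_gen_step=2, seed=0),
            GanConfig(input_shape=(16, 16), K=3, base_channels=2, seed=0),
        )
        assert len(history) == 3
        for row in history:
            for k, v in row.items():
                if k != "step":
                    assert np.isfinite(v), k

    def test_two_domain_stargan_reduction_runs(self, tiny_ds):
        # lambda_cnn = 0 and K = 2 reduces to a plain two-domain StarGAN
        from neurocf.classifier import ClassifierConfig, build_classifier
        from neurocf.data import LabeledDataset

        two = LabeledDataset(
            [m for m in tiny_ds.maps if m.label < 2], tiny_ds.class_names[:2]
        )
        clf = build_classifier(
            ClassifierConfig(input_shape=(16, 16), K=2,
                             conv_blocks=[(4, 3, 2)], fc_widths=[8], seed=0)
        )
        _, _, history = train_cag(
            clf, two,
            LossWeights(lambda_cnn=0.0),
            CagTrainConfig(batch_size=4, gen_steps=2,
                           critic_steps_per_gen_step=1, seed=0),
            GanConfig(input_shape=(16, 16), K=2, base_channels=2, seed=0),
        )
        assert all(np.isfinite(h["G_LG"]) for h in history)
        assert all("G_Lcnn" in h for h in history)

    def test_seeded_training_reproducible(self, tiny_ds):
        from neurocf.classifier import ClassifierConfig, build_classifier

        outs = []
        for _ in range(2):
            clf = build_classifier(
                ClassifierConfig(input_shape=(16, 16), K=3,
                                 conv_blocks=[(4, 3, 2)], fc_widths=[8], seed=0)
            )
            gen, _, history = train_cag(
                clf, tiny_ds, LossWeights(),
                CagTrainConfig(batch_size=4, gen_steps=2,
                               critic_steps_per_gen_step=1, seed=9),
                GanConfig(input_shape=(16, 16), K=3, base_channels=2, seed=9),
            )
            outs.append((history[-1]["G_LG"],
                         [p.data.copy() for p in gen.parameters()]))
        assert outs[0][0] == outs[1][0]
        assert all(np.array_equal(a, b) for a, b in zip(outs[0][1], outs[1][1]))
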