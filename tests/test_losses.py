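"""Closed-form and independent-oracle checks of the five training losses.

The critics here are analytic test doubles (constant, linear, quadratic)
whose gradients are known by hand, so every expected value is computed
independently of the loss implementations.
"""

import numpy as np
import pytest

import s3cgan.autodiff as ad
from s3cgan.autodiff import Tensor
from s3cgan.image_data import Domain
from s3cgan.losses import (LossWeights, NonFiniteLossError, color_loss,
                           critic_loss, cycle_loss, generator_adversarial_loss,
                           generator_objective, gradient_penalty)
from conftest import ConstantCritic, LinearCritic, QuadraticCritic


class FixedProbClassifier:
    """Test double returning a fixed target-class probability."""

    def __init__(self, p_class1: float):
        self.p = p_class1
        self.frozen = True

    def logits(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        base = ad.mul(ad.reshape(ad.sum_(ad.reshape(x, (n, -1)), axis=1), (n, 1)), 0.0)
        logit1 = np.log(self.p / (1 - self.p))
        row = ad.concat([base, ad.add(base, Tensor(logit1))], axis=1)
        return row


def _rand_batch(rng, n=3, shape=(2, 4, 4)):
    return rng.normal(size=(n, *shape))


def test_default_weights():
    w = LossWeights()
    assert (w.alpha, w.beta, w.gp_coeff) == (10.0, 1.0, 10.0)
    with pytest.raises(ValueError):
        LossWeights(alpha=-1)


class TestGradientPenalty:
    def test_constant_critic_penalty_is_one(self):
        rng = np.random.default_rng(0)
        real, fake = _rand_batch(rng), _rand_batch(rng)
        gp = gradient_penalty(ConstantCritic(3.0), real, fake, seed=1)
        assert gp.item() == pytest.approx(1.0, abs=1e-5)

    def test_unit_slope_linear_critic_penalty_is_zero(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(2, 4, 4))
        u /= np.linalg.norm(u)
        real, fake = _rand_batch(rng), _rand_batch(rng)
        gp = gradient_penalty(LinearCritic(u), real, fake, seed=2)
        assert gp.item() == pytest.approx(0.0, abs=1e-5)

    def test_slope_three_penalty_is_four(self):
        # critic(x) = 3 * x[first pixel]: gradient norm 3 -> (3-1)^2 = 4
        u = np.zeros((2, 4, 4))
        u[0, 0, 0] = 3.0
        rng = np.random.default_rng(2)
        gp = gradient_penalty(LinearCritic(u), _rand_batch(rng), _rand_batch(rng), seed=3)
        assert gp.item() == pytest.approx(4.0, abs=1e-5)

    def test_random_linear_critics_match_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            u = rng.normal(size=(2, 3, 3)) * rng.uniform(0.1, 3)
            expected = (np.linalg.norm(u) - 1.0) ** 2
            gp = gradient_penalty(LinearCritic(u), _rand_batch(rng, shape=(2, 3, 3)),
                                  _rand_batch(rng, shape=(2, 3, 3)), seed=int(rng.integers(1e6)))
            assert gp.item() == pytest.approx(expected, abs=1e-5)

    def test_quadratic_critic_matches_hand_derivative(self):
        # D(x) = sum(a x^2) + <b, x>; grad = 2 a xhat + b, per sample
        rng = np.random.default_rng(4)
        a = rng.normal(size=(1, 2, 2))
        b = rng.normal(size=(1, 2, 2))
        real = _rand_batch(rng, n=4, shape=(1, 2, 2))
        fake = _rand_batch(rng, n=4, shape=(1, 2, 2))
        seed = 99
        eps = np.random.default_rng(seed).uniform(size=(4, 1, 1, 1))
        x_hat = eps * real + (1 - eps) * fake
        grads = 2 * a[None] * x_hat + b[None]
        norms = np.sqrt((grads ** 2).sum(axis=(1, 2, 3)))
        expected = ((norms - 1) ** 2).mean()
        gp = gradient_penalty(QuadraticCritic(a, b), real, fake, seed=seed)
        assert gp.item() == pytest.approx(expected, abs=1e-5)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for s in range(5):
            u = rng.normal(size=(2, 4, 4))
            gp = gradient_penalty(LinearCritic(u), _rand_batch(rng), _rand_batch(rng), seed=s)
            assert gp.item() >= 0.0

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            gradient_penalty(ConstantCritic(0.0), _rand_batch(rng, n=2),
                             _rand_batch(rng, n=3), seed=0)


class TestCriticLoss:
    def test_constant_critic_gives_ten(self):
        # c - c + 10 * (0 - 1)^2 = 10
        rng = np.random.default_rng(0)
        loss = critic_loss(ConstantCritic(5.0), _rand_batch(rng), _rand_batch(rng), seed=0)
        assert loss.item() == pytest.approx(10.0, abs=1e-5)

    def test_unit_slope_identical_batches_gives_zero(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(2, 4, 4))
        u /= np.linalg.norm(u)
        batch = _rand_batch(rng)
        loss = critic_loss(LinearCritic(u), batch, batch.copy(), seed=1)
        assert loss.item() == pytest.approx(0.0, abs=1e-5)

    def test_quadratic_critic_matches_symbolic_value(self):
        # two-pixel images, D(x) = a1 x1^2 + a2 x2^2 + b1 x1 + b2 x2
        rng = np.random.default_rng(2)
        a = np.array([[[0.7, -0.3]]])
        b = np.array([[[0.2, 1.1]]])
        real = rng.normal(size=(3, 1, 1, 2))
        fake = rng.normal(size=(3, 1, 1, 2))
        seed = 5
        critic = QuadraticCritic(a, b)

        def score(batch):
            return (a * batch ** 2 + b * batch).reshape(len(batch), -1).sum(axis=1)

        eps = np.random.default_rng(seed).uniform(size=(3, 1, 1, 1))
        x_hat = eps * real + (1 - eps) * fake
        grads = 2 * a[None] * x_hat + b[None]
        norms = np.sqrt((grads ** 2).sum(axis=(1, 2, 3)))
        expected = (score(fake).mean() - score(real).mean()
                    + 10.0 * ((norms - 1) ** 2).mean())
        loss = critic_loss(critic, real, fake, seed=seed)
        assert loss.item() == pytest.approx(expected, abs=1e-5)

    def test_sign_convention_real_scores_up_loss_down(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=(2, 4, 4))
        real, fake = _rand_batch(rng), _rand_batch(rng)
        base = critic_loss(LinearCritic(u), real, fake, seed=7).item()
        # raise every real score by shifting real batch along u
        shifted = real + 0.5 * u[None] / (u ** 2).sum()
        higher_real = critic_loss(LinearCritic(u), shifted, fake, seed=7).item()
        assert higher_real < base


class TestGeneratorAdversarialLoss:
    def test_constant_critic_wasserstein(self):
        rng = np.random.default_rng(0)
        loss = generator_adversarial_loss(ConstantCritic(2.5), _rand_batch(rng))
        assert loss.item() == pytest.approx(-2.5, abs=1e-9)

    def test_zero_critic_logistic(self):
        rng = np.random.default_rng(1)
        loss = generator_adversarial_loss(ConstantCritic(0.0), _rand_batch(rng),
                                          mode="logistic")
        assert loss.item() == pytest.approx(np.log(0.5), abs=1e-6)

    @pytest.mark.parametrize("mode", ["wasserstein", "logistic"])
    def test_monotone_decreasing_in_scores(self, mode):
        rng = np.random.default_rng(2)
        batch = _rand_batch(rng)
        lo = generator_adversarial_loss(ConstantCritic(1.0), batch, mode=mode).item()
        hi = generator_adversarial_loss(ConstantCritic(2.0), batch, mode=mode).item()
        assert hi < lo


class TestCycleLoss:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        b = _rand_batch(rng)
        assert cycle_loss(b, b.copy()).item() == 0.0

    def test_constant_offset(self):
        z = np.zeros((2, 3, 4, 4))
        assert cycle_loss(z, z + 0.5).item() == pytest.approx(0.5, abs=1e-12)

    def test_hand_example(self):
        orig = np.array([[[[0.0, 1.0], [0.5, 0.25]]]])
        recon = np.array([[[[0.25, 0.5], [0.5, 0.75]]]])
        assert cycle_loss(orig, recon).item() == pytest.approx(0.3125, abs=1e-12)

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = _rand_batch(rng), _rand_batch(rng)
            assert cycle_loss(a, b).item() == pytest.approx(np.mean(np.abs(b - a)), abs=1e-10)


class TestColorLoss:
    def test_perfect_confidence_is_zero(self):
        rng = np.random.default_rng(0)
        loss = color_loss(FixedProbClassifier(1 - 1e-12), _rand_batch(rng), Domain.B)
        assert loss.item() == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("p,expected", [(0.5, np.log(2)), (0.25, np.log(4))])
    def test_known_probabilities(self, p, expected):
        rng = np.random.default_rng(1)
        loss = color_loss(FixedProbClassifier(p), _rand_batch(rng), Domain.B)
        assert loss.item() == pytest.approx(expected, abs=1e-6)

    def test_target_domain_a_uses_other_column(self):
        rng = np.random.default_rng(2)
        loss = color_loss(FixedProbClassifier(0.25), _rand_batch(rng), Domain.A)
        assert loss.item() == pytest.approx(-np.log(0.75), abs=1e-6)

    def test_unfrozen_classifier_rejected(self):
        clf = FixedProbClassifier(0.5)
        clf.frozen = False
        with pytest.raises(RuntimeError):
            color_loss(clf, np.zeros((1, 3, 4, 4)), Domain.B)

    def test_strictly_positive_unless_certain(self):
        rng = np.random.default_rng(3)
        assert color_loss(FixedProbClassifier(0.9), _rand_batch(rng), Domain.B).item() > 0


class TestGeneratorObjective:
    def test_hand_arithmetic(self):
        assert generator_objective(1.0, 0.2, 0.7).item() == pytest.approx(3.7, abs=1e-9)

    def test_beta_zero_reduces_to_plain_cyclegan(self):
        w = LossWeights(beta=0.0)
        assert generator_objective(1.0, 0.2, 123.0, w).item() == pytest.approx(3.0, abs=1e-9)

    def test_all_zero(self):
        assert generator_objective(0.0, 0.0, 0.0).item() == 0.0

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            adv, cyc, col = rng.normal(), abs(rng.normal()), abs(rng.normal())
            alpha, beta = rng.uniform(0, 20), rng.uniform(0, 5)
            got = generator_objective(adv, cyc, col, LossWeights(alpha=alpha, beta=beta)).item()
            assert got == pytest.approx(adv + alpha * cyc + beta * col, abs=1e-10)

    def test_non_finite_halts(self):
        with pytest.raises(NonFiniteLossError):
            generator_objective(float("nan"), 0.0, 0.0)
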