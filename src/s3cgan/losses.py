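"""The five training losses, each a pure function of batches and models.

Sign conventions and weighting
------------------------------

* Critic (WGAN-GP):  L_advD = E[D(fake)] - E[D(real)] + 10 * GP, where
  GP = E[(||grad_xhat D(xhat)||_2 - 1)^2] over interpolates
  xhat = eps*real + (1-eps)*fake with eps ~ U(0,1) per sample. The N x N
  score map is reduced to one scalar per image by arithmetic mean before
  any expectation.
* Generator adversarial term: the Wasserstein form -E[D(fake)] by
  default. A ``logistic`` mode squashes the (unbounded) critic score
  through a sigmoid and evaluates E[log(1 - sigma(D(fake)))] — the
  classical saturating form — for comparison; both are strictly
  decreasing in every critic score.
* Cycle consistency: plain L1 between an input and its round trip
  through both generators.
* Color guidance: cross-entropy of the frozen color classifier against
  the *target* domain of the transfer, -E[log p_target]. Minimizing it
  pushes generated patches toward stain colors the pretrained
  classifier attributes to the target domain.
* Full generator objective: L_adv + alpha * L_cyc + beta * L_color with
  defaults alpha=10, beta=1.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .image_data import Domain

_NORM_EPS = 1e-16  # inside the sqrt of the gradient norm


@dataclasses.dataclass
class LossWeights:
    alpha: float = 10.0     # cycle-consistency weight
    beta: float = 1.0       # color-classifier weight
    gp_coeff: float = 10.0  # gradient-penalty multiplier

    def __post_init__(self):
        for name in ("alpha", "beta", "gp_coeff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"loss weight {name} must be finite and >= 0, got {v}")


@dataclasses.dataclass
class LossReport:
    l_advD: float
    l_adv: float
    l_cyc: float
    l_color: float
    l_obj: float
    step: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class NonFiniteLossError(RuntimeError):
    """Raised when a loss turns NaN/Inf; training must halt."""


def _check_finite(value: float, what: str) -> float:
    if not np.isfinite(value):
        raise NonFiniteLossError(f"{what} is non-finite ({value})")
    return value


def _as_batch_tensor(batch) -> Tensor:
    return batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch))


def _per_image_score(critic, batch: Tensor) -> Tensor:
    """Critic score map reduced to one scalar per image (arithmetic mean)."""
    scores = critic(batch)
    axes = tuple(range(1, scores.ndim))
    return ad.mean(scores, axis=axes) if axes else scores


def gradient_penalty(critic, real_batch, fake_batch, seed: int,
                     create_graph: bool = False) -> Tensor:
    """E[(||grad D at interpolates||_2 - 1)^2], without the x10 multiplier.

    With ``create_graph=True`` the result can be differentiated with
    respect to the critic's parameters (the double backward pass a
    WGAN-GP update requires).
    """
    real = _as_batch_tensor(real_batch)
    fake = _as_batch_tensor(fake_batch)
    if real.shape != fake.shape:
        raise ValueError(f"real/fake shape mismatch: {real.shape} vs {fake.shape}")
    n = real.shape[0]
    rng = np.random.default_rng(seed)
    eps = rng.uniform(size=(n, 1, 1, 1)).astype(real.data.dtype)
    x_hat = Tensor(eps * real.data + (1.0 - eps) * fake.data, requires_grad=True)
    total = ad.sum_(_per_image_score(critic, x_hat))
    (gx,) = ad.grad(total, [x_hat], create_graph=create_graph)
    dt = gx.data.dtype
    with ad.set_grad_enabled(create_graph):
        sq = ad.sum_(ad.mul(gx, gx), axis=(1, 2, 3))
        norms = ad.sqrt(ad.add(sq, Tensor(np.asarray(_NORM_EPS, dtype=dt))))
        penalty = ad.mean(ad.pow_(ad.add(norms, Tensor(np.asarray(-1.0, dtype=dt))), 2.0))
    return penalty


def critic_loss(critic, real_batch, fake_batch, weights: LossWeights | None = None,
                seed: int = 0, create_graph: bool = False) -> Tensor:
    """WGAN-GP critic loss: E[D(fake)] - E[D(real)] + gp_coeff * GP."""
    weights = weights or LossWeights()
    real = _as_batch_tensor(real_batch)
    fake = _as_batch_tensor(fake_batch)
    if real.shape != fake.shape:
        raise ValueError(f"real/fake shape mismatch: {real.shape} vs {fake.shape}")
    s_fake = ad.mean(_per_image_score(critic, fake))
    s_real = ad.mean(_per_image_score(critic, real))
    _check_finite(float(s_fake.data), "critic score (fake)")
    _check_finite(float(s_real.data), "critic score (real)")
    gp = gradient_penalty(critic, real, fake, seed=seed, create_graph=create_graph)
    return ad.add(ad.add(s_fake, ad.neg(s_real)), ad.mul(gp, weights.gp_coeff))


def generator_adversarial_loss(critic, fake_batch, mode: str = "wasserstein") -> Tensor:
    """Adversarial term driving the generator, decreasing in every score."""
    fake = _as_batch_tensor(fake_batch)
    scores = _per_image_score(critic, fake)
    if not np.all(np.isfinite(scores.data)):
        raise NonFiniteLossError("critic produced non-finite scores")
    if mode == "wasserstein":
        return ad.neg(ad.mean(scores))
    if mode == "logistic":
        # saturating form on the sigmoid-squashed score
        return ad.mean(ad.log(ad.add(Tensor(1.0), ad.neg(ad.sigmoid(scores)))))
    raise ValueError(f"unknown adversarial mode '{mode}'")


def cycle_loss(original_batch, reconstructed_batch) -> Tensor:
    """Mean absolute error between input and its A->B->A round trip."""
    orig = _as_batch_tensor(original_batch)
    recon = _as_batch_tensor(reconstructed_batch)
    if orig.shape != recon.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {recon.shape}")
    return ad.mean(ad.abs_(ad.add(recon, ad.neg(orig))))


def color_loss(classifier, fake_batch, target_domain: Domain | str) -> Tensor:
    """Frozen-classifier cross-entropy against the transfer's target domain."""
    if not getattr(classifier, "frozen", False):
        raise RuntimeError(
            "color_loss requires a frozen classifier: the color consultant "
            "must not be trained during adversarial training")
    target_domain = Domain(target_domain)
    fake = _as_batch_tensor(fake_batch)
    logp = ad.log_softmax(classifier.logits(fake), axis=1)
    col = 0 if target_domain == Domain.A else 1
    picked = ad.narrow(logp, 1, col, 1)
    return ad.neg(ad.mean(picked))


def generator_objective(l_adv: Tensor | float, l_cyc: Tensor | float,
                        l_color: Tensor | float,
                        weights: LossWeights | None = None) -> Tensor:
    weights = weights or LossWeights()
    parts = []
    for name, val in (("l_adv", l_adv), ("l_cyc", l_cyc), ("l_color", l_color)):
        t = val if isinstance(val, Tensor) else Tensor(float(val))
        _check_finite(float(t.data), name)
        parts.append(t)
    return ad.add(ad.add(parts[0], ad.mul(parts[1], weights.alpha)),
                  ad.mul(parts[2], weights.beta))
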