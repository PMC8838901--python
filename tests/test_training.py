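"""Protocol invariants: isolation of updates, frozen consultant,
determinism, resumability, and the loss-report identity."""

import numpy as np
import pytest

from s3cgan.losses import LossWeights
from s3cgan.synthetic_data import make_fixture_set
from s3cgan.training import (TrainingConfig, TrainingState, critic_step,
                             cycle_slope, generator_step,
                             pretrain_color_classifier, train)


@pytest.fixture(scope="module")
def fx():
    return make_fixture_set(n_per_domain=16, size=32, seed=21, n_paired=4,
                            n_pretrain=16)


@pytest.fixture(scope="module")
def cfg():
    return TrainingConfig.desk_scale(image_size=32, steps_classifier=120,
                                     steps_gan=6, batch_size=2, seed=5)


@pytest.fixture(scope="module")
def frozen_clf(fx, cfg):
    clf, acc = pretrain_color_classifier(fx["pre_a"], fx["pre_b"], cfg)
    assert acc > 0.5
    return clf


def _batches(fx, n=2):
    return fx["ds_a"].as_array()[:n], fx["ds_b"].as_array()[:n]


class TestPretraining:
    def test_classifier_comes_back_frozen(self, frozen_clf):
        assert frozen_clf.frozen

    def test_identical_images_give_chance_accuracy(self, fx):
        cfg = TrainingConfig.desk_scale(image_size=32, steps_classifier=80,
                                        batch_size=2, seed=1)
        ds = fx["pre_a"]
        _, acc = pretrain_color_classifier(ds, ds, cfg)
        assert acc == pytest.approx(0.5, abs=0.25)


class TestStepIsolation:
    def test_critic_step_leaves_generators_untouched(self, fx, cfg, frozen_clf):
        state = TrainingState(cfg, frozen_clf)
        ga, gb = state.g_a2b.checksum(), state.g_b2a.checksum()
        ba, bb = _batches(fx)
        critic_step(state, ba, bb)
        assert state.g_a2b.checksum() == ga and state.g_b2a.checksum() == gb

    def test_generator_step_leaves_critics_and_classifier_untouched(self, fx, cfg, frozen_clf):
        state = TrainingState(cfg, frozen_clf)
        da, db, cc = state.d_a.checksum(), state.d_b.checksum(), state.c_color.checksum()
        ba, bb = _batches(fx)
        generator_step(state, ba, bb)
        assert state.d_a.checksum() == da
        assert state.d_b.checksum() == db
        assert state.c_color.checksum() == cc

    def test_critic_step_determinism(self, fx, cfg, frozen_clf):
        ba, bb = _batches(fx)
        sums = []
        for _ in range(2):
            state = TrainingState(cfg, frozen_clf)
            critic_step(state, ba, bb)
            sums.append((state.d_a.checksum(), state.d_b.checksum()))
        assert sums[0] == sums[1]

    def test_critic_learns_to_separate_real_from_fake(self, fx, cfg, frozen_clf):
        import s3cgan.autodiff as ad
        state = TrainingState(cfg, frozen_clf)
        ba, bb = _batches(fx, n=4)
        for _ in range(50):
            critic_step(state, ba, bb)
        with ad.no_grad():
            fake_b = state.g_a2b(ad.Tensor(ba.astype(np.float32))).data
            d_real = state.d_b(ad.Tensor(bb.astype(np.float32))).data.mean()
            d_fake = state.d_b(ad.Tensor(fake_b)).data.mean()
        assert d_real - d_fake > 0


class TestGeneratorStep:
    def test_report_identity_under_default_weights(self, fx, cfg, frozen_clf):
        state = TrainingState(cfg, frozen_clf)
        ba, bb = _batches(fx)
        rep = generator_step(state, ba, bb)
        w = cfg.weights
        assert (w.alpha, w.beta) == (10.0, 1.0)
        assert rep.l_obj == pytest.approx(
            rep.l_adv + w.alpha * rep.l_cyc + w.beta * rep.l_color, abs=1e-6)

    def test_cycle_weight_drives_reconstruction(self, fx, frozen_clf):
        """With alpha=10 the cycle error falls over a short run; with
        alpha=beta=0 it has no gradient pressure and stays higher."""
        def run(alpha, beta, seed):
            cfg = TrainingConfig.desk_scale(
                image_size=32, steps_gan=60, batch_size=2, seed=seed,
                weights=LossWeights(alpha=alpha, beta=beta))
            fx_local = make_fixture_set(n_per_domain=16, size=32, seed=21,
                                        n_pretrain=16)
            state = train(fx_local["ds_a"], fx_local["ds_b"], cfg,
                          c_color=frozen_clf)
            return np.mean([r.l_cyc for r in state.history[-10:]])

        with_cycle = [run(10.0, 1.0, s) for s in range(2)]
        without = [run(0.0, 0.0, s) for s in range(2)]
        assert np.mean(with_cycle) < np.mean(without)


class TestTrainLoop:
    def test_history_one_report_per_step_and_identity(self, fx, cfg, frozen_clf):
        state = train(fx["ds_a"], fx["ds_b"], cfg, c_color=frozen_clf)
        assert len(state.history) == cfg.steps_gan == state.step
        w = cfg.weights
        for r in state.history:
            assert r.l_obj == pytest.approx(
                r.l_adv + w.alpha * r.l_cyc + w.beta * r.l_color, abs=1e-6)

    def test_frozen_consultant_checksum_constant(self, fx, cfg, frozen_clf):
        before = frozen_clf.checksum()
        train(fx["ds_a"], fx["ds_b"], cfg, c_color=frozen_clf)
        assert frozen_clf.checksum() == before

    def test_full_run_determinism(self, fx, cfg, frozen_clf):
        runs = []
        for _ in range(2):
            state = train(fx["ds_a"], fx["ds_b"], cfg, c_color=frozen_clf)
            runs.append(([r.as_dict() for r in state.history],
                         state.g_a2b.checksum(), state.d_b.checksum()))
        assert runs[0] == runs[1]

    def test_resume_equals_uninterrupted(self, fx, frozen_clf, tmp_path):
        mk = lambda steps: TrainingConfig.desk_scale(
            image_size=32, steps_classifier=120, steps_gan=steps,
            batch_size=2, seed=5)
        full = train(fx["ds_a"], fx["ds_b"], mk(8), c_color=frozen_clf)

        half_state = train(fx["ds_a"], fx["ds_b"], mk(4), c_color=frozen_clf)
        half_state.save(tmp_path / "ck.npz")
        resumed = TrainingState.load(tmp_path / "ck.npz")
        resumed.cfg.steps_gan = 8
        resumed = train(fx["ds_a"], fx["ds_b"], resumed.cfg, state=resumed)

        assert [r.as_dict() for r in resumed.history] == [r.as_dict() for r in full.history]
        assert resumed.g_a2b.checksum() == full.g_a2b.checksum()

    def test_unfrozen_classifier_rejected(self, cfg):
        from s3cgan.networks import ColorClassifier
        with pytest.raises(RuntimeError, match="frozen"):
            TrainingState(cfg, ColorClassifier(4, seed=0))

    def test_cycle_slope_readout(self, fx, cfg, frozen_clf):
        state = train(fx["ds_a"], fx["ds_b"], cfg, c_color=frozen_clf)
        assert np.isfinite(cycle_slope(state.history, window=5))


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainingConfig(steps_gan=0)
    with pytest.raises(ValueError):
        TrainingConfig(lr=0)
    with pytest.raises(ValueError):
        TrainingConfig(image_size=100, gen_depth=3)
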