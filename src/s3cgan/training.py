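"""Three-step training protocol.

Step 1 pretrains the binary color classifier on its own data split and
freezes it. Steps 2-3 then alternate: each iteration first updates the
two Wasserstein critics (generators fixed), then updates both
generators jointly against the adversarial, cycle-consistency and
frozen-classifier color losses (critics and classifier fixed).

Everything is driven by one ``numpy`` PCG64 stream stored in the
training state; checkpoints carry its state, so resuming reproduces the
uninterrupted run bit for bit on the same backend.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import losses as L
from . import nn
from .autodiff import Tensor
from .image_data import (Domain, DomainDataset, RangeTag, Split,
                         batch_to_patches, patches_to_batch, write_patch)
from .losses import LossReport, LossWeights, NonFiniteLossError
from .networks import ColorClassifier, PatchCritic, UNetGenerator


@dataclasses.dataclass
class TrainingConfig:
    steps_classifier: int = 300
    steps_gan: int = 600
    batch_size: int = 4
    lr: float = 2e-4
    optimizer_betas: tuple[float, float] = (0.5, 0.999)
    critic_updates_per_gen: int = 1
    weights: LossWeights = dataclasses.field(default_factory=LossWeights)
    seed: int = 0
    snapshot_every: int = 0  # 0 = no snapshots
    image_size: int = 256
    adv_mode: str = "wasserstein"
    # network shapes (library defaults sized for 256x256 patches)
    gen_depth: int = 4
    gen_width: int = 64
    critic_layers: int = 4
    critic_width: int = 64
    classifier_width: int = 8
    classifier_lr: float = 2e-3
    classifier_batch: int = 16
    dtype: str = "float64"  # "float32" halves the memory-bound conv cost

    def __post_init__(self):
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)
        if min(self.steps_classifier, self.steps_gan, self.batch_size,
               self.critic_updates_per_gen) < 1:
            raise ValueError("all step/batch counts must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        div = 2 ** self.gen_depth
        if self.image_size % div:
            raise ValueError(f"image_size {self.image_size} not divisible by 2^depth={div}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["optimizer_betas"] = list(self.optimizer_betas)
        return d

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        """Shapes sized for 64x64 fixtures on a single CPU core."""
        base = dict(image_size=64, gen_depth=2, gen_width=8, critic_layers=3,
                    critic_width=8, classifier_width=4, steps_classifier=200,
                    steps_gan=600, batch_size=4, snapshot_every=0,
                    dtype="float32")
        base.update(overrides)
        return cls(**base)


class TrainingState:
    """All mutable training artifacts: models, optimizers, RNG, history."""

    def __init__(self, cfg: TrainingConfig, c_color: ColorClassifier):
        if not c_color.frozen:
            raise RuntimeError("the color classifier must be pretrained and frozen "
                               "before adversarial training starts")
        self.cfg = cfg
        seed = cfg.seed
        self.g_a2b = UNetGenerator(cfg.gen_depth, cfg.gen_width, seed=seed + 1,
                                   identifier="G_A2B")
        self.g_b2a = UNetGenerator(cfg.gen_depth, cfg.gen_width, seed=seed + 2,
                                   identifier="G_B2A")
        self.d_a = PatchCritic(cfg.critic_layers, cfg.critic_width, seed=seed + 3,
                               identifier="D_A")
        self.d_b = PatchCritic(cfg.critic_layers, cfg.critic_width, seed=seed + 4,
                               identifier="D_B")
        self.c_color = c_color
        self.np_dtype = np.float32 if cfg.dtype == "float32" else np.float64
        if cfg.dtype == "float32":
            for model in (self.g_a2b, self.g_b2a, self.d_a, self.d_b, self.c_color):
                for p in model.parameters():
                    p.data = p.data.astype(np.float32)
        gen_params = self.g_a2b.parameters() + self.g_b2a.parameters()
        self.opt_g = nn.Adam(gen_params, lr=cfg.lr, betas=cfg.optimizer_betas)
        self.opt_da = nn.Adam(self.d_a.parameters(), lr=cfg.lr, betas=cfg.optimizer_betas)
        self.opt_db = nn.Adam(self.d_b.parameters(), lr=cfg.lr, betas=cfg.optimizer_betas)
        self.rng = np.random.default_rng(seed + 1000)
        self.step = 0
        self.history: list[LossReport] = []

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "step": self.step,
            "cfg": self.cfg.as_dict(),
            "rng_state": self.rng.bit_generator.state,
            "history": [r.as_dict() for r in self.history],
            "classifier_frozen": self.c_color.frozen,
        }
        nn.save_checkpoint(
            path,
            modules={"g_a2b": self.g_a2b, "g_b2a": self.g_b2a,
                     "d_a": self.d_a, "d_b": self.d_b, "c_color": self.c_color},
            meta=meta,
            optimizers={"g": self.opt_g, "d_a": self.opt_da, "d_b": self.opt_db})

    @classmethod
    def load(cls, path) -> "TrainingState":
        mod_states, opt_states, meta = nn.load_checkpoint(path)
        cfg_d = dict(meta["cfg"])
        cfg_d["optimizer_betas"] = tuple(cfg_d["optimizer_betas"])
        cfg = TrainingConfig(**cfg_d)
        clf = ColorClassifier(cfg.classifier_width, seed=0)
        clf.load_state_dict(mod_states["c_color"])
        if meta.get("classifier_frozen", True):
            clf.freeze()
        state = cls(cfg, clf)
        state.g_a2b.load_state_dict(mod_states["g_a2b"])
        state.g_b2a.load_state_dict(mod_states["g_b2a"])
        state.d_a.load_state_dict(mod_states["d_a"])
        state.d_b.load_state_dict(mod_states["d_b"])
        state.opt_g.load_state_dict(opt_states["g"])
        state.opt_da.load_state_dict(opt_states["d_a"])
        state.opt_db.load_state_dict(opt_states["d_b"])
        state.rng = np.random.default_rng()
        state.rng.bit_generator.state = meta["rng_state"]
        state.step = int(meta["step"])
        state.history = [LossReport(**r) for r in meta["history"]]
        return state


# -- Step 1: classifier pretraining -------------------------------------

def pretrain_color_classifier(ds_a: DomainDataset, ds_b: DomainDataset,
                              cfg: TrainingConfig) -> tuple[ColorClassifier, float]:
    """Train the color consultant (domain A = class 0, B = class 1).

    Uses a seeded 10% held-out split for the returned accuracy; the
    classifier comes back frozen. Accuracy below 0.9 only warns — an
    unreliable consultant degrades guidance but is not a hard failure.
    """
    for ds, name in ((ds_a, "A"), (ds_b, "B")):
        if ds.split == Split.CYCLEGAN_TRAIN:
            warnings.warn(f"domain-{name} classifier data carries the adversarial "
                          f"training split; pretraining should use its own split")
    x = np.concatenate([ds_a.as_array(), ds_b.as_array()])
    y = np.concatenate([np.zeros(len(ds_a), dtype=int), np.ones(len(ds_b), dtype=int)])
    rng = np.random.default_rng(cfg.seed + 500)
    perm = rng.permutation(len(x))
    x, y = x[perm], y[perm]
    n_hold = max(1, len(x) // 10)
    x_tr, y_tr, x_ho, y_ho = x[n_hold:], y[n_hold:], x[:n_hold], y[:n_hold]

    clf = ColorClassifier(cfg.classifier_width, seed=cfg.seed + 42)
    opt = nn.Adam(clf.parameters(), lr=cfg.classifier_lr, betas=(0.9, 0.999))
    params = clf.parameters()
    for _ in range(cfg.steps_classifier):
        idx = rng.choice(len(x_tr), size=min(cfg.classifier_batch, len(x_tr)),
                         replace=False)
        logits = clf.logits(Tensor(x_tr[idx]))
        logp = ad.log_softmax(logits, axis=1)
        onehot = np.zeros((len(idx), 2))
        onehot[np.arange(len(idx)), y_tr[idx]] = 1.0
        loss = ad.neg(ad.mean(ad.sum_(ad.mul(logp, Tensor(onehot)), axis=1)))
        grads = ad.grad(loss, params)
        opt.step(grads)

    pred = clf.predict_proba(x_ho).argmax(axis=1)
    accuracy = float((pred == y_ho).mean())
    if accuracy < 0.9:
        warnings.warn(f"color classifier held-out accuracy {accuracy:.3f} < 0.9; "
                      f"the consultant may be unreliable")
    clf.freeze()
    return clf, accuracy


# -- Steps 2-3: adversarial training ------------------------------------

def _draw_batch(ds: DomainDataset, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(len(ds), size=n, replace=n > len(ds))
    return patches_to_batch([ds[int(i)] for i in idx])


def critic_step(state: TrainingState, batch_a: np.ndarray, batch_b: np.ndarray,
                cfg: TrainingConfig | None = None) -> dict:
    """Update D_B on (real B, G_A2B(A)) and D_A on (real A, G_B2A(B))."""
    cfg = cfg or state.cfg
    batch_a = np.asarray(batch_a, dtype=state.np_dtype)
    batch_b = np.asarray(batch_b, dtype=state.np_dtype)
    with ad.no_grad():
        fake_b = state.g_a2b(Tensor(batch_a)).data
        fake_a = state.g_b2a(Tensor(batch_b)).data
    seed_b, seed_a = (int(s) for s in state.rng.integers(0, 2 ** 31 - 1, size=2))

    loss_db = L.critic_loss(state.d_b, batch_b, fake_b, cfg.weights,
                            seed=seed_b, create_graph=True)
    grads = ad.grad(loss_db, state.d_b.parameters())
    state.opt_db.step(grads)

    loss_da = L.critic_loss(state.d_a, batch_a, fake_a, cfg.weights,
                            seed=seed_a, create_graph=True)
    grads = ad.grad(loss_da, state.d_a.parameters())
    state.opt_da.step(grads)
    l_advD = 0.5 * (float(loss_db.data) + float(loss_da.data))
    if not np.isfinite(l_advD):
        raise NonFiniteLossError(
            f"critic loss non-finite at step {state.step}; batch stats: "
            f"A mean {batch_a.mean():.4g} sd {batch_a.std():.4g}, "
            f"B mean {batch_b.mean():.4g} sd {batch_b.std():.4g}")
    return {"l_advD": l_advD}


def generator_step(state: TrainingState, batch_a: np.ndarray, batch_b: np.ndarray,
                   cfg: TrainingConfig | None = None,
                   l_advD: float = float("nan")) -> LossReport:
    """Joint update of both generators by the weighted three-loss objective."""
    cfg = cfg or state.cfg
    w = cfg.weights

    batch_a = np.asarray(batch_a, dtype=state.np_dtype)
    batch_b = np.asarray(batch_b, dtype=state.np_dtype)
    a, b = Tensor(batch_a), Tensor(batch_b)
    fake_b = state.g_a2b(a)
    rec_a = state.g_b2a(fake_b)
    fake_a = state.g_b2a(b)
    rec_b = state.g_a2b(fake_a)

    adv_ab = L.generator_adversarial_loss(state.d_b, fake_b, mode=cfg.adv_mode)
    adv_ba = L.generator_adversarial_loss(state.d_a, fake_a, mode=cfg.adv_mode)
    cyc_ab = L.cycle_loss(a, rec_a)
    cyc_ba = L.cycle_loss(b, rec_b)
    col_ab = L.color_loss(state.c_color, fake_b, Domain.B)
    col_ba = L.color_loss(state.c_color, fake_a, Domain.A)

    l_adv = 0.5 * (float(adv_ab.data) + float(adv_ba.data))
    l_cyc = 0.5 * (float(cyc_ab.data) + float(cyc_ba.data))
    l_color = 0.5 * (float(col_ab.data) + float(col_ba.data))

    obj_ab = L.generator_objective(adv_ab, cyc_ab, col_ab, w)
    obj_ba = L.generator_objective(adv_ba, cyc_ba, col_ba, w)
    total = ad.add(obj_ab, obj_ba)
    grads = ad.grad(total, state.opt_g.params)
    state.opt_g.step(grads)

    report = LossReport(l_advD=l_advD, l_adv=l_adv, l_cyc=l_cyc, l_color=l_color,
                        l_obj=l_adv + w.alpha * l_cyc + w.beta * l_color,
                        step=state.step)
    if not np.isfinite(report.l_obj):
        raise NonFiniteLossError(
            f"generator objective non-finite at step {state.step}; batch stats: "
            f"A mean {batch_a.mean():.4g}, B mean {batch_b.mean():.4g}")
    return report


def train(ds_a: DomainDataset, ds_b: DomainDataset, cfg: TrainingConfig,
          c_color: ColorClassifier | None = None,
          pre_a: DomainDataset | None = None, pre_b: DomainDataset | None = None,
          out_dir=None, state: TrainingState | None = None,
          snapshot_sources: np.ndarray | None = None) -> TrainingState:
    """Run the full protocol (or continue a loaded ``state``).

    Each iteration performs ``critic_updates_per_gen`` critic updates
    followed by one generator update, appending exactly one
    :class:`LossReport` per generator step. With ``out_dir`` set,
    checkpoints and source/transfer snapshot grids are written every
    ``snapshot_every`` steps.
    """
    if state is None:
        if c_color is None:
            if pre_a is None or pre_b is None:
                raise ValueError("either a frozen classifier or pretraining "
                                 "datasets must be supplied")
            c_color, _ = pretrain_color_classifier(pre_a, pre_b, cfg)
        state = TrainingState(cfg, c_color)
    cfg = state.cfg
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    frozen_checksum = state.c_color.checksum()
    log_fh = open(out_dir / "loss_log.jsonl", "a") if out_dir is not None else None
    try:
        while state.step < cfg.steps_gan:
            batch_a = _draw_batch(ds_a, cfg.batch_size, state.rng)
            batch_b = _draw_batch(ds_b, cfg.batch_size, state.rng)
            l_advD = float("nan")
            for _ in range(cfg.critic_updates_per_gen):
                l_advD = critic_step(state, batch_a, batch_b, cfg)["l_advD"]
            report = generator_step(state, batch_a, batch_b, cfg, l_advD=l_advD)
            state.step += 1
            report.step = state.step
            state.history.append(report)
            if log_fh is not None:
                log_fh.write(json.dumps(report.as_dict()) + "\n")
            if (out_dir is not None and cfg.snapshot_every
                    and state.step % cfg.snapshot_every == 0):
                state.save(out_dir / "checkpoint.npz")
                if snapshot_sources is not None:
                    _write_snapshot(state, snapshot_sources,
                                    out_dir / f"step_{state.step}.png")
    except NonFiniteLossError:
        if out_dir is not None:
            # last good checkpoint is retained; do not overwrite it
            pass
        raise
    finally:
        if log_fh is not None:
            log_fh.close()

    if state.c_color.checksum() != frozen_checksum:
        raise RuntimeError("frozen color classifier changed during training")
    if out_dir is not None:
        state.save(out_dir / "checkpoint.npz")
    return state


def _write_snapshot(state: TrainingState, sources: np.ndarray, path) -> None:
    """Grid: top row source patches, bottom row their A->B transfers."""
    with ad.no_grad():
        transferred = state.g_a2b(Tensor(sources)).data
    rows = [np.concatenate(list(batch.transpose(0, 2, 3, 1)), axis=1)
            for batch in (sources, transferred)]
    grid = np.concatenate(rows, axis=0)
    patch = batch_to_patches(np.clip(grid, -1, 1).transpose(2, 0, 1)[None])[0]
    write_patch(path, patch)


def cycle_slope(history: list[LossReport], window: int = 50) -> float:
    """Moving-average slope of the cycle loss — the stability readout
    used in place of an automatic stopping rule."""
    vals = np.array([r.l_cyc for r in history[-window:]])
    if len(vals) < 2:
        return float("nan")
    t = np.arange(len(vals), dtype=float)
    return float(np.polyfit(t, vals, 1)[0])
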