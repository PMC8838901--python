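"""Layers, parameter containers, the Adam optimizer and checkpoint I/O.

Built on :mod:`s3cgan.autodiff`. Deliberately minimal: only what the
U-Net generators, the patch critics and the color classifier need.
Initialization follows the DCGAN convention (weights ~ N(0, 0.02),
biases zero) and is fully determined by the generator passed in, so
identical seeds give bit-identical parameters.
"""

from __future__ import annotations

import hashlib
import io
import json
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

INIT_STD = 0.02


class Module:
    """Base class: tracks parameters and sub-modules by attribute name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def checksum(self) -> str:
        """SHA-256 over all parameter bytes, in declaration order."""
        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch; differing keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.dtype not in (np.float32, np.float64):
                arr = arr.astype(np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.pad = pad
        self.weight = Tensor(rng.normal(0.0, INIT_STD, size=(out_ch, in_ch, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = ad.conv2d(x, self.weight, stride=self.stride, pad=self.pad)
        return ad.add(y, ad.reshape(self.bias, (1, -1, 1, 1)))


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(rng.normal(0.0, INIT_STD, size=(in_f, out_f)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_f), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), ad.reshape(self.bias, (1, -1)))


class Adam:
    """Adam with CycleGAN's customary momentum pair (0.5, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list length does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [a.copy() for a in self.m],
                "v": [a.copy() for a in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        # dtypes preserved: resuming must replay the exact arithmetic
        self.m = [np.asarray(a).copy() for a in state["m"]]
        self.v = [np.asarray(a).copy() for a in state["v"]]


def save_checkpoint(path, modules: dict[str, Module], meta: dict,
                    optimizers: dict[str, Adam] | None = None) -> None:
    """Single-file .npz container: weights, optimizer state, JSON metadata."""
    arrays: dict[str, np.ndarray] = {}
    for mod_name, mod in modules.items():
        for p_name, p in mod.named_parameters():
            arrays[f"param/{mod_name}/{p_name}"] = p.data
    if optimizers:
        for opt_name, opt in optimizers.items():
            arrays[f"opt/{opt_name}/t"] = np.array(opt.t)
            for i, (m, v) in enumerate(zip(opt.m, opt.v)):
                arrays[f"opt/{opt_name}/m{i}"] = m
                arrays[f"opt/{opt_name}/v{i}"] = v
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[dict[str, dict[str, np.ndarray]], dict, dict]:
    """Returns (module states, optimizer states, metadata)."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("meta_json")).decode())
    mod_states: dict[str, dict[str, np.ndarray]] = {}
    opt_states: dict[str, dict] = {}
    for key, arr in arrays.items():
        kind, name, rest = key.split("/", 2)
        if kind == "param":
            mod_states.setdefault(name, {})[rest] = arr
        else:
            entry = opt_states.setdefault(name, {"m": {}, "v": {}})
            if rest == "t":
                entry["t"] = int(arr)
            elif rest.startswith("m"):
                entry["m"][int(rest[1:])] = arr
            else:
                entry["v"][int(rest[1:])] = arr
    for entry in opt_states.values():
        entry["m"] = [entry["m"][i] for i in sorted(entry["m"])]
        entry["v"] = [entry["v"][i] for i in sorted(entry["v"])]
    return mod_states, opt_states, meta
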