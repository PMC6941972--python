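"""Neural-network building blocks (numpy + gexmol.autodiff).

Dense / batch-norm / dropout layers, a GRU cell, and an RMSprop optimizer —
the complete set of primitives the translator and the GAN networks need.
Modules hold :class:`~gexmol.autodiff.Tensor` parameters; ``parameters()``
and ``state_dict()`` walk attributes recursively, so composite networks
serialize to flat name → array dictionaries.
"""

from __future__ import annotations

import json

import numpy as np

from gexmol.autodiff import Tensor, concat, no_grad
from gexmol.exceptions import ShapeError

__all__ = [
    "Module",
    "Dense",
    "BatchNorm",
    "Dropout",
    "GRUCell",
    "MLP",
    "RMSprop",
    "glorot_uniform",
    "save_archive",
    "load_archive",
]


def glorot_uniform(rng: np.random.Generator, nin: int, nout: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (nin + nout))
    return rng.uniform(-limit, limit, size=(nin, nout))


class Module:
    """Base class with recursive parameter / state traversal."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, (Tensor, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, (Tensor, Module)):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        out = []
        for _, child in self._children():
            if isinstance(child, Tensor):
                if child.requires_grad:
                    out.append(child)
            else:
                out.extend(child.parameters())
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, child in self._children():
            key = f"{prefix}{name}"
            if isinstance(child, Tensor):
                state[key] = child.data.copy()
            else:
                state.update(child.state_dict(prefix=f"{key}."))
        for name, arr in getattr(self, "_buffers", {}).items():
            state[f"{prefix}{name}"] = np.asarray(arr).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, child in self._children():
            key = f"{prefix}{name}"
            if isinstance(child, Tensor):
                if key not in state:
                    raise KeyError(f"missing parameter {key!r}")
                if child.data.shape != state[key].shape:
                    raise ShapeError(
                        f"{key}: expected {child.data.shape}, got {state[key].shape}"
                    )
                child.data = np.asarray(state[key], dtype=np.float64).copy()
            else:
                child.load_state_dict(state, prefix=f"{key}.")
        for name in getattr(self, "_buffers", {}):
            key = f"{prefix}{name}"
            if key in state:
                self._buffers[name] = np.asarray(state[key]).copy()


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.weight = Tensor(glorot_uniform(rng, nin, nout), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[-1] != self.weight.data.shape[0]:
            raise ShapeError(
                f"Dense expects input width {self.weight.data.shape[0]}, "
                f"got {x.data.shape[-1]}"
            )
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization: batch statistics in training, running averages at inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self._buffers = {"running_mean": np.zeros(dim), "running_var": np.ones(dim)}

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                m * self._buffers["running_mean"] + (1 - m) * mu.data.ravel()
            )
            self._buffers["running_var"] = (
                m * self._buffers["running_var"] + (1 - m) * var.data.ravel()
            )
            xhat = centered * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self._buffers["running_mean"])
            sd = Tensor(np.sqrt(self._buffers["running_var"] + self.eps))
            xhat = (x - mu) * sd ** -1.0
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator | None = None) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep).astype(np.float64) / keep
        return x * Tensor(mask)


class GRUCell(Module):
    """Single gated recurrent unit cell."""

    def __init__(self, nin: int, nh: int, rng: np.random.Generator):
        def w(a, b):
            return Tensor(glorot_uniform(rng, a, b), requires_grad=True)

        self.w_z, self.u_z, self.b_z = w(nin, nh), w(nh, nh), Tensor(np.zeros(nh), requires_grad=True)
        self.w_r, self.u_r, self.b_r = w(nin, nh), w(nh, nh), Tensor(np.zeros(nh), requires_grad=True)
        self.w_h, self.u_h, self.b_h = w(nin, nh), w(nh, nh), Tensor(np.zeros(nh), requires_grad=True)
        self.nh = nh

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.w_z + h @ self.u_z + self.b_z).sigmoid()
        r = (x @ self.w_r + h @ self.u_r + self.b_r).sigmoid()
        h_cand = (x @ self.w_h + (r * h) @ self.u_h + self.b_h).tanh()
        return (1.0 - z) * h + z * h_cand


class MLP(Module):
    """Stack of Dense layers with LeakyReLU and optional batch-norm per layer."""

    def __init__(
        self,
        nin: int,
        widths: list[int],
        rng: np.random.Generator,
        leaky_slope: float = 0.2,
        batch_norm: bool = False,
    ):
        self.layers = [Dense(a, b, rng) for a, b in zip([nin] + list(widths[:-1]), widths)]
        self.norms = [BatchNorm(w) for w in widths] if batch_norm else []
        self.slope = leaky_slope

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x).leaky_relu(self.slope)
            if self.norms:
                x = self.norms[i](x, training)
        return x


class RMSprop:
    """RMSprop with the usual ρ=0.9, ε=1e-7 accumulator defaults."""

    def __init__(self, params: list[Tensor], lr: float = 5e-5, rho: float = 0.9, eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._acc = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        with no_grad():
            for p, g, s in zip(self.params, grads, self._acc):
                gd = g.data
                s *= self.rho
                s += (1.0 - self.rho) * gd * gd
                p.data = p.data - self.lr * gd / (np.sqrt(s) + self.eps)


# ---------------------------------------------------------------------------
# single-file archives: npz holding arrays + a JSON config blob


def save_archive(path, config: dict, state: dict[str, np.ndarray]) -> None:
    arrays = {f"state/{k}": v for k, v in state.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(config, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_archive(path) -> tuple[dict, dict[str, np.ndarray]]:
    with np.load(path) as npz:
        config = json.loads(bytes(npz["__config__"].tobytes()).decode())
        state = {
            k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")
        }
    return config, state
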