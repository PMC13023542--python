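"""Neural-network layers built on the autodiff Tensor.

Each ``Module`` tracks its parameters and submodules by attribute name, can
be switched between train/eval modes, and carries a ``trainable`` flag used
for transfer-learning layer freezing.  Normalization layers additionally
support freezing of their running statistics.
"""

from __future__ import annotations

import numpy as np

from apneaseg.nn.tensor import Tensor


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)
        object.__setattr__(self, "trainable", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_parameters(self, prefix: str = ""):
        for n, p in self._params.items():
            yield f"{prefix}{n}", p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self):
        """Parameters of modules whose whole ownership chain is trainable."""
        out = []
        if not self.trainable:
            return out
        out.extend(self._params.values())
        for m in self._modules.values():
            out.extend(m.trainable_parameters())
        return out

    def named_buffers(self, prefix: str = ""):
        for n, b in self._buffers.items():
            yield f"{prefix}{n}", b
        for mn, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{mn}.")

    # -- modes ------------------------------------------------------------
    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def set_trainable(self, flag: bool):
        for m in self.modules():
            object.__setattr__(m, "trainable", flag)
            for p in m._params.values():
                p.requires_grad = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.data.copy()
                 for n, p in self.named_parameters()}
        state.update({f"buffer:{n}": np.asarray(b).copy()
                      for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expect = ({f"param:{n}" for n in params}
                  | {f"buffer:{n}" for n in buffers})
        got = set(state)
        if expect != got:
            missing = sorted(expect - got)[:5]
            extra = sorted(got - expect)[:5]
            raise ValueError(
                f"state mismatch: missing {missing}, unexpected {extra}")
        for n, p in params.items():
            arr = state[f"param:{n}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        for n, b in buffers.items():
            np.asarray(b)[...] = state[f"buffer:{n}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.dilation = dilation
        self.weight = Tensor(_he_init(rng, (out_ch, in_ch, kernel),
                                      in_ch * kernel), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_ch), requires_grad=True)
                     if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias,
                        stride=self.stride, dilation=self.dilation)


class Dense(Module):
    """Affine map on the last axis."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (in_dim, out_dim), in_dim),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Per-channel normalization over (N, C, L) batches with running stats.

    When ``stats_frozen`` (or in eval mode) the stored running estimates are
    used even during training -- the BN-freezing regime for fine-tuning.
    """

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.stats_frozen = False
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self._buffers["running_mean"] = np.zeros(n_ch)
        self._buffers["running_var"] = np.ones(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        if self.training and not self.stats_frozen:
            xhat, mu, var = x.normalize(axis=(0, 2), eps=self.eps)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            m = self.momentum
            rm[...] = (1 - m) * rm + m * mu.reshape(-1)
            rv[...] = (1 - m) * rv + m * var.reshape(-1)
            return (xhat * self.gamma.reshape(1, -1, 1)
                    + self.beta.reshape(1, -1, 1))
        # eval / stats-frozen: fold running stats into one affine map
        rm = self._buffers["running_mean"]
        rv = self._buffers["running_var"]
        invstd = 1.0 / np.sqrt(rv + self.eps)
        a = self.gamma.data * invstd
        b = self.beta.data - rm * a
        return x * Tensor(a[None, :, None]) + Tensor(b[None, :, None])


class LayerNorm(Module):
    """Normalization over the last axis (transformer pre-norm)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        xhat, _, _ = x.normalize(axis=x.ndim - 1, eps=self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * Tensor(mask)


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.swish()


class ModuleList(Module):
    def __init__(self, mods: list[Module]):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self.items = mods

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)
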