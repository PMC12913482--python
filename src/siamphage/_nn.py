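"""Neural-network building blocks (layers, parameter containers) on numpy.

Weight initialisation is fully seeded: every layer draws from the
``numpy.random.Generator`` handed to its constructor, so a model built twice
from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv2d

__all__ = [
    "BatchNorm2d",
    "Conv2d",
    "LayerNorm",
    "Linear",
    "Module",
]


class Module:
    """Parameter container with recursive discovery, torch-style."""

    def named_parameters(self, prefix: str = "", _seen: set[int] | None = None):
        if _seen is None:
            _seen = set()
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                if id(value) not in _seen:  # weight sharing: yield once
                    _seen.add(id(value))
                    yield full, value
            elif isinstance(value, Module):
                if id(value) not in _seen:
                    _seen.add(id(value))
                    yield from value.named_parameters(prefix=f"{full}.", _seen=_seen)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module) and id(item) not in _seen:
                        _seen.add(id(item))
                        yield from item.named_parameters(prefix=f"{full}.{i}.",
                                                         _seen=_seen)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self, _seen: set[int] | None = None):
        if _seen is None:
            _seen = set()
        if id(self) in _seen:
            return
        _seen.add(id(self))
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules(_seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules(_seen)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters plus normalisation buffers, for checkpointing."""
        state = {name: p.data for name, p in self.named_parameters()}
        for i, mod in enumerate(m for m in self.modules() if isinstance(m, BatchNorm2d)):
            state[f"__bn{i}.moving_mean"] = mod.moving_mean
            state[f"__bn{i}.moving_var"] = mod.moving_var
            state[f"__bn{i}.num_updates"] = np.asarray(mod.num_updates)
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        for i, mod in enumerate(m for m in self.modules() if isinstance(m, BatchNorm2d)):
            mod.moving_mean = np.asarray(state[f"__bn{i}.moving_mean"],
                                         dtype=mod.moving_mean.dtype)
            mod.moving_var = np.asarray(state[f"__bn{i}.moving_var"],
                                        dtype=mod.moving_var.dtype)
            mod.num_updates = int(state[f"__bn{i}.num_updates"])


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float64):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """Stride-1, 'same'-padded 2-D convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float64):
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale,
                       size=(out_channels, in_channels, kernel, kernel)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


def _norm_forward(x: Tensor, gamma: Tensor, beta: Tensor,
                  norm_axes: tuple[int, ...], param_axes: tuple[int, ...],
                  eps: float, pshape: tuple[int, ...],
                  stats: tuple[np.ndarray, np.ndarray] | None):
    """Shared normalisation core.

    ``stats=None`` normalises with statistics of ``x`` over ``norm_axes``
    (gradient flows through them); otherwise the supplied (mean, var) act as
    constants. ``param_axes`` are the axes summed out for the gamma/beta
    gradients (the axes the parameters broadcast over).
    """
    from_batch = stats is None
    if from_batch:
        mu = x.data.mean(axis=norm_axes, keepdims=True)
        ex2 = np.mean(np.square(x.data), axis=norm_axes, keepdims=True)
        var = np.maximum(ex2 - mu * mu, 0.0)  # one-pass variance
    else:
        mu, var = (s.reshape(pshape) for s in stats)
    inv_std = 1.0 / np.sqrt(var + eps)
    g_r = gamma.data.reshape(pshape)
    # fold normalisation + affine into out = a*x + b (minimal array passes;
    # xhat is re-materialised only if the backward pass runs)
    a = g_r * inv_std
    b = beta.data.reshape(pshape) - a * mu
    out = x.data * a
    out += np.broadcast_to(b, out.shape)

    def backward(g):
        need_xhat = gamma.requires_grad or (x.requires_grad and from_batch)
        xhat = (x.data - mu) * inv_std if need_xhat else None
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=param_axes).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=param_axes).reshape(beta.data.shape))
        if x.requires_grad:
            dxhat = g * g_r
            if from_batch:
                m1 = dxhat.mean(axis=norm_axes, keepdims=True)
                m2 = (dxhat * xhat).mean(axis=norm_axes, keepdims=True)
                x._accumulate(inv_std * (dxhat - m1 - xhat * m2))
            else:
                x._accumulate(dxhat * inv_std)

    out_t = Tensor(out, x.requires_grad or gamma.requires_grad or beta.requires_grad,
                   (x, gamma, beta), backward)
    if from_batch:
        return out_t, mu.reshape(-1), var.reshape(-1)
    return out_t


class BatchNorm2d(Module):
    """Per-channel batch normalisation over (batch, H, W).

    Training accumulates ``moving <- decay*moving + (1-decay)*batch``; because
    the accumulator starts at zero it is biased toward zero for small update
    counts, so evaluation divides by ``1 - decay**n`` (exact debiasing, and
    convergent to the plain moving average as n grows).
    """

    def __init__(self, channels: int, decay: float = 0.999, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.decay = decay
        self.eps = eps
        self.moving_mean = np.zeros(channels, dtype=np.float64)
        self.moving_var = np.zeros(channels, dtype=np.float64)
        self.num_updates = 0

    def set_population(self, mean: np.ndarray, var: np.ndarray) -> None:
        """Install externally estimated population statistics (post-training
        calibration); stored so the debiasing correction is a no-op."""
        self.moving_mean = np.asarray(mean, dtype=np.float64).copy()
        self.moving_var = np.asarray(var, dtype=np.float64).copy()
        self.num_updates = 10 ** 9  # 1 - decay**n == 1 at float precision

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        pshape = (1, -1, 1, 1)
        if training:
            out, mu, var = _norm_forward(x, self.gamma, self.beta, (0, 2, 3),
                                         (0, 2, 3), self.eps, pshape, None)
            d = self.decay
            self.moving_mean = d * self.moving_mean + (1 - d) * mu
            self.moving_var = d * self.moving_var + (1 - d) * var
            self.num_updates += 1
            return out
        if self.num_updates == 0:
            mean = np.zeros_like(self.moving_mean)
            var = np.ones_like(self.moving_var)
        else:
            corr = 1.0 - self.decay ** self.num_updates
            mean = self.moving_mean / corr
            var = self.moving_var / corr
        return _norm_forward(x, self.gamma, self.beta, (0, 2, 3), (0, 2, 3),
                             self.eps, pshape,
                             (mean.astype(x.dtype), var.astype(x.dtype)))


class LayerNorm(Module):
    """Normalisation over the last axis with learnable gain/bias."""

    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float64):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        pshape = (1,) * (x.ndim - 1) + (-1,)
        out, _, _ = _norm_forward(x, self.gamma, self.beta, (x.ndim - 1,),
                                  tuple(range(x.ndim - 1)), self.eps, pshape, None)
        return out
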