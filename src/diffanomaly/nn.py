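"""Minimal dense-network machinery with explicit backpropagation.

The anomaly model needs three small networks (generator, critic, encoder)
trained with non-standard objectives (Wasserstein critic, izif encoder loss
backpropagated through frozen networks). This module provides just enough:
dense layers, a few activations, a ``Sequential`` container whose ``backward``
both accumulates parameter gradients and returns the gradient with respect to
the input (so a frozen network can be used as a differentiable function), and
an Adam optimizer. Everything is float64 numpy and fully deterministic given
the seeding of the weight-initialisation RNG.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "LeakyReLU",
    "Tanh",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: a differentiable map with optional parameters."""

    params: list  # list of numpy arrays, updated in place
    grads: list   # matching gradient accumulators

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0


class Dense(Layer):
    """Affine layer ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ g
        self.grads[1] += g.sum(axis=0)
        return g @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.alpha * g)


class Tanh(Layer):
    def __init__(self):
        super().__init__()
        self._y: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * (1.0 - self._y**2)


class Sequential:
    """Layer stack. ``backward`` returns dL/dinput and accumulates dL/dparams.

    ``forward`` caches activations layer by layer, so a full
    forward-then-backward pair must not be interleaved with another forward of
    the same network.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def forward_upto(self, x: np.ndarray, n_layers: int) -> np.ndarray:
        """Forward through the first ``n_layers`` layers only (with caching)."""
        for layer in self.layers[:n_layers]:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray, from_layer: int | None = None) -> np.ndarray:
        """Backpropagate from the output of layer ``from_layer - 1``.

        ``from_layer=None`` starts at the final output. Returns the gradient
        with respect to the network input.
        """
        layers = self.layers if from_layer is None else self.layers[:from_layer]
        for layer in reversed(layers):
            g = layer.backward(g)
        return g

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def clip_params(self, c: float) -> None:
        for p in self.params:
            np.clip(p, -c, c, out=p)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.copy() for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, network has {len(params)}"
            )
        for i, p in enumerate(params):
            src = np.asarray(state[f"p{i}"])
            if src.shape != p.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p[...] = src


class Adam:
    """Adam on a fixed list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.0,
        beta2: float = 0.9,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
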