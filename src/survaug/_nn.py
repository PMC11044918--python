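"""Feed-forward building blocks and the Adam optimizer on the autodiff tape."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, matmul, relu, sigmoid

__all__ = ["Linear", "MLP", "Adam"]


class Linear:
    """Affine layer with He-style initialisation (ReLU trunk default)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 gain: float | None = None):
        scale = (gain if gain is not None else np.sqrt(2.0)) / np.sqrt(d_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.data + self.b.data

    def parameters(self):
        return [self.W, self.b]


_ACTS = {
    "linear": (lambda t: t, lambda a: a),
    "relu": (relu, lambda a: np.maximum(a, 0.0)),
    "sigmoid": (sigmoid, lambda a: 1.0 / (1.0 + np.exp(-np.clip(a, -500, 500)))),
}


class MLP:
    """Stack of Linear+ReLU layers with a configurable final activation."""

    def __init__(self, widths: list[int], rng: np.random.Generator,
                 final_activation: str = "linear"):
        if len(widths) < 2:
            raise ValueError("MLP needs at least an input and an output width")
        if final_activation not in _ACTS:
            raise ValueError(f"unknown activation {final_activation!r}")
        self.widths = list(widths)
        self.final_activation = final_activation
        self.layers = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            last = i == len(widths) - 2
            gain = 1.0 if (last and final_activation != "relu") else None
            self.layers.append(Linear(a, b, rng, gain=gain))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = relu(layer(x))
        return _ACTS[self.final_activation][0](self.layers[-1](x))

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Inference pass outside the tape (frozen / evaluation use)."""
        for layer in self.layers[:-1]:
            x = np.maximum(layer.forward_np(x), 0.0)
        return _ACTS[self.final_activation][1](self.layers[-1].forward_np(x))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = s.copy()


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
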