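"""Minimal fully-connected encoder networks with analytic backpropagation.

The encoders are small (three dense layers, ELU after the first two, dropout
P=0.2 during training), so they are implemented directly on numpy with
hand-derived gradients and a standard Adam optimizer.  Gradients are
verified against central finite differences in the test suite.  All
randomness (initialization, dropout masks) flows through a
``numpy.random.Generator``, making training bit-reproducible from a seed in
single-threaded use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def elu(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    neg = a < 0
    out[neg] = np.expm1(a[neg])
    return out


def elu_grad(a: np.ndarray) -> np.ndarray:
    g = np.ones_like(a)
    neg = a < 0
    g[neg] = np.exp(a[neg])
    return g


@dataclass
class EncoderSpec:
    """Architecture of one modality's encoder.

    ``layer_dims`` are the output sizes of the three (or more) dense layers;
    ELU + dropout follow every layer except the last.
    """

    modality: str
    input_dim: int
    layer_dims: list[int] = field(default_factory=lambda: [1024, 512, 256])
    dropout_p: float = 0.2

    @property
    def output_dim(self) -> int:
        return self.layer_dims[-1]


#: Default architectures per modality; protein panels are narrow, hence the
#: wide 2048 middle layer to re-expand them.
DEFAULT_LAYER_DIMS = {
    "RNA": [1024, 512, 256],
    "ATAC": [1024, 512, 256],
    "HistoneMark": [1024, 512, 256],
    "Protein": [512, 2048, 256],
}


def default_encoder_spec(modality: str, input_dim: int) -> EncoderSpec:
    dims = DEFAULT_LAYER_DIMS.get(modality, [1024, 512, 256])
    return EncoderSpec(modality=modality, input_dim=input_dim, layer_dims=list(dims))


class MLPEncoder:
    """Dense MLP: linear -> (ELU -> dropout) x (L-1) -> linear output.

    Uniform fan-in initialization: W, b ~ U(-1/sqrt(fan_in), 1/sqrt(fan_in)).
    """

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        fan_in = spec.input_dim
        for dim in spec.layer_dims:
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, dim)))
            self.b.append(rng.uniform(-bound, bound, size=dim))
            fan_in = dim

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """Return (output, cache); cache is needed only for backward()."""
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"encoder {self.spec.modality!r} expects input dim {self.spec.input_dim}, "
                f"got {X.shape[1]}"
            )
        p = self.spec.dropout_p
        hs = [X]  # layer inputs
        pre = []  # pre-activations
        masks = []
        h = X
        for li in range(self.n_layers):
            a = h @ self.W[li] + self.b[li]
            pre.append(a)
            if li < self.n_layers - 1:
                h = elu(a)
                if train and p > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    mask = (rng.random(h.shape) >= p) / (1.0 - p)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                hs.append(h)
            else:
                h = a
        return h, (hs, pre, masks)

    def backward(self, cache, dOut: np.ndarray) -> list[np.ndarray]:
        """Gradients of a scalar loss w.r.t. parameters, given dL/d(output).

        Returns a flat list matching :meth:`parameters` order.
        """
        hs, pre, masks = cache
        dW = [np.empty(0)] * self.n_layers
        db = [np.empty(0)] * self.n_layers
        delta = dOut
        for li in range(self.n_layers - 1, -1, -1):
            dW[li] = hs[li].T @ delta
            db[li] = delta.sum(axis=0)
            if li > 0:
                dh = delta @ self.W[li].T
                mask = masks[li - 1]
                if mask is not None:
                    dh = dh * mask
                delta = dh * elu_grad(pre[li - 1])
        return [*dW, *db]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Inference pass: dropout disabled, deterministic."""
        out, _ = self.forward(X, train=False)
        return out


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
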