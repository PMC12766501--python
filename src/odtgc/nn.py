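"""Neural building blocks for the temporal graph clustering network.

Layers are thin parameter containers over the autodiff core: dense layers,
an LSTM cell, a multi-head graph attention layer with LeakyReLU scoring, a
conditional variational encoder/decoder pair, and the adaptive attention
unit that fuses the structural (graph) and semantic (variational) pathways.
Weights use Glorot initialization from a caller-supplied generator so a
fixed seed reproduces training exactly.
"""

from __future__ import annotations

import numpy as np

from odtgc.autodiff import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "LSTMCell",
    "GATLayer",
    "CVAE",
    "AttentionFusion",
    "Adam",
    "clip_gradients",
]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Minimal parameter container with named state for checkpointing."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor) and attr.requires_grad:
                out[key] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(f"{key}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=float).reshape(p.shape)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Two-layer perceptron with tanh hidden activation."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


class LSTMCell(Module):
    """Standard LSTM cell; gate order (input, forget, cell, output)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.d_hidden = d_hidden
        self.W = glorot(rng, d_in + d_hidden, 4 * d_hidden)
        self.b = Tensor(np.zeros(4 * d_hidden), requires_grad=True)

    def __call__(
        self, x: Tensor, h: Tensor, c: Tensor
    ) -> tuple[Tensor, Tensor]:
        z = concat([x, h], axis=-1) @ self.W + self.b
        dh = self.d_hidden
        i = z[..., 0 * dh:1 * dh].sigmoid()
        f = z[..., 1 * dh:2 * dh].sigmoid()
        g = z[..., 2 * dh:3 * dh].tanh()
        o = z[..., 3 * dh:4 * dh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class GATLayer(Module):
    """Multi-head graph attention over a fixed small graph.

    Attention scores use the additive LeakyReLU formulation; self-loops are
    added to the adjacency inside the layer.  Head outputs are concatenated;
    hidden layers use tanh, the output layer is linear so the embedding
    scale is free to adapt (the clustering kernel and the inner-product
    adjacency decoder both live on an unbounded scale).
    """

    def __init__(self, d_in: int, d_out: int, n_heads: int,
                 rng: np.random.Generator, leaky_alpha: float = 0.2,
                 activation: str | None = "tanh"):
        if d_out % n_heads:
            raise ValueError("d_out must be divisible by n_heads")
        self.n_heads = n_heads
        self.leaky_alpha = leaky_alpha
        self.activation = activation
        d_head = d_out // n_heads
        self.W = [glorot(rng, d_in, d_head) for _ in range(n_heads)]
        self.a_src = [glorot(rng, d_head, 1) for _ in range(n_heads)]
        self.a_dst = [glorot(rng, d_head, 1) for _ in range(n_heads)]

    def attention(self, x: Tensor, adj: np.ndarray) -> list[np.ndarray]:
        """Per-head attention matrices (no grad), for inspection/tests."""
        _, alphas = self._forward(x, adj)
        return [a.data for a in alphas]

    def _forward(self, x: Tensor, adj: np.ndarray):
        mask = adj + np.eye(adj.shape[0])
        neg = (1.0 - (mask > 0)) * -1e9
        outs, alphas = [], []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            h = x @ W                                   # (..., V, d_head)
            s_src = h @ a_s                             # (..., V, 1)
            s_dst = h @ a_d
            e = (s_src + s_dst.swapaxes(-1, -2)).leaky_relu(self.leaky_alpha)
            e = e + Tensor(neg)
            alpha = e.softmax(axis=-1)                  # rows sum to 1 over nbrs
            outs.append(alpha @ h)
            alphas.append(alpha)
        out = concat(outs, axis=-1)
        if self.activation == "tanh":
            out = out.tanh()
        return out, alphas

    def __call__(self, x: Tensor, adj: np.ndarray) -> Tensor:
        out, _ = self._forward(x, adj)
        return out


class CVAE(Module):
    """Conditional variational autoencoder over node attribute vectors.

    Encoder and decoder are both conditioned on the current outcome
    prediction (appended as an input channel).  The latent is Gaussian with
    a diagonal covariance; sampling uses the reparameterization trick with
    caller-supplied noise so training is seed-deterministic.
    """

    def __init__(self, d_in: int, d_cond: int, d_hidden: int, d_latent: int,
                 rng: np.random.Generator):
        self.d_latent = d_latent
        self.enc = Linear(d_in + d_cond, d_hidden, rng)
        self.enc_mu = Linear(d_hidden, d_latent, rng)
        self.enc_logvar = Linear(d_hidden, d_latent, rng)
        self.dec = MLP(d_latent + d_cond, d_hidden, d_in, rng)

    def encode(self, x: Tensor, cond: Tensor) -> tuple[Tensor, Tensor]:
        hidden = self.enc(concat([x, cond], axis=-1)).tanh()
        mu = self.enc_mu(hidden)
        logvar = self.enc_logvar(hidden).clip(-8.0, 8.0)
        return mu, logvar

    def __call__(
        self, x: Tensor, cond: Tensor, eps: np.ndarray | None = None
    ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Return (latent h, reconstruction, mu, logvar)."""
        mu, logvar = self.encode(x, cond)
        if eps is None:
            h = mu
        else:
            h = mu + (logvar * 0.5).exp() * Tensor(eps)
        xhat = self.dec(concat([h, cond], axis=-1))
        return h, xhat, mu, logvar


class AttentionFusion(Module):
    """Adaptive two-way attention fusing semantic (h) and structural (g) paths.

    Per node, scalar scores are computed for each pathway and softmaxed, and
    the fused embedding is the convex combination ``a_h * h + a_g * g``.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        self.proj = Linear(d, d, rng)
        self.v = glorot(rng, d, 1)

    def __call__(self, h: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        s_h = self.proj(h).tanh() @ self.v          # (..., 1)
        s_g = self.proj(g).tanh() @ self.v
        scores = concat([s_h, s_g], axis=-1)        # (..., 2)
        weights = scores.softmax(axis=-1)
        a_h = weights[..., 0:1]
        a_g = weights[..., 1:2]
        return a_h * h + a_g * g, weights


class Adam:
    """Adam with bias correction (the training loop's adaptive method)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_gradients(params: list[Tensor], max_norm: float = 5.0) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
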