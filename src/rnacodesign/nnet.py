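"""Minimal numpy feed-forward networks with explicit backprop.

The trainable components in this package are small per-node MLPs (a few
thousand parameters), so a compact hand-written forward/backward pair plus
Adam is all that is needed; everything is seeded and bitwise reproducible.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully connected tanh network, linear output layer.

    ``sizes`` lists layer widths including input and output, e.g.
    ``[29, 64, 64, 4]``.  The output layer's weights are scaled by
    ``out_init_scale`` at initialization (0 gives an exactly-zero output
    head, useful for residual parameterizations).
    """

    def __init__(self, sizes, seed: int = 0, out_init_scale: float = 1.0,
                 linear_skip: bool = False):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.weights = []
        self.biases = []
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(1.0 / fan_in)
            if i == len(sizes) - 2:
                scale *= out_init_scale
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        # optional input->output linear path: lets the network represent
        # exact affine maps (e.g. "subtract the input coordinates") that
        # saturating tanh layers approximate poorly
        self.skip = (np.zeros((sizes[0], sizes[-1])) if linear_skip else None)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray):
        """Returns (output, cache); ``x`` is (N, F_in)."""
        activations = [np.asarray(x, dtype=float)]
        h = activations[0]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = z if i == len(self.weights) - 1 else np.tanh(z)
            activations.append(h)
        if self.skip is not None:
            h = h + activations[0] @ self.skip
        return h, activations

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, grad_out: np.ndarray, cache):
        """Backprop ``grad_out`` (N, F_out) through a cached forward pass.

        Returns (param_grads, grad_input) where param_grads is a flat list
        [dW0, db0, dW1, db1, ...].
        """
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        g = np.asarray(grad_out, dtype=float)
        for i in reversed(range(len(self.weights))):
            h_in = cache[i]
            if i != len(self.weights) - 1:
                g = g * (1.0 - cache[i + 1] ** 2)  # through tanh
            grads_w[i] = h_in.T @ g
            grads_b[i] = g.sum(axis=0)
            g = g @ self.weights[i].T
        params = []
        for dw, db in zip(grads_w, grads_b):
            params.extend([dw, db])
        if self.skip is not None:
            g_out = np.asarray(grad_out, dtype=float)
            params.append(cache[0].T @ g_out)
            g = g + g_out @ self.skip.T
        return params, g

    # -- parameter plumbing ------------------------------------------------
    @property
    def parameters(self):
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend([w, b])
        if self.skip is not None:
            out.append(self.skip)
        return out

    def set_parameters(self, params) -> None:
        it = iter(params)
        for i in range(len(self.weights)):
            self.weights[i] = np.array(next(it), dtype=float)
            self.biases[i] = np.array(next(it), dtype=float)
        if self.skip is not None:
            self.skip = np.array(next(it), dtype=float)

    def copy(self) -> "MLP":
        clone = MLP(self.sizes, seed=0, linear_skip=self.skip is not None)
        clone.set_parameters([p.copy() for p in self.parameters])
        return clone


class Adam:
    """Adam over a list of parameter arrays, updated in place."""

    def __init__(self, params, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g ** 2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
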