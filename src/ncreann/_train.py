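"""Numba-compiled inner loop for incremental (per-sample) backpropagation.

One call runs a single epoch of stochastic gradient descent with momentum
over the samples in ``order``, mutating the weight and momentum-buffer
arrays in place, and returns the epoch's summed squared error.  Keeping
only the per-sample loop inside numba leaves the adaptive learning rate,
early stopping and cross-validation logic in plain Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["sgd_epoch", "forward"]


@njit(cache=False, fastmath=True)
def sgd_epoch(X, Y, W1, b1, W2, b2, vW1, vb1, vW2, vb2,
              lr, momentum, order, linear_act):
    """One epoch of per-sample gradient descent with momentum.

    Network: out = W2 @ act(W1 @ x + b1) + b2 with act = tanh (or identity
    when ``linear_act``).  Returns the summed squared error accumulated
    while the weights evolve.
    """
    n_hidden = W1.shape[0]
    n_out = W2.shape[0]
    n_in = W1.shape[1]
    h = np.empty(n_hidden)
    e = np.empty(n_out)
    back = np.empty(n_hidden)
    sse = 0.0
    for idx in range(order.shape[0]):
        n = order[idx]
        x = X[n]
        y = Y[n]
        for k in range(n_hidden):
            acc = b1[k]
            for d in range(n_in):
                acc += W1[k, d] * x[d]
            h[k] = acc if linear_act else np.tanh(acc)
        for j in range(n_out):
            acc = b2[j]
            for k in range(n_hidden):
                acc += W2[j, k] * h[k]
            e[j] = acc - y[j]
            sse += e[j] * e[j]
        for k in range(n_hidden):
            acc = 0.0
            for j in range(n_out):
                acc += W2[j, k] * e[j]
            back[k] = acc if linear_act else acc * (1.0 - h[k] * h[k])
        for j in range(n_out):
            for k in range(n_hidden):
                vW2[j, k] = momentum * vW2[j, k] - lr * e[j] * h[k]
                W2[j, k] += vW2[j, k]
            vb2[j] = momentum * vb2[j] - lr * e[j]
            b2[j] += vb2[j]
        for k in range(n_hidden):
            for d in range(x.shape[0]):
                vW1[k, d] = momentum * vW1[k, d] - lr * back[k] * x[d]
                W1[k, d] += vW1[k, d]
            vb1[k] = momentum * vb1[k] - lr * back[k]
            b1[k] += vb1[k]
    return sse / (order.shape[0] * n_out)


def forward(X: np.ndarray, W1: np.ndarray, b1: np.ndarray, W2: np.ndarray,
            b2: np.ndarray, linear_act: bool) -> np.ndarray:
    """Vectorized forward pass for a batch of lag vectors (rows of X)."""
    a = X @ W1.T + b1
    h = a if linear_act else np.tanh(a)
    return h @ W2.T + b2
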