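"""Numba-compiled inner loop for per-sample (online) network training.

One kernel call performs a full epoch of stochastic updates in the given
visiting order, mutating the weight and momentum matrices in place. The
arithmetic mirrors :func:`cranioclass.network.backprop_update` exactly
(same operation order within each sample); only the summation order of
the dot products differs from BLAS, so cross-checks against the numpy
path compare at ~1e-12 relative tolerance rather than bitwise.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def train_epoch(X, Y, scale, order, w_ih, w_ho, p_ih, p_ho, eta, alpha, lam):
    """Run one epoch of online updates in place.

    scale[i] multiplies sample i's error-gradient term (AdaBoost
    reweighting, N*D(i)); the momentum and weight-decay terms are not
    scaled. Momentum memory p_* is overwritten with the applied deltas.
    """
    M, Q = w_ih.shape
    L = w_ho.shape[1]
    h = np.empty(Q)
    o = np.empty(L)
    dk = np.empty(L)
    dj = np.empty(Q)
    for t in range(order.shape[0]):
        i = order[t]
        s = scale[i]
        for j in range(Q):
            acc = 0.0
            for m in range(M):
                acc += X[i, m] * w_ih[m, j]
            h[j] = 1.0 / (1.0 + np.exp(-acc))
        for k in range(L):
            acc = 0.0
            for j in range(Q):
                acc += h[j] * w_ho[j, k]
            o[k] = 1.0 / (1.0 + np.exp(-acc))
        for k in range(L):
            dk[k] = (Y[i, k] - o[k]) * o[k] * (1.0 - o[k])
        for j in range(Q):
            acc = 0.0
            for k in range(L):
                acc += dk[k] * w_ho[j, k]
            dj[j] = h[j] * (1.0 - h[j]) * acc
        for j in range(Q):
            for k in range(L):
                d = alpha * p_ho[j, k] + eta * s * dk[k] * h[j] - eta * lam * w_ho[j, k]
                p_ho[j, k] = d
                w_ho[j, k] += d
        for m in range(M):
            for j in range(Q):
                d = alpha * p_ih[m, j] + eta * s * dj[j] * X[i, m] - eta * lam * w_ih[m, j]
                p_ih[m, j] = d
                w_ih[m, j] += d


@njit(cache=True)
def epoch_mse(X, Y, w_ih, w_ho):
    """Summed-per-sample squared error averaged over rows (two-layer forward)."""
    n = X.shape[0]
    M, Q = w_ih.shape
    L = w_ho.shape[1]
    total = 0.0
    h = np.empty(Q)
    for i in range(n):
        for j in range(Q):
            acc = 0.0
            for m in range(M):
                acc += X[i, m] * w_ih[m, j]
            h[j] = 1.0 / (1.0 + np.exp(-acc))
        for k in range(L):
            acc = 0.0
            for j in range(Q):
                acc += h[j] * w_ho[j, k]
            ok = 1.0 / (1.0 + np.exp(-acc))
            diff = Y[i, k] - ok
            total += diff * diff
    return total / n
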