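"""Independent numerical oracles used by the test suite.

These deliberately re-derive the dynamics from the published formulae with
a different integration scheme (classical fixed-step RK4), so they share no
code path with the package's adaptive Cash-Karp kernels.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def rk4_trajectory(y0, params, current, n_samples, dt, n_substeps):
    """Fixed-step classical RK4 on the conductance model, constant drive.

    `params` uses the same 22-float layout as the package kernels but the
    right-hand side is written out independently here.
    """
    out = np.empty((n_samples, 4))
    y = y0.copy()
    out[0] = y
    h = dt / n_substeps
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    yt = np.empty(4)

    for s in range(n_samples - 1):
        for _ in range(n_substeps):
            _rhs(y, params, current, k1)
            for i in range(4):
                yt[i] = y[i] + 0.5 * h * k1[i]
            _rhs(yt, params, current, k2)
            for i in range(4):
                yt[i] = y[i] + 0.5 * h * k2[i]
            _rhs(yt, params, current, k3)
            for i in range(4):
                yt[i] = y[i] + h * k3[i]
            _rhs(yt, params, current, k4)
            for i in range(4):
                y[i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        out[s + 1] = y
    return out


@njit(cache=True, inline="always")
def _rhs(y, p, I, out):
    V = y[0]
    out[0] = (
        p[1] * y[1] ** 3 * y[2] * (p[4] - V)
        + p[2] * y[3] ** 4 * (p[5] - V)
        + p[3] * (p[6] - V)
        + I
    ) / p[0]
    for gi in range(3):
        base = 7 + 5 * gi
        inf = 0.5 * (1.0 + np.tanh((V - p[base]) / p[base + 1]))
        tb = np.tanh((V - p[base]) / p[base + 4])
        tau = p[base + 2] + p[base + 3] * (1.0 - tb * tb)
        out[1 + gi] = (inf - y[1 + gi]) / tau


def ridge_normal_equations(states, targets, beta, sigma):
    """Generic regularized normal-equations readout, physical units.

    Standardizes exactly like the package contract (per-column center and
    RMS spread to amplitude sigma, target likewise, raw-sum Gram) but solves
    with an explicit inverse — an independent route to the same estimator.
    """
    X = np.asarray(states, float)
    y = np.asarray(targets, float)
    c = X.mean(axis=0)
    s = np.sqrt(np.mean((X - c) ** 2, axis=0))
    s = np.where(s > 0, s, 1.0)
    yc = y.mean()
    ys = np.sqrt(np.mean((y - yc) ** 2))
    H = sigma * (X - c) / s
    Y = sigma * (y - yc) / ys
    w_std = np.linalg.inv(H.T @ H + beta * np.eye(X.shape[1])) @ (H.T @ Y)
    w = w_std * (ys / sigma) * (sigma / s)
    b = yc - float(w @ c)
    return w, b
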