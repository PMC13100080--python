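"""Numba-compiled hot loops.

Everything in here operates on plain float64 arrays so it can be jitted and
cached.  The public modules (`neuron`, `reservoir`, `hybrid`) wrap these
kernels in typed, documented APIs; do not call the kernels directly unless
you are extending the package.

Parameter vector layout (22 floats), shared by all kernels:

    0:C  1:g_Na  2:g_K  3:g_L  4:E_Na  5:E_K  6:E_L
    7..11  gate m: V_half, dV, tau0, eps_tau, dVt
    12..16 gate h: V_half, dV, tau0, eps_tau, dVt
    17..21 gate n: V_half, dV, tau0, eps_tau, dVt

State vector layout: (V, m, h, n).

Status codes returned by the integrators / loops:
    0 ok, 1 step-size underflow, 2 non-finite state, 3 non-finite feedback.
"""

import numpy as np
from numba import njit

# Cash-Karp embedded Runge-Kutta 4(5) tableau.
B21 = 1.0 / 5.0
B31, B32 = 3.0 / 40.0, 9.0 / 40.0
B41, B42, B43 = 3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0
B51, B52, B53, B54 = -11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0
B61, B62, B63, B64, B65 = (
    1631.0 / 55296.0,
    175.0 / 512.0,
    575.0 / 13824.0,
    44275.0 / 110592.0,
    253.0 / 4096.0,
)
# 5th-order solution weights.
C1, C3, C4, C6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
# Difference to the embedded 4th-order weights (error estimate).
E1 = C1 - 2825.0 / 27648.0
E3 = C3 - 18575.0 / 48384.0
E4 = C4 - 13525.0 / 55296.0
E5 = -277.0 / 14336.0
E6 = C6 - 1.0 / 4.0

SAFETY = 0.9
GROW_EXP = -0.2
SHRINK_EXP = -0.25
MAX_GROW = 5.0
MAX_SHRINK = 0.1


@njit(cache=True, inline="always")
def _rhs(V, m, h, n, p, I, out):
    out[0] = (
        p[1] * m * m * m * h * (p[4] - V)
        + p[2] * n * n * n * n * (p[5] - V)
        + p[3] * (p[6] - V)
        + I
    ) / p[0]
    # gate m
    th = np.tanh((V - p[7]) / p[8])
    tb = np.tanh((V - p[7]) / p[11])
    out[1] = (0.5 * (1.0 + th) - m) / (p[9] + p[10] * (1.0 - tb * tb))
    # gate h
    th = np.tanh((V - p[12]) / p[13])
    tb = np.tanh((V - p[12]) / p[16])
    out[2] = (0.5 * (1.0 + th) - h) / (p[14] + p[15] * (1.0 - tb * tb))
    # gate n
    th = np.tanh((V - p[17]) / p[18])
    tb = np.tanh((V - p[17]) / p[21])
    out[3] = (0.5 * (1.0 + th) - n) / (p[19] + p[20] * (1.0 - tb * tb))


@njit(cache=True)
def hh_derivative(y, p, I):
    """Time derivative of (V, m, h, n) under constant drive I."""
    out = np.empty(4)
    _rhs(y[0], y[1], y[2], y[3], p, I, out)
    return out


@njit(cache=True)
def _advance(y, p, I, T, rtol, atol, hmin):
    """Advance state `y` in place over duration T (constant I), adaptively.

    Cash-Karp 4(5) pair with step-doubling style error control: accept when
    the weighted error norm <= 1, step scaled by SAFETY*err^exp.  Gates are
    clamped to [0, 1] after every accepted step.  Returns a status code.
    """
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    yt = np.empty(4)
    y5 = np.empty(4)
    t = 0.0
    h = T
    while t < T * (1.0 - 1e-14):
        if h > T - t:
            h = T - t
        _rhs(y[0], y[1], y[2], y[3], p, I, k1)
        for i in range(4):
            yt[i] = y[i] + h * B21 * k1[i]
        _rhs(yt[0], yt[1], yt[2], yt[3], p, I, k2)
        for i in range(4):
            yt[i] = y[i] + h * (B31 * k1[i] + B32 * k2[i])
        _rhs(yt[0], yt[1], yt[2], yt[3], p, I, k3)
        for i in range(4):
            yt[i] = y[i] + h * (B41 * k1[i] + B42 * k2[i] + B43 * k3[i])
        _rhs(yt[0], yt[1], yt[2], yt[3], p, I, k4)
        for i in range(4):
            yt[i] = y[i] + h * (
                B51 * k1[i] + B52 * k2[i] + B53 * k3[i] + B54 * k4[i]
            )
        _rhs(yt[0], yt[1], yt[2], yt[3], p, I, k5)
        for i in range(4):
            yt[i] = y[i] + h * (
                B61 * k1[i]
                + B62 * k2[i]
                + B63 * k3[i]
                + B64 * k4[i]
                + B65 * k5[i]
            )
        _rhs(yt[0], yt[1], yt[2], yt[3], p, I, k6)

        errnorm = 0.0
        for i in range(4):
            y5[i] = y[i] + h * (C1 * k1[i] + C3 * k3[i] + C4 * k4[i] + C6 * k6[i])
            erri = h * (
                E1 * k1[i] + E3 * k3[i] + E4 * k4[i] + E5 * k5[i] + E6 * k6[i]
            )
            ay = abs(y[i])
            ay5 = abs(y5[i])
            scale = atol + rtol * (ay if ay > ay5 else ay5)
            w = abs(erri) / scale
            if w > errnorm:
                errnorm = w
        if not np.isfinite(errnorm):
            return 2
        if errnorm <= 1.0:
            t += h
            y[0] = y5[0]
            for i in range(1, 4):
                v = y5[i]
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                y[i] = v
            if errnorm == 0.0:
                h *= MAX_GROW
            else:
                fac = SAFETY * errnorm**GROW_EXP
                if fac > MAX_GROW:
                    fac = MAX_GROW
                h *= fac
            if h > T - t:
                h = T - t
        else:
            fac = SAFETY * errnorm**SHRINK_EXP
            if fac < MAX_SHRINK:
                fac = MAX_SHRINK
            h *= fac
            if h < hmin:
                return 1
    if not (
        np.isfinite(y[0])
        and np.isfinite(y[1])
        and np.isfinite(y[2])
        and np.isfinite(y[3])
    ):
        return 2
    return 0


@njit(cache=True)
def integrate_grid(y0, p, I, dt, rtol, atol, hmin):
    """Integrate over a uniformly sampled current trace (zero-order hold).

    Returns (out, status, n_done): `out[k]` is the state at sample k,
    `out[0] = y0`; sample k -> k+1 uses the held current I[k].
    """
    n = I.shape[0]
    m = n if n > 0 else 1
    out = np.empty((m, 4))
    y = y0.copy()
    out[0] = y
    for k in range(n - 1):
        st = _advance(y, p, I[k], dt, rtol, atol, hmin)
        if st != 0:
            return out, st, k + 1
        out[k + 1] = y
    return out, 0, m


@njit(cache=True)
def run_teacher(
    indptr,
    indices,
    data,
    chan,
    sI,
    sV,
    Iraw,
    Vraw,
    p,
    x0,
    dt,
    rtol,
    atol,
    hmin,
    n_in_model,
    sigma,
    v_center,
    v_spread,
    scale_model,
    use_model,
):
    """Teacher-forced pass over the training window.

    Per step t: (i) if a surrogate model is embedded, overwrite its voltage
    with the reference V(t), integrate one sample interval under I(t);
    (ii) assemble the input vector (channel order: I, V, model V, m, h, n);
    (iii) tanh reservoir update.  Records the reservoir state and the model
    state aligned with target V(t+dt).

    Returns (states, xout, r, x, status).
    """
    N = sI.shape[0]
    NR = chan.shape[0]
    states = np.zeros((N - 1, NR))
    xout = np.zeros((N - 1, 4))
    r = np.zeros(NR)
    rn = np.zeros(NR)
    x = x0.copy()
    vin = np.zeros(6)
    status = 0
    for t in range(N - 1):
        if use_model:
            x[0] = Vraw[t]
            st = _advance(x, p, Iraw[t], dt, rtol, atol, hmin)
            if st != 0:
                status = st
                break
        vin[0] = sI[t]
        vin[1] = sV[t]
        if n_in_model >= 1:
            if scale_model:
                vin[2] = sigma * (x[0] - v_center) / v_spread
            else:
                vin[2] = x[0]
        if n_in_model == 4:
            if scale_model:
                vin[3] = sigma * (2.0 * x[1] - 1.0)
                vin[4] = sigma * (2.0 * x[2] - 1.0)
                vin[5] = sigma * (2.0 * x[3] - 1.0)
            else:
                vin[3] = x[1]
                vin[4] = x[2]
                vin[5] = x[3]
        for i in range(NR):
            acc = vin[chan[i]]
            for jj in range(indptr[i], indptr[i + 1]):
                acc += data[jj] * r[indices[jj]]
            rn[i] = np.tanh(acc)
        tmp = r
        r = rn
        rn = tmp
        states[t] = r
        xout[t] = x
    return states, xout, r, x, status


@njit(cache=True)
def run_closed_loop(
    indptr,
    indices,
    data,
    chan,
    sI,
    Iraw,
    r0,
    x0,
    vfb0,
    p,
    dt,
    rtol,
    atol,
    hmin,
    n_in_model,
    n_out_model,
    sigma,
    v_center,
    v_spread,
    scale_model,
    w,
    b,
    v_lo,
    v_hi,
    use_model,
):
    """Closed-loop (autonomous) prediction.

    The previous readout voltage replaces the reference feedback on both the
    reservoir's voltage channel and the embedded model's voltage component.
    The readout estimates a membrane voltage: values escaping [v_lo, v_hi]
    (the training range expanded by a wide margin) are estimator saturation
    and are pinned at the rail, mirroring the railed saturation a driven
    reservoir exhibits rather than letting the loop diverge numerically.
    Never raises: remaining samples stay NaN on integrator failure and a
    non-zero status is returned.

    Returns (vpred, gates, status, n_clipped): vpred[k] is the prediction one
    sample after drive sample Iraw[k]; gates[k] the surrogate's (m, h, n).
    """
    H = Iraw.shape[0]
    NR = chan.shape[0]
    vpred = np.full(H, np.nan)
    gates = np.full((H, 3), np.nan)
    r = r0.copy()
    rn = np.zeros(NR)
    x = x0.copy()
    vin = np.zeros(6)
    vfb = vfb0
    status = 0
    n_clipped = 0
    for t in range(H):
        if not np.isfinite(vfb):
            status = 3
            break
        if use_model:
            x[0] = vfb
            st = _advance(x, p, Iraw[t], dt, rtol, atol, hmin)
            if st != 0:
                status = st
                break
        vin[0] = sI[t]
        vin[1] = sigma * (vfb - v_center) / v_spread
        if n_in_model >= 1:
            if scale_model:
                vin[2] = sigma * (x[0] - v_center) / v_spread
            else:
                vin[2] = x[0]
        if n_in_model == 4:
            if scale_model:
                vin[3] = sigma * (2.0 * x[1] - 1.0)
                vin[4] = sigma * (2.0 * x[2] - 1.0)
                vin[5] = sigma * (2.0 * x[3] - 1.0)
            else:
                vin[3] = x[1]
                vin[4] = x[2]
                vin[5] = x[3]
        for i in range(NR):
            acc = vin[chan[i]]
            for jj in range(indptr[i], indptr[i + 1]):
                acc += data[jj] * r[indices[jj]]
            rn[i] = np.tanh(acc)
        tmp = r
        r = rn
        rn = tmp
        out = b
        for i in range(NR):
            out += w[i] * r[i]
        if n_out_model >= 1:
            out += w[NR] * x[0]
        if n_out_model == 4:
            out += w[NR + 1] * x[1] + w[NR + 2] * x[2] + w[NR + 3] * x[3]
        if out < v_lo:
            out = v_lo
            n_clipped += 1
        elif out > v_hi:
            out = v_hi
            n_clipped += 1
        vpred[t] = out
        gates[t, 0] = x[1]
        gates[t, 1] = x[2]
        gates[t, 2] = x[3]
        vfb = out
    return vpred, gates, status, n_clipped
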