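"""Conductance-based point neuron with sigmoidal gate kinetics.

The membrane voltage obeys

    C dV/dt = g_Na m^3 h (E_Na - V) + g_K n^4 (E_K - V) + g_L (E_L - V) + I(t)

and each gate variable χ ∈ {m, h, n} relaxes as

    dχ/dt = (χ∞(V) - χ) / τ_χ(V)
    χ∞(V) = 0.5 (1 + tanh[(V - V_χ)/dV_χ])
    τ_χ(V) = τ0_χ + ε_χ (1 - tanh²[(V - V_χ)/dVt_χ])

so τ_χ ranges between τ0_χ (far from threshold) and τ0_χ + ε_χ (at V_χ).
Sodium inactivation (h) uses the same sigmoid with a negative width dV_h.
Units: mV, ms, µF, mS, µA for a unit-area membrane.

Deliberate "model error" is introduced by fractionally detuning the sodium
parameters (conductance, activation threshold, activation recovery time),
which turns the reference model into a surrogate of itself.

The widely separated gate time constants make the system stiff; trajectories
are produced with an adaptive Cash-Karp embedded Runge-Kutta 4(5) scheme,
with the forcing current held constant across each sampling interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from . import _kernels
from .timeseries import CurrentProtocol, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "GateParams",
    "NeuronParams",
    "NeuronState",
    "ModelError",
    "IntegrationError",
    "default_neuron_params",
    "gate_steady_state",
    "gate_time_constant",
    "state_derivative",
    "detune",
    "resting_state",
    "integrate_window",
    "generate_reference",
]


class IntegrationError(RuntimeError):
    """Adaptive integration failed (step underflow or non-finite state)."""


@dataclass(frozen=True)
class GateParams:
    """Voltage dependence of one gate.

    v_half : half-activation voltage V_χ (mV)
    dv     : sigmoid width dV_χ (mV); its sign selects activation (+)
             versus inactivation (−)
    tau0   : minimum relaxation time τ0_χ (ms)
    eps_tau: amplitude of the bell-shaped τ component (ms); the maximum
             relaxation time is tau0 + eps_tau
    dvt    : width of the bell curve dVt_χ (mV)
    """

    v_half: float
    dv: float
    tau0: float
    eps_tau: float
    dvt: float

    def __post_init__(self):
        if not self.tau0 > 0:
            raise ValueError("tau0 must be > 0")
        if self.eps_tau < 0:
            raise ValueError("eps_tau must be >= 0")
        if self.dv == 0:
            raise ValueError("dv must be non-zero")
        if not self.dvt > 0:
            raise ValueError("dvt must be > 0")


@dataclass(frozen=True)
class NeuronParams:
    """Full parameter set: membrane constants plus one GateParams per gate."""

    C: float
    g_na: float
    g_k: float
    g_l: float
    e_na: float
    e_k: float
    e_l: float
    m: GateParams
    h: GateParams
    n: GateParams

    def __post_init__(self):
        if not self.C > 0:
            raise ValueError("C must be > 0")
        for g in (self.g_na, self.g_k, self.g_l):
            if g < 0:
                raise ValueError("conductances must be >= 0")

    @property
    def gates(self) -> dict:
        return {"m": self.m, "h": self.h, "n": self.n}

    def to_array(self) -> np.ndarray:
        """Pack into the 22-float kernel layout."""
        out = np.empty(22)
        out[0:7] = (self.C, self.g_na, self.g_k, self.g_l, self.e_na, self.e_k, self.e_l)
        for base, g in ((7, self.m), (12, self.h), (17, self.n)):
            out[base : base + 5] = (g.v_half, g.dv, g.tau0, g.eps_tau, g.dvt)
        return out


@dataclass(frozen=True)
class NeuronState:
    """State (V, m, h, n) at one instant; gates are open fractions in [0, 1]."""

    V: float
    m: float
    h: float
    n: float

    def __post_init__(self):
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not -1e-9 <= x <= 1 + 1e-9:
                raise ValueError(f"gate {name}={x} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n], dtype=np.float64)

    @classmethod
    def from_array(cls, a) -> "NeuronState":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass(frozen=True)
class ModelError:
    """Fractional detuning of the sodium parameters (0.1 = 10 %).

    eps_g   scales the sodium conductance g_Na -> g_Na (1 + eps_g)
    eps_v   scales the activation threshold V_m -> V_m (1 + eps_v)
    eps_tau scales the whole activation recovery curve τ_m(V) by (1 + eps_tau)
    """

    eps_g: float = 0.0
    eps_v: float = 0.0
    eps_tau: float = 0.0

    def __post_init__(self):
        if self.eps_g <= -1:
            raise ValueError("eps_g <= -1 gives a non-physical conductance")


def default_neuron_params() -> NeuronParams:
    """Repository default parameter set.

    Classic squid-like magnitudes (g_Na=120, g_K=36, g_L=0.3 mS, E_Na=50,
    E_K=-77, E_L=-54.4 mV, C=1 µF) with sigmoid/bell gate curves chosen to
    give tonic spiking under sustained step currents.  These are package
    defaults, not a published set; everything is overridable via config.
    """
    return NeuronParams(
        C=1.0,
        g_na=120.0,
        g_k=36.0,
        g_l=0.3,
        e_na=50.0,
        e_k=-77.0,
        e_l=-54.4,
        m=GateParams(v_half=-40.0, dv=15.0, tau0=0.1, eps_tau=0.4, dvt=18.0),
        h=GateParams(v_half=-62.0, dv=-14.0, tau0=1.0, eps_tau=7.0, dvt=15.0),
        n=GateParams(v_half=-53.0, dv=16.0, tau0=1.5, eps_tau=4.0, dvt=30.0),
    )


def gate_steady_state(V, g: GateParams):
    """χ∞(V) = 0.5 (1 + tanh[(V - V_half)/dV]); strictly inside (0, 1)."""
    return 0.5 * (1.0 + np.tanh((np.asarray(V, dtype=float) - g.v_half) / g.dv))


def gate_time_constant(V, g: GateParams):
    """τ_χ(V) = tau0 + eps_tau (1 - tanh²[(V - V_half)/dVt])."""
    t = np.tanh((np.asarray(V, dtype=float) - g.v_half) / g.dvt)
    return g.tau0 + g.eps_tau * (1.0 - t * t)


def state_derivative(s: NeuronState, p: NeuronParams, I: float) -> NeuronState:
    """Right-hand side (dV/dt, dm/dt, dh/dt, dn/dt) at state `s` under drive I.

    Reference (pure numpy) evaluation; the compiled integrator uses the same
    formulae and is cross-checked against this function in the test suite.
    """
    V = s.V
    dV = (
        p.g_na * s.m**3 * s.h * (p.e_na - V)
        + p.g_k * s.n**4 * (p.e_k - V)
        + p.g_l * (p.e_l - V)
        + I
    ) / p.C
    rates = []
    for name, x in (("m", s.m), ("h", s.h), ("n", s.n)):
        g = p.gates[name]
        rates.append((gate_steady_state(V, g) - x) / gate_time_constant(V, g))
    return _raw_state(dV, rates)


def _raw_state(dV, rates):
    # A derivative is not a physical state: bypass the [0,1] gate check.
    obj = object.__new__(NeuronState)
    object.__setattr__(obj, "V", float(dV))
    object.__setattr__(obj, "m", float(rates[0]))
    object.__setattr__(obj, "h", float(rates[1]))
    object.__setattr__(obj, "n", float(rates[2]))
    return obj


def detune(p: NeuronParams, e: ModelError) -> NeuronParams:
    """Return a surrogate parameter set with the sodium parameters detuned.

    g_Na is scaled by (1+eps_g); the m-gate half-activation voltage by
    (1+eps_v); the full τ_m(V) curve by (1+eps_tau), i.e. both tau0 and
    eps_tau of the m gate.  All other fields are untouched.
    """
    m = p.m
    m_new = GateParams(
        v_half=m.v_half * (1.0 + e.eps_v),
        dv=m.dv,
        tau0=m.tau0 * (1.0 + e.eps_tau),
        eps_tau=m.eps_tau * (1.0 + e.eps_tau),
        dvt=m.dvt,
    )
    return replace(p, g_na=p.g_na * (1.0 + e.eps_g), m=m_new)


def _membrane_current(V, p: NeuronParams):
    """Net membrane current at voltage V with all gates at steady state."""
    m = gate_steady_state(V, p.m)
    h = gate_steady_state(V, p.h)
    n = gate_steady_state(V, p.n)
    return (
        p.g_na * m**3 * h * (p.e_na - V)
        + p.g_k * n**4 * (p.e_k - V)
        + p.g_l * (p.e_l - V)
    )


def resting_state(p: NeuronParams, I: float = 0.0, v_lo=-120.0, v_hi=20.0) -> NeuronState:
    """Resting fixed point: solve the steady-state current balance for V.

    Scans [v_lo, v_hi] for sign changes of the steady-state membrane current
    and refines each with Brent's method; returns the most hyperpolarized
    root (the physiological rest).
    """
    f = lambda V: _membrane_current(V, p) + I
    grid = np.linspace(v_lo, v_hi, 281)
    vals = np.array([f(v) for v in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(optimize.brentq(f, a, b, xtol=1e-12, rtol=1e-14))
    if not roots:
        raise ValueError("no steady state found in the scanned voltage range")
    V = min(roots)
    return NeuronState(
        V,
        float(gate_steady_state(V, p.m)),
        float(gate_steady_state(V, p.h)),
        float(gate_steady_state(V, p.n)),
    )


def integrate_window(
    s0: NeuronState,
    p: NeuronParams,
    protocol: CurrentProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate over the protocol grid with the adaptive Cash-Karp scheme.

    The current is held constant (zero-order hold) across each sampling
    interval; the maximum internal step is the sampling interval dt, the
    minimum dt*1e-6.  Gates are clamped to [0, 1] after every accepted step.

    Raises
    ------
    IntegrationError
        On step-size underflow (stiffness beyond tolerance) or a non-finite
        state.
    """
    if not rtol > 0:
        raise ValueError("rtol must be positive")
    I = protocol.current
    out, status, n_done = _kernels.integrate_grid(
        s0.to_array(), p.to_array(), I, protocol.dt, rtol, atol, protocol.dt * 1e-6
    )
    if status == 1:
        raise IntegrationError(
            f"step-size underflow at sample {n_done} "
            f"(t={protocol.t0 + n_done * protocol.dt:.4f} ms): the system is "
            f"stiffer than the requested tolerance allows"
        )
    if status == 2:
        raise IntegrationError(f"non-finite state at sample {n_done}")
    return Trajectory(
        out,
        protocol.dt,
        protocol.t0,
        meta={"rtol": rtol, "atol": atol, "integrator": "cash-karp-45"},
    )


def generate_reference(
    p: NeuronParams,
    protocol: CurrentProtocol,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Reference run: start at the I=0 resting fixed point, then integrate.

    Emits the observable voltage together with the hidden gate trajectories
    so that hidden-state reconstructions can later be validated against
    ground truth.
    """
    s0 = resting_state(p, 0.0)
    return integrate_window(s0, p, protocol, rtol=rtol, atol=atol)
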