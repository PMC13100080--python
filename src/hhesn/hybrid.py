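"""Reservoir–surrogate-model hybrids for model-error correction.

An approximate (detuned) conductance model is embedded in front of the
reservoir.  Every sample step the surrogate's voltage is overwritten by the
feedback voltage — the reference V(t) in training, the readout Ṽ(t) in
closed-loop prediction — while its gate variables persist and are integrated
forward one sample interval.  The surrogate's state then enters the
reservoir's input layer and/or its readout, depending on the variant:

==========  ====================  =======================  ====================
variant     input data channels   input model channels     readout model terms
==========  ====================  =======================  ====================
TVH-IH      S(I), S(V)            V                        —
TVH-OH      S(I), S(V)            —                        V
TVH-FH      S(I), S(V)            V                        V
ASVH-IH     S(I), S(V)            V, m, h, n               —
ASVH-OH     S(I), S(V)            —                        V, m, h, n
ASVH-FH     S(I), S(V)            V, m, h, n               V, m, h, n
==========  ====================  =======================  ====================

(TVH = target-variable hybrid, passing only the voltage; ASVH = all-state-
variables hybrid; IH/OH/FH = injection into the input layer, the output
layer, or both.)  Model state enters the input layer in raw physical units
(the input-vector convention (S(V_mem), S(I), V, m, h, n)): the large raw
voltage drives its nodes deep into the tanh, turning them into robust
spike-phase detectors, while the gates are already tanh-sized.  Setting
``scale_model_inputs=True`` instead passes model V through the voltage
scaler and gates through χ ↦ σ(2χ − 1), for sensitivity studies.  A
fraction γ of the reservoir nodes listens to the model channels; the
remainder split evenly between the two data channels.

Because the surrogate's voltage is slaved to the feedback signal while its
gates run free, the gate trajectories produced in closed loop are the
hybrid's reconstruction of the hidden (unobservable) state — the quantity
of interest when only the membrane voltage can be measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .neuron import NeuronParams, NeuronState, resting_state
from .reservoir import (
    PredictionResult,
    Readout,
    ReservoirConfig,
    ReservoirSystem,
    _csr_parts,
    build_adjacency,
    channel_assignment,
    fit_scaler,
    train_readout,
)
from .timeseries import CurrentProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "HybridVariant",
    "HybridLayout",
    "HybridSystem",
    "hybrid_reservoir_config",
    "build_hybrid_layout",
    "make_hybrid",
    "surrogate_teacher_step",
    "hybrid_collect_states",
    "hybrid_train",
    "hybrid_predict",
    "min_delay_observations",
]

#: Input channel order used throughout: data channels then model channels.
CHANNELS = ("I", "V_mem", "model_V", "model_m", "model_h", "model_n")


def min_delay_observations(n_state_vars: int = 4) -> int:
    """Delay-embedding requirement: 2n+1 delayed voltage samples constrain an
    n-component state vector (9 for the four-variable conductance model).

    This sets the memory the reservoir must retain to reconstruct hidden
    gates from voltage observations alone.
    """
    return 2 * n_state_vars + 1


@dataclass(frozen=True)
class HybridVariant:
    """One of the six architecture variants (state_scope × injection)."""

    state_scope: str  # "tvh" | "asvh"
    injection: str  # "ih" | "oh" | "fh"

    def __post_init__(self):
        if self.state_scope not in ("tvh", "asvh"):
            raise ValueError("state_scope must be 'tvh' or 'asvh'")
        if self.injection not in ("ih", "oh", "fh"):
            raise ValueError("injection must be 'ih', 'oh' or 'fh'")

    @classmethod
    def parse(cls, tag: str) -> "HybridVariant":
        scope, _, inj = tag.lower().partition("-")
        return cls(scope, inj)

    @property
    def tag(self) -> str:
        return f"{self.state_scope}-{self.injection}"

    @property
    def n_model_states(self) -> int:
        return 1 if self.state_scope == "tvh" else 4

    @property
    def n_input_model(self) -> int:
        """Model channels wired into the input layer."""
        return self.n_model_states if self.injection in ("ih", "fh") else 0

    @property
    def n_output_model(self) -> int:
        """Model components appended to the readout regressor."""
        return self.n_model_states if self.injection in ("oh", "fh") else 0


@dataclass(frozen=True)
class HybridLayout:
    """Node allocation per input channel.

    counts[0], counts[1] feed the data channels I and V_mem; the remaining
    entries feed the model channels.  gamma is the fraction of nodes updated
    by the model.
    """

    gamma: float
    counts: tuple

    def __post_init__(self):
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return int(sum(self.counts))


def build_hybrid_layout(
    variant: HybridVariant, gamma: float, n_nodes: int
) -> HybridLayout:
    """Allocate nodes: (1−γ)N/2 to each data channel, γN to the model.

    TVH gives all model nodes to V; ASVH splits them γN/4 each across
    V, m, h, n.  Fractional counts are floored and the remainder goes to the
    last listed channel.  OH variants inject nothing into the input layer,
    so their allocation is the γ=0 split.
    """
    if not 0 <= gamma <= 1:
        raise ValueError("gamma must lie in [0, 1]")
    n_in_model = variant.n_input_model
    g = gamma if n_in_model else 0.0
    data = int(np.floor((1.0 - g) * n_nodes / 2.0))
    counts = [data, data]
    if n_in_model:
        model_total = n_nodes - 2 * data
        per = int(np.floor(gamma * n_nodes / n_in_model)) if n_in_model > 1 else model_total
        if n_in_model == 1:
            counts.append(model_total)
        else:
            model_counts = [per] * n_in_model
            model_counts[-1] = model_total - per * (n_in_model - 1)
            counts.extend(model_counts)
    else:
        counts[1] = n_nodes - data
    if counts[-1] < 0:
        raise ValueError("infeasible allocation")
    layout = HybridLayout(gamma, tuple(counts))
    assert layout.n_nodes == n_nodes
    return layout


def hybrid_reservoir_config(
    n_nodes: int = 1000, seed: int = 0
) -> ReservoirConfig:
    """Hybrid hyperparameter row: ρ=1, D=8, σ=0.8, β=1e-3, N_R=1000.

    Relative to the stand-alone reservoir, the lower spectral radius and the
    higher degree lengthen the network's retention time — needed to carry
    the delayed voltage information that constrains the hidden gates.
    """
    return ReservoirConfig(
        n_nodes=n_nodes,
        degree=8,
        spectral_radius=1.0,
        input_scaling=0.8,
        ridge_beta=1e-3,
        seed=seed,
    )


@dataclass
class HybridSystem:
    """A reservoir plus an embedded surrogate conductance model."""

    reservoir: ReservoirSystem
    surrogate_params: NeuronParams
    variant: HybridVariant
    layout: HybridLayout
    surrogate_state: NeuronState = None
    rtol: float = 1e-8
    atol: float = 1e-10
    #: pass model state to the input layer raw (physical units) rather than
    #: through the data scalers; raw is the default input-vector convention
    scale_model_inputs: bool = False

    @property
    def config(self) -> ReservoirConfig:
        return self.reservoir.config

    @property
    def n_regressors(self) -> int:
        return self.reservoir.config.n_nodes + self.variant.n_output_model

    @property
    def trained(self) -> bool:
        return self.reservoir.readout is not None


def make_hybrid(
    config: ReservoirConfig,
    surrogate_params: NeuronParams,
    variant: HybridVariant | str,
    gamma: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    scale_model_inputs: bool = False,
) -> HybridSystem:
    """Build (untrained) hybrid: adjacency, node layout, embedded surrogate."""
    if isinstance(variant, str):
        variant = HybridVariant.parse(variant)
    a = build_adjacency(
        config.n_nodes, config.degree, config.spectral_radius, config.seed
    )
    layout = build_hybrid_layout(variant, gamma, config.n_nodes)
    chan = channel_assignment(layout.counts)
    res = ReservoirSystem(config=config, A=a, chan=chan)
    return HybridSystem(
        reservoir=res,
        surrogate_params=surrogate_params,
        variant=variant,
        layout=layout,
        rtol=rtol,
        atol=atol,
        scale_model_inputs=scale_model_inputs,
    )


def surrogate_teacher_step(
    state: NeuronState,
    params: NeuronParams,
    v_feedback: float,
    I: float,
    dt: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> NeuronState:
    """One embedded-model update: slave V to the feedback voltage, keep the
    gates, integrate one sample interval under held current I."""
    y = state.to_array()
    y[0] = v_feedback
    status = _kernels._advance(y, params.to_array(), I, dt, rtol, atol, dt * 1e-6)
    if status != 0:
        raise RuntimeError(f"surrogate integration failed (status {status})")
    return NeuronState.from_array(y)


def hybrid_collect_states(
    system: HybridSystem, protocol: CurrentProtocol, v_mem: np.ndarray
) -> np.ndarray:
    """Teacher-forced pass: returns the (N_W−1, n_regressors) regressor matrix.

    Per step: surrogate teacher update → input vector per variant →
    reservoir update; the regressor row is the reservoir state, concatenated
    with the surrogate's output components for OH/FH variants.
    """
    v_mem = np.asarray(v_mem, dtype=float)
    if v_mem.size != protocol.n_samples:
        raise ValueError("protocol and voltage series lengths differ")
    res = system.reservoir
    cfg = res.config
    res.scaler_i = fit_scaler(protocol.current, cfg.input_scaling)
    res.scaler_v = fit_scaler(v_mem, cfg.input_scaling)
    if system.surrogate_state is None:
        system.surrogate_state = resting_state(system.surrogate_params)
    indptr, indices, data = _csr_parts(res.A)
    states, xout, r_end, x_end, status = _kernels.run_teacher(
        indptr,
        indices,
        data,
        res.chan,
        res.scaler_i.apply(protocol.current),
        res.scaler_v.apply(v_mem),
        protocol.current,
        v_mem,
        system.surrogate_params.to_array(),
        system.surrogate_state.to_array(),
        protocol.dt,
        system.rtol,
        system.atol,
        protocol.dt * 1e-6,
        system.variant.n_input_model,
        cfg.input_scaling,
        res.scaler_v.center,
        res.scaler_v.spread,
        system.scale_model_inputs,
        True,
    )
    if status != 0:
        raise RuntimeError(f"surrogate integration failed during training (status {status})")
    res.r_state = r_end
    res.v_feedback = float(v_mem[-1])
    span = float(v_mem.max() - v_mem.min())
    res.v_lo = float(v_mem.min()) - 0.5 * span
    res.v_hi = float(v_mem.max()) + 0.5 * span
    system.surrogate_state = NeuronState.from_array(np.clip(x_end, [-np.inf, 0, 0, 0], [np.inf, 1, 1, 1]))
    n_out = system.variant.n_output_model
    if n_out == 0:
        return states
    comps = xout[:, :1] if n_out == 1 else xout
    return np.hstack([states, comps])


def hybrid_train(
    system: HybridSystem, protocol: CurrentProtocol, v_mem: np.ndarray
) -> HybridSystem:
    """Fit the readout over the widened regressor; store warm-start states."""
    regressors = hybrid_collect_states(system, protocol, v_mem)
    system.reservoir.readout = train_readout(
        regressors,
        np.asarray(v_mem, dtype=float)[1:],
        system.config.ridge_beta,
        system.config.input_scaling,
    )
    return system


def hybrid_predict(
    system: HybridSystem, protocol: CurrentProtocol, horizon: int | None = None
) -> PredictionResult:
    """Closed-loop prediction with hidden-state reconstruction.

    The readout voltage replaces the reference feedback both on the
    reservoir voltage channel and in the surrogate teacher step.  Returns
    the corrected voltage series and the surrogate's gate trajectories
    (m, h, n) — the reconstructed hidden states.  Saturation or divergence
    is flagged, never raised.
    """
    if not system.trained:
        raise RuntimeError("system has no trained readout")
    h = protocol.n_samples if horizon is None else int(horizon)
    if h == 0:
        return PredictionResult(np.empty(0), np.empty((0, 3)), False)
    if h > protocol.n_samples:
        raise ValueError("horizon exceeds protocol length")
    res = system.reservoir
    cfg = res.config
    indptr, indices, data = _csr_parts(res.A)
    i_raw = protocol.current[:h]
    vpred, gates, status, n_clipped = _kernels.run_closed_loop(
        indptr,
        indices,
        data,
        res.chan,
        res.scaler_i.apply(i_raw),
        i_raw,
        res.r_state,
        system.surrogate_state.to_array(),
        res.v_feedback,
        system.surrogate_params.to_array(),
        protocol.dt,
        system.rtol,
        system.atol,
        protocol.dt * 1e-6,
        system.variant.n_input_model,
        system.variant.n_output_model,
        cfg.input_scaling,
        res.scaler_v.center,
        res.scaler_v.spread,
        system.scale_model_inputs,
        res.readout.weights,
        res.readout.bias,
        res.v_lo,
        res.v_hi,
        True,
    )
    saturated = status != 0 or not np.all(np.isfinite(vpred))
    if not saturated:
        saturated = bool(n_clipped > 0.01 * h)
    return PredictionResult(vpred, gates, saturated, status, int(n_clipped))
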