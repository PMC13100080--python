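"""Identifiability-oriented current protocols.

A good training current must probe the full internal dynamics of the neuron
(every gate's kinetics), which requires aperiodic forcing with power across
the band of gate relaxation rates and excursions both below and above the
spiking threshold.  The protocols here interleave chaotic segments (the x
component of the Lorenz system) with sequences of random-amplitude,
random-duration current steps, switched at random (exponentially
distributed) times, and finally rescale the mixture into a target current
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import periodogram

from .neuron import NeuronParams, gate_time_constant, resting_state
from .timeseries import DT_MS, CurrentProtocol

__all__ = [
    "LorenzParams",
    "StepParams",
    "ProtocolPlan",
    "BandwidthReport",
    "lorenz_series",
    "random_steps",
    "mixed_protocol",
    "training_and_prediction_protocols",
    "protocol_bandwidth_check",
]


@dataclass(frozen=True)
class LorenzParams:
    """Standard Lorenz system dx/dt = α(y−x), dy/dt = x(ρ−z)−y, dz/dt = xy−βz.

    ``time_scale`` maps one Lorenz time unit onto this many ms, placing the
    attractor's oscillation band inside the neuron's gate-rate band.
    """

    alpha: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    ic: tuple = (1.0, 1.0, 1.0)
    time_scale: float = 5.0

    def __post_init__(self):
        if not self.time_scale > 0:
            raise ValueError("time_scale must be positive")


@dataclass(frozen=True)
class StepParams:
    """Random step train: amplitudes ~ U(amp_range), durations ~ U(dur_range) ms."""

    amp_range: tuple = (-18.0, 18.0)
    dur_range: tuple = (1.0, 20.0)
    seed: int = 0

    def __post_init__(self):
        if self.amp_range[0] > self.amp_range[1]:
            raise ValueError("amp_range low > high")
        if not 0 < self.dur_range[0] <= self.dur_range[1]:
            raise ValueError("dur_range must satisfy 0 < low <= high")


@dataclass(frozen=True)
class ProtocolPlan:
    """Layout of a mixed protocol.

    Regimes alternate at exponentially distributed switch times with mean
    ``switch_mean_ms``; the concatenated series is affinely rescaled so its
    min/max hit ``target_range`` exactly (one global map, preserving the
    relative amplitudes of the two regimes).
    """

    total_duration_ms: float
    dt: float = DT_MS
    switch_mean_ms: float = 25.0
    target_range: tuple = (-3.0, 22.0)
    seed: int = 0

    def __post_init__(self):
        n = self.total_duration_ms / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total_duration_ms must be a multiple of dt")
        if not self.switch_mean_ms > 0:
            raise ValueError("switch_mean_ms must be positive")
        if self.target_range[0] >= self.target_range[1]:
            raise ValueError("target_range low must be < high")

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_ms / self.dt)) + 1


def lorenz_series(lp: LorenzParams, duration_ms: float, dt: float = DT_MS) -> np.ndarray:
    """x(t) of the Lorenz system sampled at dt over `duration_ms`.

    Deterministic: fixed-tolerance RK45 from the stated initial condition;
    the 3D trajectory is collapsed onto its x component.
    """
    if not duration_ms > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_ms / dt)) + 1
    t_end = duration_ms / lp.time_scale
    t_eval = np.linspace(0.0, t_end, n)
    a, r, b = lp.alpha, lp.rho, lp.beta

    def rhs(_, s):
        x, y, z = s
        return (a * (y - x), x * (r - z) - y, x * y - b * z)

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        np.asarray(lp.ic, dtype=float),
        t_eval=t_eval,
        rtol=1e-9,
        atol=1e-9,
        max_step=0.05,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"Lorenz integration failed: {sol.message}")
    return sol.y[0]


def random_steps(sp: StepParams, duration_ms: float, dt: float = DT_MS) -> np.ndarray:
    """Piecewise-constant series of uniform random amplitudes and durations."""
    if not duration_ms > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_ms / dt)) + 1
    rng = np.random.default_rng(sp.seed)
    out = np.empty(n)
    # segments tile the n-1 sampling intervals; the endpoint sample belongs
    # to the final segment
    k = 0
    while k < n - 1:
        amp = rng.uniform(sp.amp_range[0], sp.amp_range[1])
        dur = rng.uniform(sp.dur_range[0], sp.dur_range[1])
        span = max(int(round(dur / dt)), 1)
        out[k : k + span] = amp
        k += span
    if n >= 2:
        out[n - 1] = out[n - 2]
    elif n == 1:
        out[0] = rng.uniform(sp.amp_range[0], sp.amp_range[1])
    return out


def _regime_mask(n: int, dt: float, switch_mean_ms: float, rng) -> np.ndarray:
    """Boolean mask, True where the step regime is active; alternating
    segments with exponentially distributed lengths, random initial regime."""
    mask = np.empty(n, dtype=np.bool_)
    regime = bool(rng.integers(0, 2))
    k = 0
    while k < n:
        span = max(int(round(rng.exponential(switch_mean_ms) / dt)), 1)
        mask[k : k + span] = regime
        regime = not regime
        k += span
    return mask


def mixed_protocol(
    plan: ProtocolPlan,
    lp: LorenzParams | None = None,
    sp: StepParams | None = None,
) -> CurrentProtocol:
    """Alternate Lorenz and random-step segments, then rescale globally.

    The switching law is driven by ``plan.seed``; the step train by
    ``sp.seed``.  The output min/max equal the plan's target range exactly
    (affine map of the concatenated series).
    """
    lp = lp if lp is not None else LorenzParams()
    sp = sp if sp is not None else StepParams(seed=plan.seed + 1)
    n = plan.n_samples
    rng = np.random.default_rng(plan.seed)
    mask = _regime_mask(n, plan.dt, plan.switch_mean_ms, rng)
    series = np.where(
        mask,
        random_steps(sp, plan.total_duration_ms, plan.dt),
        lorenz_series(lp, plan.total_duration_ms, plan.dt),
    )
    lo, hi = series.min(), series.max()
    t_lo, t_hi = plan.target_range
    if hi - lo < 1e-30:
        series = np.full(n, 0.5 * (t_lo + t_hi))
    else:
        series = t_lo + (series - lo) * (t_hi - t_lo) / (hi - lo)
    return CurrentProtocol(series, plan.dt)


def training_and_prediction_protocols(
    train_ms: float,
    predict_ms: float,
    seed: int,
    dt: float = DT_MS,
    switch_mean_ms: float = 25.0,
    target_range: tuple = (-3.0, 22.0),
    lp: LorenzParams | None = None,
) -> tuple[CurrentProtocol, CurrentProtocol]:
    """Paired protocols from disjoint sub-seeds of `seed`.

    The prediction waveform is distinct from the training waveform (different
    switching draws, different step train, and a perturbed Lorenz initial
    condition so the chaotic segments decorrelate).
    """
    ss = np.random.SeedSequence(seed)
    s_train, s_pred = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    lp = lp if lp is not None else LorenzParams()
    lp_pred = LorenzParams(
        lp.alpha, lp.rho, lp.beta, (lp.ic[0] + 1.0, lp.ic[1], lp.ic[2]), lp.time_scale
    )
    train = mixed_protocol(
        ProtocolPlan(train_ms, dt, switch_mean_ms, target_range, s_train),
        lp,
        StepParams(seed=s_train + 1),
    )
    pred = mixed_protocol(
        ProtocolPlan(predict_ms, dt, switch_mean_ms, target_range, s_pred),
        lp_pred,
        StepParams(seed=s_pred + 1),
    )
    return train, pred


@dataclass(frozen=True)
class BandwidthReport:
    """95 %-power band of a protocol versus the neuron's gate-rate band.

    ``band_khz`` holds the central 95 % power band (2.5th to 97.5th power
    percentile frequency); ``gate_band_khz`` the interval
    [1/(2π max τ), 1/(2π min τ)] over all gates at rest; ``covered`` whether
    every octave of the gate band carries non-negligible power.
    """

    band_khz: tuple
    gate_band_khz: tuple
    covered: bool
    reason: str = ""
    psd: np.ndarray = field(default=None, repr=False, compare=False)
    freqs_khz: np.ndarray = field(default=None, repr=False, compare=False)


def protocol_bandwidth_check(
    protocol: CurrentProtocol, p: NeuronParams, min_octave_frac: float = 5e-4
) -> BandwidthReport:
    """Check that a protocol's spectrum spans the gate relaxation rates.

    Gate rates are evaluated at the resting voltage.  Coverage requires
    every octave of the gate-rate band to carry at least
    ``min_octave_frac`` of the total (DC-excluded) power — a narrowband
    drive concentrated in one octave does not probe all gate kinetics even
    if it sits inside the band — and the band must be resolvable within
    [frequency resolution, Nyquist].
    """
    x = protocol.current
    if x.size < 256:
        raise ValueError("need at least 256 samples for a spectral estimate")
    rest = resting_state(p)
    taus = [gate_time_constant(rest.V, g) for g in p.gates.values()]
    gate_band = (1.0 / (2 * np.pi * max(taus)), 1.0 / (2 * np.pi * min(taus)))

    fs = 1.0 / protocol.dt  # kHz, since dt is in ms
    freqs, psd = periodogram(x, fs=fs, detrend=False)
    freqs, psd = freqs[1:], psd[1:]  # drop DC
    total = psd.sum()
    if total <= 1e-30 * x.size:
        return BandwidthReport(
            (0.0, 0.0), gate_band, False, "no dynamic content", psd, freqs
        )
    cum = np.cumsum(psd) / total
    f_lo = freqs[int(np.searchsorted(cum, 0.025))]
    f_hi = freqs[min(int(np.searchsorted(cum, 0.975)), freqs.size - 1)]

    df = freqs[0]
    nyq = freqs[-1]
    if gate_band[0] < df or gate_band[1] > nyq:
        return BandwidthReport(
            (f_lo, f_hi),
            gate_band,
            False,
            "gate band not resolvable at this sampling",
            psd,
            freqs,
        )
    covered = True
    reason = ""
    lo = gate_band[0]
    while lo < gate_band[1]:
        hi = min(lo * 2.0, gate_band[1])
        octave = (freqs >= lo) & (freqs < hi) if hi < gate_band[1] else (
            (freqs >= lo) & (freqs <= hi)
        )
        if psd[octave].sum() < min_octave_frac * total:
            covered = False
            reason = f"power gap in the {lo:.4g}-{hi:.4g} kHz octave of the gate band"
            break
        lo = hi
    return BandwidthReport((f_lo, f_hi), gate_band, covered, reason, psd, freqs)
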