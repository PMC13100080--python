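"""Benchmark harness: shared data generation, single cases, error sweeps.

A benchmark epoch is a training window followed by a prediction window with
a distinct current waveform; the reference trajectory is one continuous
integration across both, so prediction starts from the true end-of-training
state.  Systems under test:

``surrogate``      the raw detuned model, integrated open-loop from its own
                   resting state over the whole epoch;
``reservoir``      the stand-alone echo-state reservoir;
``tvh-ih`` … ``asvh-fh``   the six hybrid variants.

The default configuration is a desk-scale benchmark (312.5 ms training,
2500 ms prediction, 300 reservoir nodes, 5 seeds) that preserves every
published ordering being tested; full-scale settings (1250 ms training with
50001 samples, N_R = 1000) are a config change away.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import WindowedError, gate_recovery_metrics, rmse_windows
from .hybrid import HybridVariant, hybrid_predict, hybrid_reservoir_config, hybrid_train, make_hybrid
from .neuron import (
    ModelError,
    NeuronParams,
    default_neuron_params,
    detune,
    generate_reference,
    integrate_window,
    resting_state,
)
from .reservoir import ReservoirConfig, make_reservoir, predict_closed_loop, train_reservoir
from .stimulus import LorenzParams, training_and_prediction_protocols
from .timeseries import DT_MS, CurrentProtocol, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkData",
    "CaseResult",
    "SweepTable",
    "make_benchmark_data",
    "run_case",
    "sweep_model_error",
    "size_and_gamma_study",
]

HYBRID_TAGS = ("tvh-ih", "tvh-oh", "tvh-fh", "asvh-ih", "asvh-oh", "asvh-fh")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for one benchmark.

    Durations in ms; dt defaults to the 25 µs grid.  Hyperparameters follow
    the published rows (stand-alone reservoir ρ=1.25, D=6, σ=0.4, β=1e-4;
    hybrid ρ=1, D=8, σ=0.8, β=1e-3), only the node count is scaled down by
    default.
    """

    dt: float = DT_MS
    train_ms: float = 312.5
    predict_ms: float = 2500.0
    window_ms: float = 1250.0
    n_nodes: int = 300
    gamma: float = 0.5
    neuron: NeuronParams = field(default_factory=default_neuron_params)
    target_range: tuple = (-3.0, 22.0)
    switch_mean_ms: float = 25.0
    rtol: float = 1e-8
    atol: float = 1e-10

    @property
    def n_train(self) -> int:
        """Samples in the training window (N_W)."""
        return int(round(self.train_ms / self.dt)) + 1

    @property
    def n_predict(self) -> int:
        return int(round(self.predict_ms / self.dt))

    def reservoir_config(self, seed: int) -> ReservoirConfig:
        return ReservoirConfig(n_nodes=self.n_nodes, seed=seed)

    def hybrid_config(self, seed: int) -> ReservoirConfig:
        return hybrid_reservoir_config(n_nodes=self.n_nodes, seed=seed)


@dataclass(frozen=True)
class BenchmarkData:
    """Reference data for one seed: protocols plus the continuous trajectory."""

    config: BenchmarkConfig
    seed: int
    train_protocol: CurrentProtocol
    full_protocol: CurrentProtocol
    reference: Trajectory

    @property
    def n_train(self) -> int:
        return self.train_protocol.n_samples

    @property
    def v_train(self) -> np.ndarray:
        return self.reference.V[: self.n_train]

    @property
    def v_predict(self) -> np.ndarray:
        """Reference voltage over the prediction window (after training end)."""
        return self.reference.V[self.n_train :]

    @property
    def gates_predict(self) -> np.ndarray:
        return self.reference.gates[self.n_train :]

    @property
    def predict_drive(self) -> CurrentProtocol:
        """Current samples driving each closed-loop prediction step."""
        i0 = self.n_train - 1
        return self.full_protocol.slice(i0, i0 + self.config.n_predict)


def _substream(seed: int, label: str) -> int:
    tag = zlib.crc32(label.encode()) % 2**31
    ss = np.random.SeedSequence([int(seed), tag])
    return int(ss.generate_state(1)[0] % 2**31)


def make_benchmark_data(config: BenchmarkConfig, seed: int) -> BenchmarkData:
    """Generate protocols and the continuous reference trajectory for `seed`."""
    train, pred = training_and_prediction_protocols(
        config.train_ms,
        config.predict_ms,
        _substream(seed, "stimulus"),
        dt=config.dt,
        switch_mean_ms=config.switch_mean_ms,
        target_range=config.target_range,
    )
    full = train.concat(pred)
    ref = generate_reference(config.neuron, full, rtol=config.rtol, atol=config.atol)
    return BenchmarkData(config, seed, train, full, ref)


@dataclass(frozen=True)
class CaseResult:
    """Outcome of one (system, model-error, seed) benchmark cell."""

    system: str
    eps: ModelError
    seed: int
    windowed: WindowedError
    saturated: bool
    gate_rmse: dict | None = None  # per-gate corrected/raw-vs-reference RMSE
    gates: np.ndarray = field(default=None, repr=False, compare=False)


def _surrogate_case(data: BenchmarkData, params: NeuronParams) -> tuple:
    """Open-loop run of the detuned model over the full epoch."""
    s0 = resting_state(params)
    traj = integrate_window(
        s0, params, data.full_protocol, rtol=data.config.rtol, atol=data.config.atol
    )
    v = traj.V[data.n_train :]
    gates = traj.gates[data.n_train :]
    return v, gates


def run_case(
    data: BenchmarkData, system: str, eps: ModelError = ModelError(), seed_offset: int = 0
) -> CaseResult:
    """Train (if applicable) and evaluate one system on shared data.

    `system` is "surrogate", "reservoir", or a hybrid tag like "asvh-fh".
    The reservoir seed derives from the data seed so that all systems for a
    given seed share their random graph draw.
    """
    cfg = data.config
    res_seed = _substream(data.seed + seed_offset, "adjacency")
    surrogate = detune(cfg.neuron, eps)
    if system == "surrogate":
        v, gates = _surrogate_case(data, surrogate)
        we = rmse_windows(v, data.v_predict, cfg.dt, cfg.window_ms)
        gr = gate_recovery_metrics(gates, gates, data.gates_predict)
        return CaseResult(system, eps, data.seed, we, False, gr, gates)
    if system == "reservoir":
        sys_ = make_reservoir(cfg.reservoir_config(res_seed))
        train_reservoir(sys_, data.train_protocol, data.v_train)
        pred = predict_closed_loop(sys_, data.predict_drive)
        we = rmse_windows(pred.voltage, data.v_predict, cfg.dt, cfg.window_ms)
        return CaseResult(system, eps, data.seed, we, pred.saturated)
    if system not in HYBRID_TAGS:
        raise ValueError(f"unknown system {system!r}")
    hyb = make_hybrid(
        cfg.hybrid_config(res_seed),
        surrogate,
        system,
        gamma=cfg.gamma,
        rtol=cfg.rtol,
        atol=cfg.atol,
    )
    hybrid_train(hyb, data.train_protocol, data.v_train)
    pred = hybrid_predict(hyb, data.predict_drive)
    we = rmse_windows(pred.voltage, data.v_predict, cfg.dt, cfg.window_ms)
    gr = gate_recovery_metrics(pred.gates, pred.gates, data.gates_predict)
    return CaseResult(system, eps, data.seed, we, pred.saturated, gr, pred.gates)


def _as_model_error(error_type: str, eps: float) -> ModelError:
    if error_type == "eps_g":
        return ModelError(eps_g=eps)
    if error_type == "eps_v":
        return ModelError(eps_v=eps)
    if error_type == "eps_tau":
        return ModelError(eps_tau=eps)
    if error_type == "combined":
        return ModelError(eps, eps, eps)
    raise ValueError(f"unknown error type {error_type!r}")


@dataclass
class SweepTable:
    """Tidy results of a model-error sweep.

    ``windows``: one row per (eps, system, seed, window) with its RMSE and
    saturation flag.  ``gates``: per-gate RMSE vs the reference hidden
    trajectories for systems that expose gates.  Failed/saturated runs stay
    in the table (flagged), never silently dropped.
    """

    error_type: str
    grid: np.ndarray
    systems: tuple
    seeds: tuple
    windows: pd.DataFrame
    gates: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Median over windows per run, then median over seeds per cell."""
        per_run = (
            self.windows.groupby(["error_type", "eps", "system", "seed"])
            .agg(median_rmse=("rmse", "median"), saturated=("saturated", "any"))
            .reset_index()
        )
        return (
            per_run.groupby(["error_type", "eps", "system"])
            .agg(
                median_rmse=("median_rmse", "median"),
                n_seeds=("seed", "nunique"),
                n_saturated=("saturated", "sum"),
            )
            .reset_index()
        )

    def medians(self, system: str) -> np.ndarray:
        """Seed-median windowed RMSE per grid point for one system."""
        s = self.summary()
        s = s[s.system == system].set_index("eps")["median_rmse"]
        return np.array([s.get(e, np.nan) for e in self.grid])


def sweep_model_error(
    config: BenchmarkConfig,
    error_type: str,
    grid,
    systems,
    seeds,
    data_cache: dict | None = None,
) -> SweepTable:
    """Run every (ε, system, seed) cell of a model-error sweep.

    Reference data are generated once per seed and shared across the grid
    and systems.  `data_cache` (seed -> BenchmarkData) allows reuse across
    sweeps.  Fully reproducible from the seed list.
    """
    grid = np.asarray(list(grid), dtype=float)
    systems = tuple(systems)
    seeds = tuple(int(s) for s in seeds)
    cache = data_cache if data_cache is not None else {}
    win_rows, gate_rows = [], []
    for seed in seeds:
        if seed not in cache:
            cache[seed] = make_benchmark_data(config, seed)
        data = cache[seed]
        for eps in grid:
            err = _as_model_error(error_type, float(eps))
            for system in systems:
                if system == "reservoir" and eps != grid[0]:
                    # the reservoir sees no surrogate: one run per seed
                    continue
                res = run_case(data, system, err)
                for w_idx, w_rmse in enumerate(res.windowed.values):
                    win_rows.append(
                        dict(
                            error_type=error_type,
                            eps=float(eps),
                            system=system,
                            seed=seed,
                            window_index=w_idx,
                            rmse=w_rmse,
                            saturated=res.saturated,
                        )
                    )
                if res.gate_rmse is not None:
                    for gname, gvals in res.gate_rmse.items():
                        gate_rows.append(
                            dict(
                                error_type=error_type,
                                eps=float(eps),
                                system=system,
                                seed=seed,
                                gate=gname,
                                rmse=gvals["corrected_rmse"],
                            )
                        )
    windows = pd.DataFrame(win_rows)
    gates = pd.DataFrame(gate_rows)
    if "reservoir" in systems and len(grid) > 1 and not windows.empty:
        # broadcast the single reservoir run across the grid for tidy joins
        base = windows[(windows.system == "reservoir") & (windows.eps == grid[0])]
        extra = [base.assign(eps=float(e)) for e in grid[1:]]
        windows = pd.concat([windows, *extra], ignore_index=True)
    return SweepTable(error_type, grid, systems, seeds, windows, gates)


def size_and_gamma_study(
    config: BenchmarkConfig,
    n_nodes_grid,
    gamma_grid,
    eps: ModelError = ModelError(eps_g=0.1),
    seeds=(0,),
    system: str = "asvh-fh",
    plateau_threshold: float = 0.1,
) -> pd.DataFrame:
    """Median RMSE versus reservoir size and versus γ.

    The size scan also runs the stand-alone reservoir for reference and
    flags the plateau: the first size whose relative improvement per
    doubling falls below `plateau_threshold`.
    """
    rows = []
    cache: dict = {}
    for n in n_nodes_grid:
        cfg = replace(config, n_nodes=int(n))
        for seed in seeds:
            key = (seed,)
            if key not in cache:
                cache[key] = make_benchmark_data(cfg, seed)
            data = BenchmarkData(cfg, seed, cache[key].train_protocol, cache[key].full_protocol, cache[key].reference)
            for sysname in (system, "reservoir"):
                res = run_case(data, sysname, eps)
                rows.append(
                    dict(
                        study="size",
                        n_nodes=int(n),
                        gamma=cfg.gamma,
                        system=sysname,
                        seed=seed,
                        median_rmse=res.windowed.median,
                        saturated=res.saturated,
                    )
                )
    for g in gamma_grid:
        cfg = replace(config, gamma=float(g))
        for seed in seeds:
            key = (seed,)
            if key not in cache:
                cache[key] = make_benchmark_data(cfg, seed)
            data = BenchmarkData(cfg, seed, cache[key].train_protocol, cache[key].full_protocol, cache[key].reference)
            res = run_case(data, system, eps)
            rows.append(
                dict(
                    study="gamma",
                    n_nodes=cfg.n_nodes,
                    gamma=float(g),
                    system=system,
                    seed=seed,
                    median_rmse=res.windowed.median,
                    saturated=res.saturated,
                )
            )
    df = pd.DataFrame(rows)
    size_med = (
        df[(df.study == "size") & (df.system == system)]
        .groupby("n_nodes")["median_rmse"]
        .median()
        .sort_index()
    )
    plateau = None
    for (n_prev, e_prev), (n_cur, e_cur) in zip(
        size_med.items(), list(size_med.items())[1:]
    ):
        if e_prev > 0:
            gain_per_doubling = (e_prev - e_cur) / e_prev / max(np.log2(n_cur / n_prev), 1e-12)
            if gain_per_doubling < plateau_threshold:
                plateau = n_cur
                break
    df.attrs["plateau_n_nodes"] = plateau
    return df
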