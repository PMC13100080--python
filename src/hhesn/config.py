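"""Run configuration: YAML files validated into typed objects.

An empty file yields the full set of defaults (published hyperparameter
rows, repository-default neuron constants, the desk-scale benchmark
windows).  Unknown keys and type mismatches are rejected with the offending
field path in the message.  Every pipeline run writes its fully resolved
configuration next to its outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .benchmark import BenchmarkConfig
from .neuron import GateParams, ModelError, NeuronParams
from .timeseries import DT_MS

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GateTable(_Strict):
    v_half: float
    dv: float
    tau0: float
    eps_tau: float
    dvt: float


class NeuronTable(_Strict):
    C: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_l: float = -54.4
    m: GateTable = GateTable(v_half=-40.0, dv=15.0, tau0=0.1, eps_tau=0.4, dvt=18.0)
    h: GateTable = GateTable(v_half=-62.0, dv=-14.0, tau0=1.0, eps_tau=7.0, dvt=15.0)
    n: GateTable = GateTable(v_half=-53.0, dv=16.0, tau0=1.5, eps_tau=4.0, dvt=30.0)

    def build(self) -> NeuronParams:
        d = self.model_dump()
        gates = {k: GateParams(**d.pop(k)) for k in ("m", "h", "n")}
        return NeuronParams(**d, **gates)


class LorenzTable(_Strict):
    alpha: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    ic: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_scale: float = 5.0


class StepsTable(_Strict):
    amp_lo: float = -18.0
    amp_hi: float = 18.0
    dur_lo: float = 1.0
    dur_hi: float = 20.0


class StimulusTable(_Strict):
    lorenz: LorenzTable = LorenzTable()
    steps: StepsTable = StepsTable()
    switch_mean_ms: float = 25.0
    target_lo: float = -3.0
    target_hi: float = 22.0


class ReservoirTable(_Strict):
    """Stand-alone reservoir hyperparameter row."""

    n_nodes: int = 1000
    degree: int = 6
    spectral_radius: float = 1.25
    input_scaling: float = 0.4
    ridge_beta: float = 1e-4


class HybridTable(_Strict):
    """Hybrid reservoir hyperparameter row plus architecture choices."""

    n_nodes: int = 1000
    degree: int = 8
    spectral_radius: float = 1.0
    input_scaling: float = 0.8
    ridge_beta: float = 1e-3
    gamma: float = 0.5
    variant: str = "asvh-fh"


class ErrorTable(_Strict):
    eps_g: float = 0.0
    eps_v: float = 0.0
    eps_tau: float = 0.0

    def build(self) -> ModelError:
        return ModelError(self.eps_g, self.eps_v, self.eps_tau)


class WindowsTable(_Strict):
    dt_ms: float = DT_MS
    train_ms: float = 1250.0
    predict_ms: float = 5500.0
    rmse_window_ms: float = 1250.0

    @model_validator(mode="after")
    def _check(self):
        if not self.dt_ms > 0:
            raise ValueError("dt_ms must be positive")
        for name in ("train_ms", "predict_ms", "rmse_window_ms"):
            v = getattr(self, name)
            if abs(v / self.dt_ms - round(v / self.dt_ms)) > 1e-9:
                raise ValueError(f"{name} must be a multiple of dt_ms")
        return self


class RunConfig(_Strict):
    neuron: NeuronTable = NeuronTable()
    stimulus: StimulusTable = StimulusTable()
    reservoir: ReservoirTable = ReservoirTable()
    hybrid: HybridTable = HybridTable()
    error: ErrorTable = ErrorTable()
    windows: WindowsTable = WindowsTable()
    seed: int = 0
    outdir: str = "runs"

    def to_benchmark(self) -> BenchmarkConfig:
        """Desk-facing view used by the sweep/benchmark commands.

        Reservoir-vs-hybrid hyperparameter rows keep their own values; the
        benchmark node count follows the hybrid table.
        """
        return BenchmarkConfig(
            dt=self.windows.dt_ms,
            train_ms=self.windows.train_ms,
            predict_ms=self.windows.predict_ms,
            window_ms=self.windows.rmse_window_ms,
            n_nodes=self.hybrid.n_nodes,
            gamma=self.hybrid.gamma,
            neuron=self.neuron.build(),
            target_range=(self.stimulus.target_lo, self.stimulus.target_hi),
            switch_mean_ms=self.stimulus.switch_mean_ms,
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; missing keys take defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
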