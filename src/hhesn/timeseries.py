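"""Uniformly sampled time-series containers shared across modules.

All series in the package live on a fixed grid with spacing ``dt`` (ms);
the reference sampling interval is 25 µs = 0.025 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reference sampling interval, ms (25 µs).
DT_MS = 0.025


@dataclass(frozen=True)
class CurrentProtocol:
    """Forcing-current trace I(t) on a uniform grid.

    Parameters
    ----------
    current
        Current samples (µA for a unit-area membrane).
    dt
        Sampling interval in ms.
    t0
        Time of the first sample in ms.
    """

    current: np.ndarray
    dt: float = DT_MS
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "current", np.asarray(self.current, dtype=np.float64)
        )
        if self.current.ndim != 1:
            raise ValueError("current must be a 1-D array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.current.size and not np.all(np.isfinite(self.current)):
            raise ValueError("current contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.current.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def duration_ms(self) -> float:
        return self.dt * max(self.n_samples - 1, 0)

    def slice(self, start: int, stop: int) -> "CurrentProtocol":
        return CurrentProtocol(
            self.current[start:stop], self.dt, self.t0 + start * self.dt
        )

    def concat(self, other: "CurrentProtocol") -> "CurrentProtocol":
        """Append `other`, dropping its first sample (shared boundary)."""
        if other.dt != self.dt:
            raise ValueError("sampling intervals differ")
        return CurrentProtocol(
            np.concatenate([self.current, other.current[1:]]), self.dt, self.t0
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "I_uA": self.current})


#: Column order of Trajectory.data.
STATE_COLUMNS = ("V", "m", "h", "n")


@dataclass(frozen=True)
class Trajectory:
    """Sampled neuron state (V, m, h, n) on a uniform grid.

    ``data`` has shape (n_samples, 4) in STATE_COLUMNS order.  ``meta``
    carries provenance (tolerances, clamp counts, ...) and does not take
    part in equality.
    """

    data: np.ndarray
    dt: float = DT_MS
    t0: float = 0.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("data must have shape (n, 4): V, m, h, n")
        object.__setattr__(self, "data", arr)
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_samples)

    @property
    def V(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def m(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def h(self) -> np.ndarray:
        return self.data[:, 2]

    @property
    def n(self) -> np.ndarray:
        return self.data[:, 3]

    @property
    def gates(self) -> np.ndarray:
        """(n, 3) array of the hidden gate columns m, h, n."""
        return self.data[:, 1:4]

    def slice(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            self.data[start:stop], self.dt, self.t0 + start * self.dt, dict(self.meta)
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"time_ms": self.times})
        for j, c in enumerate(STATE_COLUMNS):
            out[c if c != "V" else "V_mV"] = self.data[:, j]
        return out
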