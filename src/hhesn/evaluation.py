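"""Prediction-error metrics: windowed RMSE, crossover detection, gate recovery.

Accuracy is summarized as the root-mean-square error between predicted and
reference voltage over consecutive non-overlapping windows (1250 ms by
default), reported as a median with interquartile dispersion.  Medians, not
means, are used throughout so that a single saturated window cannot mask an
otherwise accurate run (or vice versa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WindowedError",
    "rmse",
    "rmse_windows",
    "crossover_points",
    "gate_recovery_metrics",
]


def rmse(pred, ref) -> float:
    """Root mean square deviation √⟨(pred − ref)²⟩.

    NaNs (from flagged saturated predictions) propagate to the result: a
    failed window reports NaN rather than silently shrinking the average.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - ref) ** 2)))


@dataclass(frozen=True)
class WindowedError:
    """Per-window RMSE values with their median and interquartile range."""

    window_ms: float
    values: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.values.size

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def iqr(self) -> float:
        q1, q3 = np.percentile(self.values, [25.0, 75.0])
        return float(q3 - q1)


def rmse_windows(pred, ref, dt: float, window_ms: float) -> WindowedError:
    """Partition into consecutive windows of `window_ms` and compute RMSE each.

    A trailing partial window is dropped (logged).  Window count is
    floor(duration / window_ms).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("length mismatch")
    span = int(round(window_ms / dt))
    if span <= 0 or span > pred.size:
        raise ValueError("window longer than the series")
    n_win = pred.size // span
    dropped = pred.size - n_win * span
    if dropped:
        logger.debug("dropping trailing partial window of %d samples", dropped)
    vals = np.array(
        [rmse(pred[i * span : (i + 1) * span], ref[i * span : (i + 1) * span]) for i in range(n_win)]
    )
    return WindowedError(window_ms, vals)


def crossover_points(grid, median_a, median_b) -> list:
    """Grid intervals bracketing sign changes of median_a − median_b.

    Returns a list of (grid[i], grid[i+1]) pairs; empty if one system wins
    everywhere.  NaN cells (failed runs) break monotonicity tracking and are
    skipped pairwise.
    """
    grid = np.asarray(grid, dtype=float)
    a = np.asarray(median_a, dtype=float)
    b = np.asarray(median_b, dtype=float)
    if not (grid.size == a.size == b.size):
        raise ValueError("grid and medians must share length")
    diff = a - b
    out = []
    prev = None
    prev_idx = None
    for i, d in enumerate(diff):
        if not np.isfinite(d) or d == 0:
            continue
        s = np.sign(d)
        if prev is not None and s != prev:
            out.append((float(grid[prev_idx]), float(grid[i])))
        prev, prev_idx = s, i
    return out


def gate_recovery_metrics(corrected, raw, reference) -> dict:
    """Per-gate RMSE of corrected and raw surrogate gates vs the reference.

    All inputs are (n, 3) arrays in (m, h, n) order.  The improvement ratio
    is corrected/raw RMSE: < 1 means the hybrid moved the hidden states
    toward the truth.
    """
    corrected = np.asarray(corrected, dtype=float)
    raw = np.asarray(raw, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not (corrected.shape == raw.shape == reference.shape):
        raise ValueError("length mismatch")
    out = {}
    for j, name in enumerate(("m", "h", "n")):
        c = rmse(corrected[:, j], reference[:, j])
        r = rmse(raw[:, j], reference[:, j])
        out[name] = {
            "corrected_rmse": c,
            "raw_rmse": r,
            "ratio": c / r if r > 0 else (0.0 if c == 0 else np.inf),
        }
    return out
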