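"""Transient/steady-state windowing and correlation analysis.

The immediate response to stress is synchronized across cells (the
transient phase); the sustained pulsing afterwards is stochastic and
unsynchronized (the steady-state phase).  Correlation statistics are
computed on the steady-state segment only, with the steady-state start
defined as twice the median end time of the transient pulses (measured from
stress arrival).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trace

DEFAULT_MAX_LAG_MIN = 30.0
TRANSIENT_WINDOW_MIN = 8.0


@dataclass
class SteadyStateWindow:
    stress_time_min: float
    steady_start_min: float
    transient_end_times: np.ndarray
    fallback_used: bool = False


def steady_state_start(pulse_df, stress_time: float,
                       transient_window_min: float = TRANSIENT_WINDOW_MIN,
                       fallback_min: float = 30.0) -> SteadyStateWindow:
    """Locate the start of the steady-state response.

    Transient pulses are those whose peak lies within ``transient_window_min``
    after stress arrival; the steady-state start is stress_time + 2 x the
    median of their right-edge times (relative to stress arrival).  With no
    transient pulses the configured fallback offset is used and flagged.
    """
    peaks = pulse_df["peak_time_min"].to_numpy(dtype=float)
    rights = pulse_df["right_edge_min"].to_numpy(dtype=float)
    mask = (peaks > stress_time) & (peaks <= stress_time + transient_window_min)
    ends = rights[mask] - stress_time
    if ends.size == 0:
        return SteadyStateWindow(stress_time, stress_time + fallback_min,
                                 ends, fallback_used=True)
    return SteadyStateWindow(stress_time, stress_time + 2.0 * float(np.median(ends)),
                             ends)


def autocorrelation_single(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag.

    Mean-subtracted with the 1/n (biased) normalization, matching the
    default estimator of the standard ``acf`` implementations, so ACF(0)=1.
    """
    x = np.asarray(values, dtype=float)
    d = x - x.mean()
    c0 = float(d @ d)
    if c0 == 0:
        raise ValueError("zero-variance trace")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = float(d[: x.size - k] @ d[k:]) / c0
    return out


def crosscorrelation_single(x: np.ndarray, y: np.ndarray, max_lag: int
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Biased cross-correlation of two equal-length series at lags -L..L.

    CCF(x, y)(k) correlates x at time t with y at time t+k, normalized by
    the biased standard deviations, so CCF(x, y)(k) = CCF(y, x)(-k).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = x.size * np.sqrt((dx @ dx) / x.size) * np.sqrt((dy @ dy) / y.size)
    if denom == 0:
        raise ValueError("zero variance in a channel")
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            out[i] = float(dx[: x.size - k] @ dy[k:]) / denom
        else:
            out[i] = float(dx[-k:] @ dy[: x.size + k]) / denom
    return lags, out


def _population(per_cell: np.ndarray, n_boot: int, seed: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    mean = per_cell.mean(axis=0)
    idx = rng.integers(0, per_cell.shape[0], size=(n_boot, per_cell.shape[0]))
    boots = per_cell[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return mean, lo, hi


def autocorrelation(traces: list[Trace], max_lag_min: float = DEFAULT_MAX_LAG_MIN,
                    n_boot: int = 1000, seed: int = 0):
    """Per-cell autocorrelations, their mean, and a 95% bootstrap CI.

    Lags run in integer frames up to ``max_lag_min`` (15 frames at 2-min
    spacing for the default 30-min maximum lag); the CI resamples cells.
    """
    dt = traces[0].dt
    max_lag = int(round(max_lag_min / dt))
    per_cell = np.stack([autocorrelation_single(tr.values, max_lag) for tr in traces])
    mean, lo, hi = _population(per_cell, n_boot, seed)
    lags_min = np.arange(max_lag + 1) * dt
    return lags_min, per_cell, mean, lo, hi


def crosscorrelation(traces2: list[Trace], traces4: list[Trace],
                     max_lag_min: float = DEFAULT_MAX_LAG_MIN,
                     n_boot: int = 1000, seed: int = 0):
    """Population cross-correlation between paired channel traces."""
    if len(traces2) != len(traces4):
        raise ValueError("need paired traces per cell")
    dt = traces2[0].dt
    max_lag = int(round(max_lag_min / dt))
    per_cell = np.stack([
        crosscorrelation_single(a.values, b.values, max_lag)[1]
        for a, b in zip(traces2, traces4)
    ])
    mean, lo, hi = _population(per_cell, n_boot, seed)
    lags_min = np.arange(-max_lag, max_lag + 1) * dt
    return lags_min, per_cell, mean, lo, hi
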