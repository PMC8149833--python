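"""Pulse-triggered averaging of nascent transcription.

The transcriptional response to one TF pulse is the maximum reporter
fluorescence within 8 min after the pulse minus the mean within 8 min
before it.  Responses are averaged by pulse context (co-pulse, Msn2-only,
Msn4-only) with bootstrap CIs; binning only-pulses by area probes whether
the promoter response is saturated at the single-pulse level (flat bins)
or dose-dependent (increasing bins).

Triggers are anchored at the pulse peak (the most precisely estimated
landmark); for co-pulses, at the mean of the two peak times.  An
edge-anchored variant is available via ``anchor="left_edge"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Trace

DEFAULT_WINDOW_MIN = 8.0


class CoverageError(ValueError):
    """Reporter trace does not cover the triggering window."""


def pulse_triggered_response(reporter: Trace, anchor_time: float,
                             pre_window_min: float = DEFAULT_WINDOW_MIN,
                             post_window_min: float = DEFAULT_WINDOW_MIN) -> float:
    """max over (anchor, anchor+post] minus mean over [anchor-pre, anchor)."""
    t = reporter.times
    if t[0] > anchor_time - pre_window_min or t[-1] < anchor_time + post_window_min:
        raise CoverageError(
            f"reporter does not cover [{anchor_time - pre_window_min:g}, "
            f"{anchor_time + post_window_min:g}] min")
    post = (t > anchor_time) & (t <= anchor_time + post_window_min)
    pre = (t >= anchor_time - pre_window_min) & (t < anchor_time)
    if not post.any() or not pre.any():
        raise CoverageError("no frames in a triggering window")
    return float(reporter.values[post].max() - reporter.values[pre].mean())


def collect_triggered_events(reporter: Trace, pulse_df: pd.DataFrame,
                             classes2: np.ndarray, classes4: np.ndarray,
                             anchor: str = "peak",
                             pre_window_min: float = DEFAULT_WINDOW_MIN,
                             post_window_min: float = DEFAULT_WINDOW_MIN
                             ) -> tuple[pd.DataFrame, int]:
    """Measure the triggered response for each classified pulse of one cell.

    ``pulse_df`` holds the cell's pulses (both channels, time-sorted per
    channel) and ``classes2``/``classes4`` the per-pulse context labels.
    Ambiguous pulses are skipped; co-pulses are collapsed to one event
    anchored at the mean of the two peaks.  Returns (events, n_dropped) with
    columns class, anchor_min, area, response; events whose window falls off
    the reporter trace are dropped and counted.
    """
    p2 = pulse_df[pulse_df["channel"] == "MSN2"].sort_values("peak_time_min")
    p4 = pulse_df[pulse_df["channel"] == "MSN4"].sort_values("peak_time_min")
    anchors: list[tuple[str, float, float]] = []
    co_times4 = p4["peak_time_min"].to_numpy()
    used4 = np.zeros(len(p4), dtype=bool)
    for (row, cls) in zip(p2.itertuples(index=False), classes2):
        a = row.peak_time_min if anchor == "peak" else row.left_edge_min
        if cls == "co_pulse":
            j = int(np.argmin(np.abs(co_times4 - row.peak_time_min)))
            used4[j] = True
            other = p4.iloc[j]
            a2 = other.peak_time_min if anchor == "peak" else other.left_edge_min
            anchors.append(("co_pulse", (a + a2) / 2.0, row.area + float(other.area)))
        elif cls == "msn2_only":
            anchors.append(("msn2_only", a, row.area))
    for k, (row, cls) in enumerate(zip(p4.itertuples(index=False), classes4)):
        if cls == "msn4_only" and not used4[k]:
            a = row.peak_time_min if anchor == "peak" else row.left_edge_min
            anchors.append(("msn4_only", a, row.area))
    rows = []
    dropped = 0
    for cls, a, area in anchors:
        try:
            resp = pulse_triggered_response(reporter, a, pre_window_min, post_window_min)
        except CoverageError:
            dropped += 1
            continue
        rows.append({"class": cls, "anchor_min": a, "area": area, "response": resp})
    return pd.DataFrame(rows, columns=["class", "anchor_min", "area", "response"]), dropped


@dataclass
class ClassAverage:
    label: str
    mean: float
    ci_low: float
    ci_high: float
    n_events: int
    degenerate: bool = False


def triggered_average_by_class(events: pd.DataFrame, n_boot: int = 1000,
                               seed: int = 0) -> dict[str, ClassAverage]:
    """Per-class mean triggered response with 95% percentile bootstrap CIs.

    Classes with a single event are returned with a degenerate CI flag;
    empty classes are omitted.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for label, grp in events.groupby("class"):
        r = grp["response"].to_numpy(dtype=float)
        if r.size == 1:
            out[label] = ClassAverage(label, float(r[0]), float(r[0]), float(r[0]),
                                      1, degenerate=True)
            continue
        idx = rng.integers(0, r.size, size=(n_boot, r.size))
        boots = r[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[label] = ClassAverage(label, float(r.mean()), float(lo), float(hi), r.size)
    return out


def bin_by_area(events: pd.DataFrame, n_bins: int = 5, n_boot: int = 1000,
                seed: int = 0) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Equal-count area bins of only-pulses with per-bin mean responses.

    Returns the per-bin table (area_mid, mean, ci_low, ci_high, n) and the
    OLS slope of response on area with its 95% CI — a flat (saturated)
    dose-response gives a slope CI containing zero, an unsaturated one a
    positive slope.
    """
    if len(events) < n_bins:
        raise ValueError("fewer events than bins")
    rng = np.random.default_rng(seed)
    areas = events["area"].to_numpy(dtype=float)
    resp = events["response"].to_numpy(dtype=float)
    if np.ptp(areas) == 0:
        bins = pd.Series(np.zeros(areas.size, dtype=int))
    else:
        bins = pd.qcut(areas, q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b in sorted(pd.unique(bins)):
        mask = np.asarray(bins == b)
        r = resp[mask]
        if r.size > 1:
            idx = rng.integers(0, r.size, size=(n_boot, r.size))
            boots = r[idx].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        else:
            lo = hi = float(r[0])
        rows.append({"bin": int(b), "area_mid": float(np.median(areas[mask])),
                     "mean": float(r.mean()), "ci_low": float(lo),
                     "ci_high": float(hi), "n": int(r.size)})
    table = pd.DataFrame(rows)
    if np.ptp(areas) == 0:
        return table, (float("nan"), float("nan"), float("nan"))
    fit = sm.OLS(resp, sm.add_constant(areas)).fit()
    slope = float(fit.params[1])
    slo, shi = fit.conf_int()[1]
    return table, (slope, float(slo), float(shi))
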