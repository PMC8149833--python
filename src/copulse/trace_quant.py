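"""Pixel- and trace-level quantification operators.

These reproduce the image-derived scalar scores used throughout the
analysis: the nuclear-localization score (mean of the five brightest pixels
minus the median of all pixels), the focus-compactness criterion on the top
ten brightest pixels, cubic background subtraction on non-positive frames,
the transient response amplitude around stress arrival, and the maximum
z-projection score for the nascent-transcription reporter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Trace

#: default compactness threshold in pixel units (the underlying criterion is
#: empirical; always config-exposed).
DEFAULT_COMPACTNESS_THRESHOLD = 3.0


@dataclass
class PixelSet:
    """Fluorescence values with 2-D pixel coordinates for one cell/frame."""

    values: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pixel values must be finite")
        if self.coords.shape != (self.values.size, 2):
            raise ValueError("coords must be (n_pixels, 2)")


def read_pixel_sets(path: str | Path, sep: str = ","
                    ) -> dict[tuple[str, int], PixelSet]:
    """Read per-cell pixel tables (cell_id, frame, x, y, value).

    Returns a dict keyed by (cell_id, frame).
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ("cell_id", "frame", "x", "y", "value")
               if c not in df.columns]
    if missing:
        raise ValueError(f"pixel table missing columns: {missing}")
    out = {}
    for (cell, frame), grp in df.groupby(["cell_id", "frame"], sort=True):
        out[(str(cell), int(frame))] = PixelSet(
            grp["value"].to_numpy(dtype=float),
            grp[["x", "y"]].to_numpy(dtype=float))
    return out


def _brightest_indices(values: np.ndarray, k: int) -> np.ndarray:
    # ties among "brightest" broken by pixel index for determinism
    order = np.lexsort((np.arange(values.size), -values))
    return order[:k]


def nuclear_localization_score(pixels: PixelSet) -> float:
    """Mean of the five brightest pixels minus the median of all pixels."""
    if pixels.values.size < 5:
        raise ValueError("need at least 5 pixels")
    top5 = pixels.values[_brightest_indices(pixels.values, 5)]
    return float(top5.mean() - np.median(pixels.values))


def focus_compactness(pixels: PixelSet,
                      distance_threshold: float = DEFAULT_COMPACTNESS_THRESHOLD
                      ) -> tuple[float, bool]:
    """Mean pairwise distance of the ten brightest pixels, and the positive flag.

    The flag is true when the mean over all 45 unordered pairs of Euclidean
    distances is strictly below the threshold (a compact bright focus, i.e.
    a genuine nucleus rather than scattered noise).
    """
    if pixels.values.size < 10:
        raise ValueError("need at least 10 pixels")
    idx = _brightest_indices(pixels.values, 10)
    pts = pixels.coords[idx]
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    mean_d = float(d[np.triu_indices(10, 1)].mean())
    return mean_d, mean_d < distance_threshold


def positive_frames(frames: Sequence[PixelSet],
                    distance_threshold: float = DEFAULT_COMPACTNESS_THRESHOLD
                    ) -> np.ndarray:
    """Per-frame positive-localization flags from focus compactness."""
    return np.array([focus_compactness(f, distance_threshold)[1] for f in frames])


def subtract_background(trace: Trace) -> Trace:
    """Remove slow baseline drift by a least-squares cubic fit.

    The cubic is fitted only to frames not flagged positive (so genuine
    pulses do not drag the baseline up), then evaluated and subtracted at
    every frame.  Positive flags are preserved.
    """
    # frames NOT flagged positive are the background sample; without flag
    # information every frame contributes
    usable = np.ones(len(trace), dtype=bool) if trace.positive is None \
        else ~trace.positive
    if usable.sum() < 4:
        raise ValueError("need at least 4 non-positive frames for a cubic fit")
    coeffs = np.polyfit(trace.times[usable], trace.values[usable], deg=3)
    background = np.polyval(coeffs, trace.times)
    return Trace(trace.cell_id, trace.channel, trace.times,
                 trace.values - background, positive=trace.positive)


def transient_response_amplitude(trace: Trace, stress_time: float,
                                 window_min: float = 20.0) -> float:
    """Stress-response amplitude around stress arrival.

    Maximum signal within ``window_min`` after the stress (exclusive of the
    stress frame itself) minus the median signal within ``window_min``
    before it.  Windows are half-open, peak-side inclusive:
    max over (t_s, t_s + w] minus median over [t_s - w, t_s).
    """
    t = trace.times
    if t[0] > stress_time - window_min or t[-1] < stress_time + window_min:
        raise ValueError("trace does not cover the stress window")
    post = (t > stress_time) & (t <= stress_time + window_min)
    pre = (t >= stress_time - window_min) & (t < stress_time)
    if not post.any() or not pre.any():
        raise ValueError("no frames in the stress window")
    return float(trace.values[post].max() - np.median(trace.values[pre]))


def pcp_activity(zstack: Sequence[PixelSet]) -> float:
    """Nascent-transcription score from a z-stack.

    Maximum z-projection per pixel across slices, then the
    nuclear-localization score of the projection.
    """
    if len(zstack) < 1:
        raise ValueError("need at least one z-slice")
    coords = zstack[0].coords
    for sl in zstack[1:]:
        if sl.coords.shape != coords.shape or not np.allclose(sl.coords, coords):
            raise ValueError("z-slices must share pixel coordinates")
    projected = np.max(np.stack([sl.values for sl in zstack]), axis=0)
    return nuclear_localization_score(PixelSet(projected, coords))
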