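"""Containers, table formats, configuration and the pipeline driver.

All time-series data move through the package as :class:`Trace` objects or as
long-format delimited tables with columns ``cell_id, time_min, channel, value``.
Times are always minutes on a regular grid (2-min frame spacing by default,
matching the acquisition rate the analysis assumes).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TRACE_COLUMNS = ("cell_id", "time_min", "channel", "value")

#: channel names used throughout: the two transcription factors, the nascent
#: transcription reporter, and the live/dead dye.
CHANNELS = ("MSN2", "MSN4", "PCP", "DRAQ7")


class TraceError(ValueError):
    """Malformed trace input (irregular grid, missing columns, ...)."""


@dataclass
class Trace:
    """One cell x one channel time series on a regular time grid.

    Parameters
    ----------
    cell_id : str
        Cell identifier.
    channel : str
        Channel name (e.g. ``"MSN2"``).
    times : ndarray
        Strictly increasing times in minutes with constant spacing.
    values : ndarray
        Fluorescence values (arbitrary units), same length as ``times``.
    positive : ndarray of bool, optional
        Per-frame flag marking frames with a genuine nuclear-localization
        focus (used to exclude pulse frames from background fitting and to
        gate candidate peaks).  ``None`` means no focus information: every
        frame is usable for background fitting and no peak is gated out.
    """

    cell_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    positive: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise TraceError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise TraceError(f"times not strictly increasing for cell {self.cell_id}")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
                raise TraceError(
                    f"irregular frame spacing for cell {self.cell_id} "
                    f"channel {self.channel}"
                )
        if self.positive is not None:
            self.positive = np.asarray(self.positive, dtype=bool)
            if self.positive.shape != self.times.shape:
                raise TraceError("positive flags must match times in length")

    @property
    def dt(self) -> float:
        """Frame spacing in minutes."""
        if self.times.size < 2:
            raise TraceError("need at least two frames to define a spacing")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


def traces_to_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    """Stack traces into the long table format."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_min": tr.times,
                    "channel": tr.channel,
                    "value": tr.values,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=list(TRACE_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame, spacing_tol: float = 1e-6) -> list[Trace]:
    """Split a long table into validated :class:`Trace` objects.

    Raises
    ------
    TraceError
        If required columns are missing or a cell/channel grid has a gap;
        the error names the offending cell and time.
    """
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"trace table missing columns: {missing}")
    traces = []
    for (cell, channel), grp in df.groupby(["cell_id", "channel"], sort=True):
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        if t.size >= 3:
            steps = np.diff(t)
            bad = np.nonzero(np.abs(steps - np.median(steps)) > spacing_tol)[0]
            if bad.size:
                raise TraceError(
                    f"cell {cell} channel {channel}: missing/irregular frame "
                    f"near t={t[bad[0]]:g} min"
                )
        traces.append(Trace(str(cell), str(channel), t, grp["value"].to_numpy(dtype=float)))
    return traces


def read_traces(path: str | Path, sep: str = ",") -> list[Trace]:
    """Read a long-format trace table from delimited text."""
    return frame_to_traces(pd.read_csv(path, sep=sep))


def write_traces(traces: Iterable[Trace], path: str | Path, sep: str = ",") -> None:
    traces_to_frame(traces).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# seeds and configuration

def derive_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage sub-seed below 2**31.

    Every stochastic stage of the pipeline receives its own seed derived from
    the single global seed so stages can be re-run independently.
    """
    h = np.uint32(2166136261)
    for ch in label.encode():
        h = np.uint32((int(h) ^ ch) * 16777619 & 0xFFFFFFFF)
    return int((np.uint64(global_seed) * np.uint64(2654435761) + np.uint64(h)) % np.uint64(2**31 - 1))


_CONFIG_SECTIONS = {
    "paths", "synth", "model", "detect", "coincidence", "correlate",
    "triggered", "survival", "redundancy", "seed", "log_level", "stages",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one section per stage)."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    coincidence: dict = field(default_factory=dict)
    correlate: dict = field(default_factory=dict)
    triggered: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    redundancy: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: ["synth", "detect", "coincidence"])
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        unknown = set(data) - _CONFIG_SECTIONS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(data)


# ---------------------------------------------------------------------------
# pipeline driver

def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the configured stages end to end and write all output tables.

    Stages: ``synth`` (ground-truthed synthetic traces) or ``model``
    (stochastic two-kinase simulation) to produce traces, then ``detect``
    (pulse table), then ``coincidence`` (per-cell summaries and population
    estimates).  A machine-readable manifest records parameters and seeds.

    Returns a dict of output table paths keyed by stage.
    """
    from . import coincidence as coin
    from . import pulse_detect, synth
    from . import model as model_mod

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    traces: list[Trace] = []

    try:
        if "synth" in config.stages:
            cfg = synth.SynthConfig(seed=derive_seed(config.seed, "synth"), **config.synth)
            events, truth = synth.generate_pulse_trains(cfg)
            traces = synth.render_cells(events, cfg)
            write_traces(traces, outdir / "traces.csv")
            truth.events.to_csv(outdir / "truth_events.csv", index=False)
            truth.cells.to_csv(outdir / "truth_cells.csv", index=False)
            outputs["traces"] = str(outdir / "traces.csv")
        elif "model" in config.stages:
            model_cfg = dict(config.model)
            n_cells = int(model_cfg.pop("n_cells", 100))
            params = model_mod.ModelParams(seed=derive_seed(config.seed, "model"), **model_cfg)
            traces = model_mod.simulate_population(params, n_cells=n_cells)
            write_traces(traces, outdir / "traces.csv")
            outputs["traces"] = str(outdir / "traces.csv")

        if "detect" in config.stages:
            params = pulse_detect.DetectionParams(**config.detect)
            pulses = []
            for tr in traces:
                if tr.channel in ("MSN2", "MSN4"):
                    pulses.extend(pulse_detect.detect_pulses(tr, params))
            pulse_df = pulse_detect.pulses_to_frame(pulses)
            pulse_df.to_csv(outdir / "pulses.csv", index=False)
            outputs["pulses"] = str(outdir / "pulses.csv")

        if "coincidence" in config.stages:
            pulse_df = pd.read_csv(outdir / "pulses.csv") if "pulses" in outputs else pd.DataFrame(
                columns=["cell_id", "channel", "peak_time_min"])
            summaries = coin.summarize_cells(pulse_df, **config.coincidence)
            summaries.to_csv(outdir / "cell_summaries.csv", index=False)
            outputs["cell_summaries"] = str(outdir / "cell_summaries.csv")
    except Exception as err:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            k: getattr(config, k)
            for k in ("synth", "model", "detect", "coincidence")
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["manifest"] = str(outdir / "manifest.json")
    return outputs
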