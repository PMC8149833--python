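"""Ground-truthed synthetic single-cell data.

Emulates the statistical structure of the microscopy and RNA-seq inputs the
downstream analysis assumes: stochastic pulse trains of two paralogous
transcription factors sampled at 2-min frames, with a controllable fraction
of shared (coincident) pulses and timing jitter; cell subpopulations with
distinct coincidence rates; a saturated OR-gate nascent-transcription
reporter; survival outcomes driven by the effective pulse number; and gene
fold-change tables mixing redundant and nonredundant targets.

Every generator is deterministic given its seed; per-cell randomness is
drawn from sub-streams spawned from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import Trace

#: jitter truncation for shared events (min); equal to the coincidence
#: tolerance so a shared event is coincident by construction.
DEFAULT_JITTER_TRUNC_MIN = 2.0

REPORTER_MODES = ("saturated_or", "msn2_specific", "msn4_specific", "additive", "linear")


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic generator.

    Rates are pulses per hour; the per-channel pulse rate is
    ``rate_shared + rate_<channel>_only``.  Defaults describe a moderately
    stressed population: ~1.5 pulses/h per factor over a 7-h movie at
    2-min frames, two thirds of them shared, triangular pulses of 6-min
    full width at half maximum and 10-fold peak signal-to-noise.
    """

    n_cells: int = 200
    duration_min: float = 420.0
    frame_interval_min: float = 2.0
    rate_shared: float = 1.0
    rate_msn2_only: float = 0.5
    rate_msn4_only: float = 0.5
    jitter_sd_min: float = 0.8
    truncate_jitter: bool = True
    refractory_min: float = 8.0
    amp_mean: float = 10.0
    amp_cv: float = 0.3
    halfmax_width_min: float = 6.0
    noise_sd: float = 1.0
    drift_coeffs: Sequence[float] = (0.0, 0.0, 0.0, 0.0)
    #: optional subpopulations: list of (weight, (rate_shared, rate2, rate4))
    mixture: Sequence[tuple] | None = None
    #: reporter burst amplitude and exponential decay time
    reporter_amp: float = 8.0
    reporter_tau_min: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.rate_shared, self.rate_msn2_only, self.rate_msn4_only)
        if any(r < 0 for r in rates):
            raise ValueError("pulse rates must be >= 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.duration_min < self.frame_interval_min:
            raise ValueError("duration too short for a single frame")
        n = self.duration_min / self.frame_interval_min
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of the frame interval")
        if self.mixture is not None:
            w = sum(m[0] for m in self.mixture)
            if abs(w - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration_min / self.frame_interval_min)) + 1
        return np.arange(n) * self.frame_interval_min


@dataclass
class GroundTruth:
    """True event records and per-cell summaries.

    ``events`` has one row per rendered pulse: cell_id, channel, time_min,
    amplitude, shared flag, event_id (shared events carry the same id in
    both channels).  ``cells`` has per-cell true counts: n2, n4, n_shared,
    total, effective, sc_rate, and the mixture component.
    """

    events: pd.DataFrame
    cells: pd.DataFrame
    genes: pd.DataFrame | None = None


def _lognormal_amps(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if cv <= 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _poisson_times(rng: np.random.Generator, rate_per_h: float, duration_min: float,
                   refractory_min: float, existing: np.ndarray,
                   max_attempts: int = 200) -> np.ndarray:
    """Homogeneous Poisson event times with a within-channel refractory gap.

    Candidate events violating the gap (against already-accepted events in
    the same channel) are rejected and redrawn.
    """
    n = rng.poisson(rate_per_h * duration_min / 60.0)
    if refractory_min <= 0:
        return np.sort(rng.uniform(0.0, duration_min, size=n))
    accepted = list(np.sort(existing))
    out = []
    for _ in range(n):
        for _ in range(max_attempts):
            t = rng.uniform(0.0, duration_min)
            if all(abs(t - a) >= refractory_min for a in accepted):
                accepted.append(t)
                out.append(t)
                break
    return np.sort(np.asarray(out))


def generate_pulse_trains(config: SynthConfig) -> tuple[dict, GroundTruth]:
    """Draw per-cell pulse trains for both transcription factors.

    Shared events arrive as one Poisson process and appear in both channels
    with independent Gaussian jitter (sd ``jitter_sd_min``, truncated to
    +/-2 min by default so that "shared" and "coincident" agree in ground
    truth).  Channel-only events arrive independently.  Events closer than
    ``refractory_min`` within a channel are rejected and redrawn.

    Returns
    -------
    events : dict
        ``events[cell_id]`` is a dict with keys ``"MSN2"``/``"MSN4"``, each a
        DataFrame of (time_min, amplitude, shared, event_id).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    cell_streams = rng.spawn(config.n_cells)

    if config.mixture is not None:
        weights = np.array([m[0] for m in config.mixture])
        comp_rates = [tuple(m[1]) for m in config.mixture]
        components = rng.choice(len(weights), size=config.n_cells, p=weights / weights.sum())
    else:
        comp_rates = [(config.rate_shared, config.rate_msn2_only, config.rate_msn4_only)]
        components = np.zeros(config.n_cells, dtype=int)

    trunc = DEFAULT_JITTER_TRUNC_MIN
    events: dict[str, dict[str, pd.DataFrame]] = {}
    event_rows = []
    cell_rows = []
    next_event_id = 0
    for i in range(config.n_cells):
        cid = f"cell{i:04d}"
        crng = cell_streams[i]
        rs, r2, r4 = comp_rates[components[i]]
        shared = _poisson_times(crng, rs, config.duration_min,
                                config.refractory_min, np.empty(0))
        # independent jitter per channel, truncated by rejection
        def _jitter(n: int) -> np.ndarray:
            if config.jitter_sd_min <= 0 or n == 0:
                return np.zeros(n)
            out = crng.normal(0.0, config.jitter_sd_min, size=n)
            if config.truncate_jitter:
                bad = np.abs(out) > trunc
                while bad.any():
                    out[bad] = crng.normal(0.0, config.jitter_sd_min, size=int(bad.sum()))
                    bad = np.abs(out) > trunc
            return out

        t2_shared = np.clip(shared + _jitter(shared.size), 0.0, config.duration_min)
        t4_shared = np.clip(shared + _jitter(shared.size), 0.0, config.duration_min)
        t2_only = _poisson_times(crng, r2, config.duration_min,
                                 config.refractory_min, t2_shared)
        t4_only = _poisson_times(crng, r4, config.duration_min,
                                 config.refractory_min, t4_shared)

        ids_shared = np.arange(next_event_id, next_event_id + shared.size)
        next_event_id += shared.size
        per_channel = {}
        for channel, t_sh, t_on in (("MSN2", t2_shared, t2_only),
                                    ("MSN4", t4_shared, t4_only)):
            n_on = t_on.size
            ids_on = np.arange(next_event_id, next_event_id + n_on)
            next_event_id += n_on
            df = pd.DataFrame({
                "time_min": np.concatenate([t_sh, t_on]),
                "amplitude": _lognormal_amps(crng, t_sh.size + n_on,
                                             config.amp_mean, config.amp_cv),
                "shared": np.concatenate([np.ones(t_sh.size, bool),
                                          np.zeros(n_on, bool)]),
                "event_id": np.concatenate([ids_shared, ids_on]),
            }).sort_values("time_min").reset_index(drop=True)
            per_channel[channel] = df
            if len(df):
                event_rows.append(df.assign(cell_id=cid, channel=channel))
        events[cid] = per_channel

        n2 = len(per_channel["MSN2"])
        n4 = len(per_channel["MSN4"])
        n_sh = shared.size
        total = n2 + n4
        cell_rows.append({
            "cell_id": cid, "component": int(components[i]),
            "n2": n2, "n4": n4, "n_shared": n_sh,
            "total": total, "effective": total - n_sh,
            "sc_rate": (2.0 * n_sh / total) if total > 0 else np.nan,
        })

    cols = ["cell_id", "channel", "time_min", "amplitude", "shared", "event_id"]
    truth = GroundTruth(
        events=(pd.concat(event_rows, ignore_index=True)[cols]
                if event_rows else pd.DataFrame(columns=cols)),
        cells=pd.DataFrame(cell_rows),
    )
    return events, truth


def triangular_kernel(t: np.ndarray, peak_time: float, amplitude: float,
                      fwhm: float) -> np.ndarray:
    """Triangular pulse whose full width at half maximum equals ``fwhm``.

    The triangle's base half-width equals ``fwhm`` (half maximum is reached
    at ``fwhm/2`` from the apex), so half-max edge recovery has an exact
    analytic answer.
    """
    return amplitude * np.clip(1.0 - np.abs(t - peak_time) / fwhm, 0.0, None)


def render_trace(event_times: Sequence[float], config: SynthConfig,
                 amplitudes: Sequence[float] | None = None,
                 cell_id: str = "cell", channel: str = "MSN2",
                 rng: np.random.Generator | None = None) -> Trace:
    """Render events as summed triangular kernels + cubic drift + noise."""
    t = config.times
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size and (event_times.min() < 0 or event_times.max() > config.duration_min):
        raise ValueError("events must lie within [0, duration]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if amplitudes is None:
        amplitudes = _lognormal_amps(rng, event_times.size, config.amp_mean, config.amp_cv)
    values = np.zeros_like(t)
    for tau, amp in zip(event_times, np.asarray(amplitudes, float)):
        values += triangular_kernel(t, tau, amp, config.halfmax_width_min)
    c = np.asarray(config.drift_coeffs, dtype=float)
    values += np.polyval(c[::-1], t)  # drift_coeffs are (c0, c1, c2, c3)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=t.size)
    return Trace(cell_id, channel, t, values)


def render_cells(events: dict, config: SynthConfig) -> list[Trace]:
    """Render both TF channels for every cell in ``events``."""
    rng = np.random.default_rng(config.seed + 1)
    streams = rng.spawn(len(events))
    traces = []
    for crng, (cid, per_channel) in zip(streams, sorted(events.items())):
        for channel in ("MSN2", "MSN4"):
            df = per_channel[channel]
            traces.append(render_trace(df["time_min"].to_numpy(), config,
                                       amplitudes=df["amplitude"].to_numpy(),
                                       cell_id=cid, channel=channel, rng=crng))
    return traces


def effective_events(per_channel: dict) -> pd.DataFrame:
    """Collapse a cell's two channels into effective activation events.

    Shared events (same ``event_id`` in both channels) count once, anchored
    at the mean of the two jittered peak times; channel-only events count
    individually.  Columns: time_min, kind in {co, msn2_only, msn4_only},
    amplitude (max of the pair for shared), area-proxy amplitude.
    """
    df2, df4 = per_channel["MSN2"], per_channel["MSN4"]
    shared_ids = set(df2.loc[df2["shared"], "event_id"]) & set(df4.loc[df4["shared"], "event_id"])
    rows = []
    t4_by_id = df4.set_index("event_id")
    for row in df2.itertuples(index=False):
        if row.shared and row.event_id in shared_ids:
            other = t4_by_id.loc[row.event_id]
            rows.append(((row.time_min + float(other["time_min"])) / 2.0, "co",
                         max(row.amplitude, float(other["amplitude"]))))
        else:
            rows.append((row.time_min, "msn2_only", row.amplitude))
    for row in df4.itertuples(index=False):
        if not (row.shared and row.event_id in shared_ids):
            rows.append((row.time_min, "msn4_only", row.amplitude))
    out = pd.DataFrame(rows, columns=["time_min", "kind", "amplitude"])
    return out.sort_values("time_min").reset_index(drop=True)


def generate_reporter(per_channel: dict, response_mode: str, config: SynthConfig,
                      cell_id: str = "cell",
                      rng: np.random.Generator | None = None) -> Trace:
    """Render the nascent-transcription (PCP) reporter for one cell.

    Modes
    -----
    ``saturated_or``
        Every effective pulse (a co-pulse counts once) triggers a burst of
        fixed mean amplitude ``reporter_amp`` decaying exponentially; this is
        the OR-gate saturation regime in which single-TF pulses and co-pulses
        produce comparable responses.
    ``msn2_specific`` / ``msn4_specific``
        Only pulses containing the named factor trigger a burst.
    ``additive``
        Per-TF contributions sum, so a co-pulse yields twice the burst.
    ``linear``
        Unsaturated control: burst amplitude scales with the pulse area
        (amplitude x FWHM) relative to the mean pulse area.
    """
    if response_mode not in REPORTER_MODES:
        raise ValueError(f"unknown response_mode {response_mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    t = config.times
    values = np.zeros_like(t)
    eff = effective_events(per_channel)
    a_rep = config.reporter_amp
    ref_area = config.amp_mean * config.halfmax_width_min
    for row in eff.itertuples(index=False):
        if response_mode == "saturated_or":
            amp = a_rep
        elif response_mode == "msn2_specific":
            amp = a_rep if row.kind in ("co", "msn2_only") else 0.0
        elif response_mode == "msn4_specific":
            amp = a_rep if row.kind in ("co", "msn4_only") else 0.0
        elif response_mode == "additive":
            amp = 2.0 * a_rep if row.kind == "co" else a_rep
        else:  # linear
            amp = a_rep * (row.amplitude * config.halfmax_width_min) / ref_area
            if row.kind == "co":
                amp *= 2.0
        if amp > 0:
            mask = t >= row.time_min
            values[mask] += amp * np.exp(-(t[mask] - row.time_min) / config.reporter_tau_min)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=t.size)
    return Trace(cell_id, "PCP", t, values)


def generate_survival(summaries: pd.DataFrame, beta0: float, beta1: float,
                      horizon_h: float = 6.0, seed: int = 0) -> pd.DataFrame:
    """Draw survival outcomes: P(survive) = logistic(beta0 + beta1*effective).

    ``summaries`` needs columns cell_id and effective.  Non-survivors get a
    death time uniform over the horizon.  ``beta1 > 0`` makes survival
    increase with the effective pulse number.
    """
    rng = np.random.default_rng(seed)
    eff = summaries["effective"].to_numpy(dtype=float)
    p = expit(beta0 + beta1 * eff)
    survived = rng.uniform(size=eff.size) < p
    death = np.where(survived, np.nan, rng.uniform(0.0, horizon_h, size=eff.size))
    return pd.DataFrame({
        "cell_id": summaries["cell_id"].to_numpy(),
        "survived_horizon": survived,
        "death_time_h": death,
        "p_survive": p,
    })


def generate_foldchange_table(n_redundant: int, n_nonredundant: int,
                              noise_cv: float = 0.2, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stress/non-stress fold-change triples for three genotypes.

    Redundant genes are activated to the same level (>= 1.2-fold) in wild
    type and in either single mutant (each paralog alone saturates the
    target).  Nonredundant genes require both paralogs: activation collapses
    toward 1 in both single mutants, so the classification rule
    (fc_msn2 + fc_msn4 > fc_wt) correctly labels them for activations
    comfortably above 2.  Multiplicative lognormal noise of CV ``noise_cv``
    is applied per measurement.

    Returns (table, truth) where truth carries the generating label.
    """
    if n_redundant < 0 or n_nonredundant < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    act_red = np.maximum(_lognormal_amps(rng, n_redundant, 3.0, 0.4), 1.25)
    act_non = rng.uniform(3.0, 8.0, size=n_nonredundant)

    def _noise(n):
        return _lognormal_amps(rng, n, 1.0, noise_cv) if noise_cv > 0 else np.ones(n)

    for i, a in enumerate(act_red):
        fc = a * _noise(3)
        rows.append((f"RED{i:04d}", fc[0], fc[1], fc[2]))
        truth_rows.append((f"RED{i:04d}", "redundant"))
    for i, a in enumerate(act_non):
        nz = _noise(3)
        rows.append((f"NON{i:04d}", a * nz[0], 1.0 * nz[1], 1.0 * nz[2]))
        truth_rows.append((f"NON{i:04d}", "nonredundant"))
    table = pd.DataFrame(rows, columns=["gene", "fc_wt", "fc_msn2", "fc_msn4"])
    truth = pd.DataFrame(truth_rows, columns=["gene", "true_label"])
    return table, truth


def generate_cell_image(n_pixels: int = 100, nucleus_fraction: float = 0.1,
                        nuclear_gain: float = 100.0, seed: int = 0,
                        background: float = 10.0, noise_sd: float = 0.0,
                        compact: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic single-cell pixel set with a compact bright nucleus.

    Returns (values, coords, true_score) where the true nuclear-localization
    score equals ``nuclear_gain`` (mean of the brightest cluster minus the
    background median) when the cluster spans >= 5 pixels.  With
    ``compact=False`` the bright pixels are scattered across the cell so the
    downstream compactness flag should be false.
    """
    if not 0 < nucleus_fraction < 1:
        raise ValueError("nucleus_fraction must be in (0, 1)")
    n_nuc = int(round(n_pixels * nucleus_fraction))
    if n_nuc < 5:
        raise ValueError("nucleus smaller than 5 pixels")
    rng = np.random.default_rng(seed)
    # pixels on a disk of radius ~sqrt(n_pixels)
    radius = np.sqrt(n_pixels / np.pi)
    coords = []
    r = int(np.ceil(radius)) + 1
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            if x * x + y * y <= radius * radius:
                coords.append((x, y))
    coords = np.asarray(coords, dtype=float)[:n_pixels]
    values = np.full(len(coords), background)
    if compact:
        center = coords[np.argmin(np.hypot(coords[:, 0], coords[:, 1]))]
        order = np.argsort(np.hypot(coords[:, 0] - center[0], coords[:, 1] - center[1]))
        nuc_idx = order[:n_nuc]
    else:
        nuc_idx = rng.choice(len(coords), size=n_nuc, replace=False)
    values[nuc_idx] += nuclear_gain
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    return values, coords, float(nuclear_gain)
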