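"""Stochastic two-kinase model of divergent paralog pulsing.

Nuclear copy numbers of the two paralogous factors obey Hill-repressed
import/export kinetics:

    dMsn2n/dt = a2 (Msn2t - Msn2n) / (1 + (PKA * kd_ratio)^n2) - b2 Msn2n
    dMsn4n/dt = a4 (Msn4t - Msn4n) / (1 + PKA^n4) / (1 + X^nX) - b4 Msn4n

where ``kd_ratio = Kd(Msn4)/Kd(Msn2)`` rescales the PKA activity seen by
Msn2 (a ratio below 1 encodes Msn2's lower affinity for PKA, so Msn2 is
derepressed by shallower PKA dips than Msn4).  A second kinase X represses
only Msn4.  Kinase activities fluctuate as periodic square events whose
amplitudes are drawn per event: PKA is up-regulated (0-10% of basal),
strongly down-regulated (0-100% of basal) or weakly down-regulated
(0-amp_weak); X is either down-regulated (0-100% of basal) or unchanged.
Strong PKA dips release both factors (a co-pulse); weak dips release only
Msn2; X dips release only Msn4 - the circuit that lets a single upstream
input tune the pulse coincidence of the paralogs.

Trajectories are simulated by the tau-leap method: per fixed step ``dt``
the four reaction counts (import/export per factor) are Poisson draws at
the current propensities, applied and clamped to the physical range.  One
model time unit maps to one minute when trajectories are exported for pulse
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import spearmanr

from . import coincidence as coin
from . import pulse_detect
from .io import Trace

PKA_SCENARIOS = ("up", "strong_down", "weak_down")

#: detection threshold (nuclear copies) used for model trajectories; model
#: traces carry demographic noise whose baseline sd differs between the two
#: factors, so a shared absolute cutoff (5% of the total copy number) is
#: used instead of a noise-scaled one.
MODEL_AMP_THRESHOLD = 10.0


@dataclass
class ModelParams:
    a2: float = 1.0
    a4: float = 1200.0
    b2: float = 2.0
    b4: float = 2.0
    n2: float = 4.0
    n4: float = 4.0
    nx: float = 4.0
    msn2_total: int = 200
    msn4_total: int = 200
    pka_basal: float = 6.0
    x_basal: float = 6.0
    kd_ratio: float = 0.5
    amp_weak: float = 4.0
    dt: float = 0.001
    duration: float = 300.0
    event_period: float = 10.0
    event_duration: float = 4.0
    pka_scenario_probs: Sequence[float] = (1 / 3, 1 / 3, 1 / 3)
    x_down_prob: float = 1 / 3
    frame_interval: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a2, self.a4, self.b2, self.b4, self.n2, self.n4, self.nx) <= 0:
            raise ValueError("rates and Hill coefficients must be positive")
        if self.msn2_total < 0 or self.msn4_total < 0:
            raise ValueError("total copy numbers must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if abs(sum(self.pka_scenario_probs) - 1.0) > 1e-9:
            raise ValueError("PKA scenario probabilities must sum to 1")


def hill_repression(activity, n):
    """Repression factor 1/(1 + activity^n) in (0, 1]."""
    return 1.0 / (1.0 + np.asarray(activity, dtype=float) ** n)


def rhs(state: Sequence[float], params: ModelParams, pka_now: float,
        x_now: float) -> tuple[float, float]:
    """Deterministic time derivatives of (Msn2n, Msn4n)."""
    m2, m4 = state
    h2 = hill_repression(pka_now * params.kd_ratio, params.n2)
    h4 = hill_repression(pka_now, params.n4) * hill_repression(x_now, params.nx)
    d2 = params.a2 * (params.msn2_total - m2) * h2 - params.b2 * m2
    d4 = params.a4 * (params.msn4_total - m4) * h4 - params.b4 * m4
    return float(d2), float(d4)


@dataclass
class KinaseProgram:
    """Per-cell square-wave kinase activity programs.

    Events occur on a shared clock (one event per ``event_period``, lasting
    ``event_duration``); each event independently gets a PKA scenario and,
    with probability ``x_down_prob``, an X down-regulation.  Amplitudes are
    drawn per event from the ranges stated in the model description;
    activities are clipped at zero.
    """

    event_starts: np.ndarray
    event_duration: float
    pka_basal: float
    x_basal: float
    #: (n_cells, n_events) arrays
    pka_delta: np.ndarray
    x_delta: np.ndarray
    pka_scenario: np.ndarray = field(default=None)

    @property
    def n_cells(self) -> int:
        return self.pka_delta.shape[0]

    def activities_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(PKA, X) activity vectors across cells at model time ``t``."""
        pka = np.full(self.n_cells, self.pka_basal)
        x = np.full(self.n_cells, self.x_basal)
        k = int(np.floor(t / (self.event_starts[1] - self.event_starts[0]))) \
            if self.event_starts.size > 1 else 0
        if 0 <= k < self.event_starts.size and \
                self.event_starts[k] <= t < self.event_starts[k] + self.event_duration:
            pka = np.clip(pka + self.pka_delta[:, k], 0.0, None)
            x = np.clip(x + self.x_delta[:, k], 0.0, None)
        return pka, x


def generate_kinase_program(params: ModelParams, n_cells: int = 1,
                            rng: np.random.Generator | None = None) -> KinaseProgram:
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_events = int(np.floor(params.duration / params.event_period))
    starts = np.arange(n_events) * params.event_period
    scen = rng.choice(3, size=(n_cells, n_events), p=np.asarray(params.pka_scenario_probs))
    u = rng.uniform(size=(n_cells, n_events))
    pka_delta = np.where(
        scen == 0, 0.1 * params.pka_basal * u,                   # up: +U(0, 0.1*basal)
        np.where(scen == 1, -params.pka_basal * u,               # strong down
                 -params.amp_weak * u))                          # weak down
    x_down = rng.uniform(size=(n_cells, n_events)) < params.x_down_prob
    x_delta = np.where(x_down, -params.x_basal * rng.uniform(size=(n_cells, n_events)), 0.0)
    return KinaseProgram(starts, params.event_duration, params.pka_basal,
                         params.x_basal, pka_delta, x_delta, pka_scenario=scen)


def _segments(params: ModelParams, program: KinaseProgram):
    """Time segments with piecewise-constant kinase activities."""
    cuts = {0.0, params.duration}
    for s in program.event_starts:
        cuts.add(float(s))
        cuts.add(float(min(s + program.event_duration, params.duration)))
    cuts = sorted(cuts)
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi > lo:
            yield lo, hi


def simulate_population(params: ModelParams, n_cells: int,
                        program: KinaseProgram | None = None,
                        return_traces: bool = True,
                        rng: np.random.Generator | None = None):
    """Tau-leap simulation of ``n_cells`` independent cells.

    Cells share the event clock but have independent scenario/amplitude
    draws.  Returns a list of :class:`Trace` (both channels per cell, times
    in minutes on the ``frame_interval`` grid) or, with
    ``return_traces=False``, the raw sample arrays.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if program is None:
        program = generate_kinase_program(params, n_cells, rng)
    # leap-condition check at basal kinase activities: mean reaction counts
    # per step should stay well below 1 most of the time
    h2b = float(hill_repression(params.pka_basal * params.kd_ratio, params.n2))
    h4b = float(hill_repression(params.pka_basal, params.n4)
                * hill_repression(params.x_basal, params.nx))
    m2_eq = params.msn2_total * params.a2 * h2b / (params.a2 * h2b + params.b2)
    m4_eq = params.msn4_total * params.a4 * h4b / (params.a4 * h4b + params.b4)
    basal_prop = max(params.a2 * (params.msn2_total - m2_eq) * h2b,
                     params.b2 * m2_eq,
                     params.a4 * (params.msn4_total - m4_eq) * h4b,
                     params.b4 * m4_eq) * params.dt
    if basal_prop >= 0.1:
        warnings.warn("tau-leap step too coarse: basal propensity*dt >= 0.1",
                      stacklevel=2)

    m2 = np.zeros(n_cells)
    m4 = np.zeros(n_cells)
    n_frames = int(np.floor(params.duration / params.frame_interval)) + 1
    rec2 = np.zeros((n_cells, n_frames))
    rec4 = np.zeros((n_cells, n_frames))
    rec2[:, 0] = m2
    rec4[:, 0] = m4
    clamped = 0
    steps_total = 0
    next_frame = 1
    next_frame_t = params.frame_interval
    t = 0.0
    lam = np.empty((4, n_cells))
    for lo, hi in _segments(params, program):
        pka, x = program.activities_at(lo)
        imp2_coef = params.a2 * hill_repression(pka * params.kd_ratio, params.n2) * params.dt
        imp4_coef = params.a4 * (hill_repression(pka, params.n4)
                                 * hill_repression(x, params.nx)) * params.dt
        exp2_coef = params.b2 * params.dt
        exp4_coef = params.b4 * params.dt
        n_steps = int(round((hi - lo) / params.dt))
        for _ in range(n_steps):
            np.multiply(imp2_coef, params.msn2_total - m2, out=lam[0])
            np.multiply(exp2_coef, m2, out=lam[1])
            np.multiply(imp4_coef, params.msn4_total - m4, out=lam[2])
            np.multiply(exp4_coef, m4, out=lam[3])
            draws = rng.poisson(lam)
            m2 += draws[0] - draws[1]
            m4 += draws[2] - draws[3]
            bad = (m2 < 0) | (m2 > params.msn2_total) | (m4 < 0) | (m4 > params.msn4_total)
            if bad.any():
                clamped += int(bad.sum())
                np.clip(m2, 0, params.msn2_total, out=m2)
                np.clip(m4, 0, params.msn4_total, out=m4)
            steps_total += n_cells
            t += params.dt
            if t >= next_frame_t - params.dt / 2 and next_frame < n_frames:
                rec2[:, next_frame] = m2
                rec4[:, next_frame] = m4
                next_frame += 1
                next_frame_t += params.frame_interval
    clamp_fraction = clamped / max(steps_total, 1)
    times = np.arange(n_frames) * params.frame_interval
    if not return_traces:
        return times, rec2, rec4, clamp_fraction
    traces = []
    for i in range(n_cells):
        cid = f"sim{i:04d}"
        traces.append(Trace(cid, "MSN2", times, rec2[i]))
        traces.append(Trace(cid, "MSN4", times, rec4[i]))
    return traces


def simulate_tau_leap(params: ModelParams,
                      program: KinaseProgram | None = None
                      ) -> tuple[Trace, Trace]:
    """Single-cell convenience wrapper around :func:`simulate_population`."""
    traces = simulate_population(params, 1, program=program)
    return traces[0], traces[1]


def integrate_deterministic(params: ModelParams,
                            program: KinaseProgram | None = None,
                            cell: int = 0, rtol: float = 1e-8
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """High-accuracy deterministic solution of the rate equations.

    Integrates segment-by-segment with the kinase activities of one cell of
    ``program`` (or constant basal activities when no program is given).
    Serves as the infinite-copy-number limit the tau-leap mean must approach.
    """
    t_eval = np.arange(0.0, params.duration + 1e-9, params.frame_interval)
    out2 = np.zeros_like(t_eval)
    out4 = np.zeros_like(t_eval)
    state = [0.0, 0.0]
    segments = list(_segments(params, program)) if program is not None \
        else [(0.0, params.duration)]
    k = 0
    if t_eval[0] == 0.0:
        out2[0], out4[0] = state
        k = 1
    for lo, hi in segments:
        if program is not None:
            pka_v, x_v = program.activities_at(lo)
            pka, x = float(pka_v[cell]), float(x_v[cell])
        else:
            pka, x = params.pka_basal, params.x_basal
        mask = (t_eval > lo) & (t_eval <= hi + 1e-12)
        pts = t_eval[mask]
        sol = solve_ivp(lambda t, y: rhs(y, params, pka, x), (lo, hi), state,
                        t_eval=pts if pts.size else None, rtol=rtol, atol=1e-10)
        if pts.size:
            out2[k:k + pts.size] = sol.y[0]
            out4[k:k + pts.size] = sol.y[1]
            k += pts.size
        state = [float(sol.y[0, -1]), float(sol.y[1, -1])]
    return t_eval, out2, out4


def coincidence_from_traces(traces: list[Trace],
                            amp_threshold: float = MODEL_AMP_THRESHOLD,
                            tol_min: float = 2.0) -> pd.DataFrame:
    """Detect pulses on simulated traces and summarize per-cell coincidence."""
    dp = pulse_detect.DetectionParams(amp_threshold=amp_threshold)
    pulses = []
    for tr in traces:
        pulses.extend(pulse_detect.detect_pulses(tr, dp))
    pulse_df = pulse_detect.pulses_to_frame(pulses)
    if pulse_df.empty:
        return pd.DataFrame(columns=["cell_id", "n2", "n4", "n_coinc",
                                     "total", "effective", "sc_rate"])
    return coin.summarize_cells(pulse_df, tol_min=tol_min)


def sweep(param_name: str, values: Sequence[float], n_cells: int = 200,
          params: ModelParams | None = None, seed: int = 0,
          amp_threshold: float = MODEL_AMP_THRESHOLD) -> tuple[pd.DataFrame, float, float]:
    """Coincidence-rate response to a parameter sweep.

    For each value a fresh population is simulated, pulses detected, and the
    per-cell coincidence rates summarized; the reported trend is Spearman's
    rho between the parameter value and the single-cell coincidence rate
    across all cells (with the per-level mean rates and frequency-controlled
    estimates in the returned table).

    Returns (table, rho, p_value).
    """
    if param_name not in ("pka_basal", "kd_ratio"):
        raise ValueError("sweep supports pka_basal and kd_ratio")
    if len(values) < 3:
        raise ValueError("need at least 3 sweep values")
    base = params or ModelParams()
    rows = []
    xs, ys = [], []
    for k, v in enumerate(values):
        p = ModelParams(**{**base.__dict__, param_name: float(v),
                           "seed": base.seed + 1000 * k})
        traces = simulate_population(p, n_cells)
        summaries = coincidence_from_traces(traces, amp_threshold)
        rates = summaries.loc[summaries["total"] > 0, "sc_rate"]
        lab2 = np.concatenate([
            np.concatenate([np.ones(int(r.n_coinc), bool),
                            np.zeros(int(r.n2 - r.n_coinc), bool)])
            for r in summaries.itertuples(index=False)]) if len(summaries) else np.empty(0, bool)
        lab4 = np.concatenate([
            np.concatenate([np.ones(int(r.n_coinc), bool),
                            np.zeros(int(r.n4 - r.n_coinc), bool)])
            for r in summaries.itertuples(index=False)]) if len(summaries) else np.empty(0, bool)
        est = np.nan
        ci = (np.nan, np.nan)
        if lab2.size and lab4.size:
            e = coin.population_rate_frequency_controlled(
                lab2, lab4, sample_size=min(lab2.size, lab4.size),
                seed=base.seed + 7 * k)
            est, ci = e.mean_rate, (e.ci_low, e.ci_high)
        rows.append({param_name: float(v), "mean_sc_rate": float(rates.mean()),
                     "freq_controlled_rate": est, "ci_low": ci[0],
                     "ci_high": ci[1], "n_cells_with_pulses": int(len(rates))})
        xs.extend([float(v)] * len(rates))
        ys.extend(rates.tolist())
    rho, pval = spearmanr(xs, ys)
    return pd.DataFrame(rows), float(rho), float(pval)
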