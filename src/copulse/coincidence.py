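"""Pulse-coincidence classification and rate estimation.

Two pulses of the paralogous factors are *coincident* when their peak times
differ by at most 2 min (one frame).  The module provides:

* one-to-one greedy matching of the two pulse trains,
* a frequency-controlled population rate (equal numbers of pulses per
  channel resampled with replacement, so conditions with different pulse
  frequencies are comparable),
* a chance-corrected rate with a cell-resampling bootstrap and the
  first-order expected-by-chance term
  ``(number of Msn4 pulses x overlap window) / total observation time``,
* per-cell rates and their bimodal classification by the trough of a
  kernel density estimate,
* pulse-context classification (co-pulse / only-pulse / ambiguous) for
  triggered averaging, and
* snapshot nuclear-colocalization percentages.

All bootstrap intervals are 95% percentile intervals over 1000 resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

DEFAULT_TOL_MIN = 2.0
DEFAULT_ONLY_WINDOW_MIN = 8.0
DEFAULT_N_BOOT = 1000


@dataclass
class CellPulseSummary:
    cell_id: str
    n2: int
    n4: int
    n_coinc: int

    @property
    def total(self) -> int:
        return self.n2 + self.n4

    @property
    def effective(self) -> int:
        return self.total - self.n_coinc

    @property
    def sc_rate(self) -> float:
        """Single-cell coincidence rate: both members of a coincident pair
        count as coincident pulses, so the rate is 2*n_coinc/(n2+n4)."""
        if self.total == 0:
            return float("nan")
        return 2.0 * self.n_coinc / self.total


@dataclass
class CoincidenceEstimate:
    mean_rate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    sample_size: int
    seed: int
    se: float = float("nan")


def match_pulses(times2: np.ndarray, times4: np.ndarray,
                 tol_min: float = DEFAULT_TOL_MIN
                 ) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """One-to-one matching of one cell's two pulse trains.

    Candidate pairs with |peak lag| <= tol are accepted greedily in
    ascending |lag|; ties resolved by the earlier pair (symmetric in the
    two channels, and equivalent to breaking ties by the earlier Msn2 peak
    except in degenerate constructions).  Each pulse joins at most one pair.

    Returns (pairs, labels2, labels4) with pairs as (index2, index4) and
    boolean coincidence labels per pulse.
    """
    t2 = np.asarray(times2, dtype=float)
    t4 = np.asarray(times4, dtype=float)
    cand = [(abs(a - b), a + b, min(a, b), i, j)
            for i, a in enumerate(t2) for j, b in enumerate(t4)
            if abs(a - b) <= tol_min]
    cand.sort()
    used2: set[int] = set()
    used4: set[int] = set()
    pairs = []
    for _, _, _, i, j in cand:
        if i not in used2 and j not in used4:
            pairs.append((i, j))
            used2.add(i)
            used4.add(j)
    lab2 = np.zeros(t2.size, dtype=bool)
    lab4 = np.zeros(t4.size, dtype=bool)
    for i, j in pairs:
        lab2[i] = True
        lab4[j] = True
    return pairs, lab2, lab4


def summarize_cells(pulse_df: pd.DataFrame, tol_min: float = DEFAULT_TOL_MIN,
                    steady_start: dict | float | None = None) -> pd.DataFrame:
    """Per-cell pulse counts and coincidence rates from a pulse table.

    ``steady_start`` optionally restricts to pulses at/after a start time
    (scalar or per-cell dict); pulses before it are treated as transient and
    excluded from coincidence statistics.
    """
    rows = []
    for cell, grp in pulse_df.groupby("cell_id", sort=True):
        if steady_start is not None:
            s = steady_start.get(cell, 0.0) if isinstance(steady_start, dict) else steady_start
            grp = grp[grp["peak_time_min"] >= s]
        t2 = grp.loc[grp["channel"] == "MSN2", "peak_time_min"].to_numpy()
        t4 = grp.loc[grp["channel"] == "MSN4", "peak_time_min"].to_numpy()
        pairs, _, _ = match_pulses(t2, t4, tol_min)
        s = CellPulseSummary(str(cell), t2.size, t4.size, len(pairs))
        rows.append({"cell_id": s.cell_id, "n2": s.n2, "n4": s.n4,
                     "n_coinc": s.n_coinc, "total": s.total,
                     "effective": s.effective, "sc_rate": s.sc_rate})
    return pd.DataFrame(rows, columns=["cell_id", "n2", "n4", "n_coinc",
                                       "total", "effective", "sc_rate"])


def population_rate_frequency_controlled(labels2: np.ndarray, labels4: np.ndarray,
                                         sample_size: int,
                                         n_boot: int = DEFAULT_N_BOOT,
                                         seed: int = 0) -> CoincidenceEstimate:
    """Frequency-controlled population coincidence rate.

    Per replicate, ``sample_size`` Msn2 pulses and ``sample_size`` Msn4
    pulses are drawn with replacement from the pooled labelled pulses of the
    condition; the statistic is the fraction of drawn pulses labelled
    coincident.  Using the same sample size across conditions removes the
    influence of per-condition pulse frequency on the estimate.
    """
    lab2 = np.asarray(labels2, dtype=bool)
    lab4 = np.asarray(labels4, dtype=bool)
    if lab2.size == 0 or lab4.size == 0:
        raise ValueError("a channel has zero pulses in this condition")
    rng = np.random.default_rng(seed)
    draws2 = rng.integers(0, lab2.size, size=(n_boot, sample_size))
    draws4 = rng.integers(0, lab4.size, size=(n_boot, sample_size))
    stats = (lab2[draws2].sum(axis=1) + lab4[draws4].sum(axis=1)) / (2.0 * sample_size)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return CoincidenceEstimate(float(stats.mean()), float(lo), float(hi),
                               n_boot, sample_size, seed, se=float(stats.std(ddof=1)))


def effective_sample_size(n2_pool: int, n4_pool: int,
                          shared_fraction: float = 0.5) -> int:
    """Resample size giving the frequency-controlled bootstrap nominal CIs.

    Both members of a coincident pair enter the pooled labels (one per
    channel), so the two per-channel coincident fractions are positively
    correlated: the estimator's true sampling variance is
    ``f(1-f)(2-f)/(2N)`` for pool size N per channel and coincident
    fraction f, not the binomial ``f(1-f)/(2N)`` that resampling N pulses
    per channel reproduces.  Drawing ``N/(2-f)`` pulses per channel instead
    matches the bootstrap variance to the true one.
    """
    return max(int(min(n2_pool, n4_pool) / (2.0 - shared_fraction)), 1)


def expected_by_chance(n_msn4_pulses: float, window_min: float,
                       total_time_min: float) -> float:
    """First-order expected-by-chance coincident fraction.

    ``(number of Msn4 pulses x overlap window) / total observation time``;
    the window is the full overlap-identification width (2 x tolerance =
    4 min by default).  The formula ignores multiple-hit overlap, exactly as
    a first-order estimate.
    """
    if total_time_min <= 0:
        raise ValueError("total observation time must be positive")
    return n_msn4_pulses * window_min / total_time_min


def population_rate_chance_corrected(cells: list[dict],
                                     tol_min: float = DEFAULT_TOL_MIN,
                                     n_boot: int = DEFAULT_N_BOOT,
                                     seed: int = 0) -> CoincidenceEstimate:
    """Chance-corrected population coincidence rate with a cell bootstrap.

    ``cells`` is a list of dicts with keys ``t2``, ``t4`` (peak-time arrays)
    and ``obs_min`` (per-cell observation time).  Per replicate, cells are
    resampled with replacement to the original population size; the raw
    statistic is the fraction of Msn2 pulses with an Msn4 peak within
    ``tol_min``, from which the expected-by-chance fraction (window
    ``2*tol_min``) is subtracted.  The corrected rate can be negative.
    """
    n2 = np.zeros(len(cells))
    hits = np.zeros(len(cells))
    n4 = np.zeros(len(cells))
    T = np.zeros(len(cells))
    for k, c in enumerate(cells):
        t2 = np.asarray(c["t2"], dtype=float)
        t4 = np.asarray(c["t4"], dtype=float)
        n2[k] = t2.size
        n4[k] = t4.size
        T[k] = float(c["obs_min"])
        if t2.size and t4.size:
            lags = np.abs(t2[:, None] - t4[None, :])
            hits[k] = int((lags.min(axis=1) <= tol_min).sum())
    if T.sum() <= 0:
        raise ValueError("zero total observation time")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(cells), size=(n_boot, len(cells)))
    raw = np.where(n2[idx].sum(1) > 0, hits[idx].sum(1) / np.maximum(n2[idx].sum(1), 1), 0.0)
    chance = n4[idx].sum(1) * (2.0 * tol_min) / T[idx].sum(1)
    stats = raw - chance
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return CoincidenceEstimate(float(stats.mean()), float(lo), float(hi),
                               n_boot, len(cells), seed, se=float(stats.std(ddof=1)))


def single_cell_rates(summaries: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-cell coincidence rates; cells without pulses excluded and counted."""
    total = summaries["n2"] + summaries["n4"]
    has_pulses = total > 0
    rates = 2.0 * summaries.loc[has_pulses, "n_coinc"] / total[has_pulses]
    return rates, int((~has_pulses).sum())


def classify_bimodal(sc_rates: np.ndarray, bandwidth: str | float = "silverman",
                     grid_size: int = 512
                     ) -> tuple[float | None, np.ndarray, bool]:
    """Split cells into low/high coincidence classes at the density trough.

    A Gaussian kernel density estimate (Silverman bandwidth by default) is
    evaluated on [0, 1]; the threshold is the minimizing abscissa between
    the two highest modes.  Returns (threshold, labels, bimodal_flag); for a
    unimodal density the threshold is None, all labels are "low", and the
    flag is False.
    """
    rates = np.asarray(sc_rates, dtype=float)
    rates = rates[np.isfinite(rates)]
    if rates.size < 2 or np.ptp(rates) == 0:
        return None, np.zeros(rates.size, dtype=bool), False
    kde = gaussian_kde(rates, bw_method=bandwidth)
    grid = np.linspace(min(0.0, rates.min()), max(1.0, rates.max()), grid_size)
    dens = kde(grid)
    interior = np.arange(1, grid_size - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    modes = interior[is_max]
    if modes.size < 2:
        return None, np.zeros(rates.size, dtype=bool), False
    top2 = modes[np.argsort(dens[modes])[-2:]]
    lo_m, hi_m = int(top2.min()), int(top2.max())
    trough_idx = lo_m + int(np.argmin(dens[lo_m:hi_m + 1]))
    threshold = float(grid[trough_idx])
    return threshold, rates > threshold, True


def classify_pulse_context(times2: np.ndarray, times4: np.ndarray,
                           tol_min: float = DEFAULT_TOL_MIN,
                           only_window_min: float = DEFAULT_ONLY_WINDOW_MIN
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Classify each pulse for triggered averaging.

    ``co_pulse`` when matched within the coincidence tolerance;
    ``msn2_only``/``msn4_only`` when no other-factor peak lies within the
    half-window (8 min, i.e. a 16-min total window); otherwise ``ambiguous``
    (a nearby but non-coincident other-factor pulse) and excluded from
    triggered averaging.
    """
    t2 = np.asarray(times2, dtype=float)
    t4 = np.asarray(times4, dtype=float)
    _, lab2, lab4 = match_pulses(t2, t4, tol_min)

    def _classes(own: np.ndarray, other: np.ndarray, matched: np.ndarray,
                 only_name: str) -> np.ndarray:
        out = np.empty(own.size, dtype=object)
        for i, t in enumerate(own):
            if matched[i]:
                out[i] = "co_pulse"
            elif other.size == 0 or np.min(np.abs(other - t)) > only_window_min:
                out[i] = only_name
            else:
                out[i] = "ambiguous"
        return out

    return (_classes(t2, t4, lab2, "msn2_only"),
            _classes(t4, t2, lab4, "msn4_only"))


def colocalization_snapshot(n_nuc2: int, n_nuc4: int, n_both: int,
                            sample_size: int, n_boot: int = DEFAULT_N_BOOT,
                            seed: int = 0) -> CoincidenceEstimate:
    """Nuclear colocalization percentage for one snapshot time point.

    Per replicate, ``sample_size`` cells are drawn with replacement from the
    nuclear-Msn2 cells and from the nuclear-Msn4 cells; the statistic is the
    fraction of drawn cells nuclear for both factors.  Reported as a
    percentage.
    """
    if n_nuc2 <= 0 or n_nuc4 <= 0:
        raise ValueError("a channel has zero nuclear cells at this time point")
    if n_both > min(n_nuc2, n_nuc4):
        raise ValueError("n_both cannot exceed either channel count")
    lab2 = np.zeros(n_nuc2, dtype=bool)
    lab2[:n_both] = True
    lab4 = np.zeros(n_nuc4, dtype=bool)
    lab4[:n_both] = True
    rng = np.random.default_rng(seed)
    d2 = rng.integers(0, n_nuc2, size=(n_boot, sample_size))
    d4 = rng.integers(0, n_nuc4, size=(n_boot, sample_size))
    stats = 100.0 * (lab2[d2].sum(1) + lab4[d4].sum(1)) / (2.0 * sample_size)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return CoincidenceEstimate(float(stats.mean()), float(lo), float(hi),
                               n_boot, sample_size, seed, se=float(stats.std(ddof=1)))
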