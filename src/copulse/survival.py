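"""Survival analyses linking pulse statistics to stress outcome.

Cells are observed for a 7-h window (pulse counting) and scored for
survival over a further 6-h horizon via a nuclear live/dead dye.  The
analyses ask whether, at matched total pulse number, cells with fewer
coincident pulses (i.e. more effective pulses) survive better:

* within total-pulse bins, cells are split at the median coincidence rate
  (never separating equal rates) and subgroup survival fractions compared;
* survival fractions are traced against effective vs total pulse counts;
* binned OLS compares a model with (total, n_coinc) regressors against a
  total-only model via adjusted R^2 and the coefficient t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import Trace

DEFAULT_OBSERVATION_H = 7.0
DEFAULT_HORIZON_H = 6.0


@dataclass
class SurvivalRecord:
    cell_id: str
    observation_window_h: float = DEFAULT_OBSERVATION_H
    horizon_h: float = DEFAULT_HORIZON_H
    death_time_h: float | None = None

    @property
    def survived_window(self) -> bool:
        return self.death_time_h is None or self.death_time_h > self.observation_window_h

    @property
    def survived_horizon(self) -> bool:
        return self.death_time_h is None or \
            self.death_time_h > self.observation_window_h + self.horizon_h


def detect_death_time(draq7: Trace, threshold: float,
                      persistence_frames: int = 2) -> float | None:
    """First time the dye signal exceeds threshold persistently.

    Death is called at the first frame from which the signal stays above
    ``threshold`` for at least ``persistence_frames`` consecutive frames
    (single-frame spikes are ignored); ``None`` when the cell never dies
    within the trace (censored).
    """
    above = draq7.values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence_frames:
            return float(draq7.times[i - persistence_frames + 1])
    return None


def _bootstrap_fraction(flags: np.ndarray, n_boot: int, rng: np.random.Generator
                        ) -> tuple[float, float, float]:
    frac = float(flags.mean()) if flags.size else float("nan")
    if flags.size < 2:
        return frac, frac, frac
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    boots = flags[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return frac, float(lo), float(hi)


def group_and_split(cells: pd.DataFrame, pulse_bins: Sequence | None = None,
                    n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Split total-pulse groups into low/high coincidence-rate subgroups.

    ``cells`` needs columns total, sc_rate, survived_horizon (restricted to
    cells that survived the observation window).  Within each total-pulse
    bin cells are sorted by sc_rate and cut as close to half as possible
    without separating cells of equal sc_rate.  Bins with a single distinct
    rate are flagged unsplittable.

    Returns one row per (bin, subgroup) with survival fraction and CI.
    """
    rng = np.random.default_rng(seed)
    if pulse_bins is None:
        # six groups spanning the observed totals
        edges = np.unique(np.quantile(cells["total"], np.linspace(0, 1, 7)))
        pulse_bins = edges
    binned = pd.cut(cells["total"], bins=pulse_bins, include_lowest=True)
    rows = []
    for b, grp in cells.groupby(binned, observed=True):
        grp = grp.sort_values(["sc_rate", "cell_id"], kind="mergesort")
        rates = grp["sc_rate"].to_numpy()
        n = len(grp)
        # candidate cut positions: between distinct sc_rate values
        change = np.nonzero(np.diff(rates) > 0)[0] + 1
        if change.size == 0:
            rows.append({"bin": str(b), "subgroup": "unsplittable", "n": n,
                         "survival_fraction": float(grp["survived_horizon"].mean()),
                         "ci_low": np.nan, "ci_high": np.nan,
                         "mean_sc_rate": float(np.nanmean(rates))})
            continue
        cut = int(change[np.argmin(np.abs(change - n / 2))])
        for name, sub in (("low", grp.iloc[:cut]), ("high", grp.iloc[cut:])):
            flags = sub["survived_horizon"].to_numpy(dtype=float)
            frac, lo, hi = _bootstrap_fraction(flags, n_boot, rng)
            rows.append({"bin": str(b), "subgroup": name, "n": len(sub),
                         "survival_fraction": frac, "ci_low": lo, "ci_high": hi,
                         "mean_sc_rate": float(sub["sc_rate"].mean())})
    return pd.DataFrame(rows)


def survival_by_pulse_count(cells: pd.DataFrame, mode: str = "effective",
                            min_cells: int = 10, n_boot: int = 1000,
                            seed: int = 0) -> pd.DataFrame:
    """Survival fraction versus pulse count (effective or total).

    Counts supported by fewer than ``min_cells`` cells are suppressed.
    """
    if mode not in ("effective", "total"):
        raise ValueError("mode must be 'effective' or 'total'")
    rng = np.random.default_rng(seed)
    rows = []
    for count, grp in cells.groupby(mode):
        if len(grp) < min_cells:
            continue
        flags = grp["survived_horizon"].to_numpy(dtype=float)
        frac, lo, hi = _bootstrap_fraction(flags, n_boot, rng)
        rows.append({"count": int(count), "survival_fraction": frac,
                     "ci_low": lo, "ci_high": hi, "n": len(grp)})
    return pd.DataFrame(rows).sort_values("count").reset_index(drop=True)


@dataclass
class RegressionComparison:
    params_a: pd.Series
    pvalues_a: pd.Series
    adj_r2_a: float
    params_b: pd.Series
    pvalues_b: pd.Series
    adj_r2_b: float
    n_bins: int
    rank_deficient: bool = False

    @property
    def delta_adj_r2(self) -> float:
        return self.adj_r2_a - self.adj_r2_b


def regression_compare(cells: pd.DataFrame, min_bin_cells: int = 20,
                       weighted: bool = False) -> RegressionComparison:
    """Binned two-variable vs one-variable survival regressions.

    Cells are binned on the integer pair (total, n_coinc); bins with at
    least ``min_bin_cells`` cells contribute one observation whose response
    is the bin survival fraction.  Model A regresses on total and n_coinc,
    model B on total alone (ordinary least squares; optionally weighted by
    bin size).  Reports coefficients, two-sided t-test p values and
    adjusted R^2 for both.
    """
    grouped = cells.groupby(["total", "n_coinc"]).agg(
        frac=("survived_horizon", "mean"), n=("survived_horizon", "size")
    ).reset_index()
    usable = grouped[grouped["n"] >= min_bin_cells]
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable bins")
    y = usable["frac"].to_numpy(dtype=float)
    Xa = sm.add_constant(usable[["total", "n_coinc"]].astype(float))
    Xb = sm.add_constant(usable[["total"]].astype(float))
    rank_deficient = usable["n_coinc"].nunique() < 2
    w = usable["n"].to_numpy(dtype=float) if weighted else None
    fit = (lambda X: (sm.WLS(y, X, weights=w) if weighted else sm.OLS(y, X)).fit())
    fa, fb = fit(Xa), fit(Xb)
    return RegressionComparison(fa.params, fa.pvalues, float(fa.rsquared_adj),
                                fb.params, fb.pvalues, float(fb.rsquared_adj),
                                len(usable), rank_deficient)


def contribution_fold_change(effective_curve: pd.DataFrame,
                             total_curve: pd.DataFrame) -> pd.DataFrame:
    """Per-count survival contributions and their fold change.

    The contribution of one extra pulse at count k is the forward difference
    S(k+1) - S(k) along each curve; the fold change divides the effective
    contribution by the total contribution where the latter is positive
    (undefined entries are flagged NaN).
    """
    def _contrib(curve: pd.DataFrame) -> dict[int, float]:
        s = dict(zip(curve["count"].astype(int), curve["survival_fraction"]))
        return {k: s[k + 1] - s[k] for k in s if k + 1 in s}

    ce = _contrib(effective_curve)
    ct = _contrib(total_curve)
    common = sorted(set(ce) & set(ct))
    if not common:
        raise ValueError("non-overlapping count ranges")
    rows = []
    for k in common:
        fold = ce[k] / ct[k] if ct[k] > 0 else float("nan")
        rows.append({"count": k, "effective_contribution": ce[k],
                     "total_contribution": ct[k], "fold_change": fold})
    return pd.DataFrame(rows)

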