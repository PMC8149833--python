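"""Paper-scale synthetic benchmark experiments.

Each function runs one self-contained experiment on synthetic data at the
cohort sizes of the original study design (300-500 imaging cells, 1676
survival cells, 436 target genes, 200-cell model populations) and returns a
dict of scalar metrics.  They serve both the acceptance checks and the
reproduction script; all randomness is derived from the single ``seed``
argument.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import coincidence as coin
from . import model as model_mod
from . import pulse_detect, synth, triggered
from . import survival as surv
from .io import Trace
from .synth import SynthConfig, triangular_kernel


def _sub(seed: int, k: int) -> int:
    return int((seed * 100003 + k * 7919 + 17) % (2**31 - 1))


# ---------------------------------------------------------------------------
# pulse detection

def pulse_recovery(seed: int, n_cells: int = 300) -> dict:
    """Detection F1 on a 7-h cohort plus exact width/area recovery.

    300 cells at 2-min frames, triangular pulses with 10-fold peak
    signal-to-noise; F1 counts ground-truth events matched within 2 min.
    The width/area check uses one noiseless amplitude-10 / FWHM-10 pulse,
    whose half-max width is 10 min and whose area between the half-max
    edges is 75 (total 100 minus two 12.5 tails).
    """
    cfg = SynthConfig(n_cells=n_cells, seed=_sub(seed, 1))
    events, truth = synth.generate_pulse_trains(cfg)
    traces = synth.render_cells(events, cfg)
    tp = fp = fn = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr in traces:
            det = np.array([p.peak_time_min for p in pulse_detect.detect_pulses(tr)])
            true_t = truth.events.loc[
                (truth.events["cell_id"] == tr.cell_id)
                & (truth.events["channel"] == tr.channel), "time_min"].to_numpy()
            a, b, c = pulse_detect.match_to_truth(det, true_t)
            tp, fp, fn = tp + a, fp + b, fn + c
    f1 = 2 * tp / (2 * tp + fp + fn)

    t = np.arange(0, 62, 2.0)
    tri = Trace("oracle", "MSN2", t, triangular_kernel(t, 20.0, 10.0, 10.0))
    pulse = pulse_detect.detect_pulses(
        tri, pulse_detect.DetectionParams(amp_threshold=3.0))[0]
    return {"f1": float(f1), "n_true": int(tp + fn),
            "width_min": float(pulse.width_min), "area": float(pulse.area)}


# ---------------------------------------------------------------------------
# coincidence estimation

def _labels_for_setting(p_share: float, n_cells: int, seed: int,
                        rate_per_channel: float = 1.5):
    # refractory disabled: no traces are rendered here, and a refractory
    # gap couples shared and only events, shifting the realized shared
    # fraction away from the nominal mixing ratio the estimator targets
    cfg = SynthConfig(n_cells=n_cells,
                      rate_shared=rate_per_channel * p_share,
                      rate_msn2_only=rate_per_channel * (1 - p_share),
                      rate_msn4_only=rate_per_channel * (1 - p_share),
                      refractory_min=0.0,
                      seed=seed)
    _, truth = synth.generate_pulse_trains(cfg)
    ev = truth.events
    lab2 = ev.loc[ev["channel"] == "MSN2", "shared"].to_numpy(dtype=bool)
    lab4 = ev.loc[ev["channel"] == "MSN4", "shared"].to_numpy(dtype=bool)
    return lab2, lab4


def coincidence_calibration(seed: int, n_cells: int = 500,
                            n_replicates: int = 200) -> dict:
    """CI coverage of the frequency-controlled estimator.

    Settings sweep the generator's shared-pulse fraction over 0.1..0.9 at a
    fixed per-channel pulse frequency (1.5/h over 7 h, 500 cells); the
    resample size is held fixed across settings (the smallest per-channel
    pool), mirroring the frequency-controlled design.  Coverage is then
    measured over 200 independent cohorts at p_share = 0.5.
    """
    settings = np.round(np.arange(0.1, 0.95, 0.1), 2)
    pools = [_labels_for_setting(p, n_cells, _sub(seed, 10 + k))
             for k, p in enumerate(settings)]
    # one resample size across all settings (the frequency control), with
    # the effective-sample-size correction at the central shared fraction
    min_pool = min(min(l2.size, l4.size) for l2, l4 in pools)
    sample_size = coin.effective_sample_size(min_pool, min_pool, 0.5)
    covered = 0
    for k, (p, (lab2, lab4)) in enumerate(zip(settings, pools)):
        est = coin.population_rate_frequency_controlled(
            lab2, lab4, sample_size, seed=_sub(seed, 30 + k))
        covered += est.ci_low <= p <= est.ci_high
    n_cov = 0
    for r in range(n_replicates):
        lab2, lab4 = _labels_for_setting(0.5, 200, _sub(seed, 1000 + r))
        ss = coin.effective_sample_size(lab2.size, lab4.size, 0.5)
        est = coin.population_rate_frequency_controlled(
            lab2, lab4, ss, seed=_sub(seed, 5000 + r))
        n_cov += est.ci_low <= 0.5 <= est.ci_high
    return {"settings_covered": int(covered), "n_settings": len(settings),
            "coverage": n_cov / n_replicates, "sample_size": int(sample_size)}


def chance_corrected_null(seed: int, n_cells: int = 500) -> dict:
    """Chance-corrected rate on independent Poisson trains (true rate 0)."""
    cfg = SynthConfig(n_cells=n_cells, rate_shared=0.0, rate_msn2_only=1.2,
                      rate_msn4_only=1.2, seed=_sub(seed, 2))
    events, _ = synth.generate_pulse_trains(cfg)
    cells = [{"t2": per["MSN2"]["time_min"].to_numpy(),
              "t4": per["MSN4"]["time_min"].to_numpy(),
              "obs_min": cfg.duration_min} for per in events.values()]
    est = coin.population_rate_chance_corrected(cells, seed=_sub(seed, 3))
    return {"corrected_rate": est.mean_rate, "bootstrap_se": est.se,
            "abs_rate_over_se": abs(est.mean_rate) / est.se,
            "formula_example": coin.expected_by_chance(10, 4.0, 400.0),
            "n_cells": n_cells}


# ---------------------------------------------------------------------------
# stochastic model

def model_equilibria(seed: int) -> dict:
    """Deterministic fixed points at zero kinase activity + tau-leap mean."""
    p = model_mod.ModelParams(pka_basal=0.0, x_basal=0.0, duration=150.0,
                              seed=_sub(seed, 4))
    t, ode2, ode4 = model_mod.integrate_deterministic(p)
    prog = model_mod.generate_kinase_program(p, 1, np.random.default_rng(_sub(seed, 4)))
    prog.pka_delta[:] = 0.0
    prog.x_delta[:] = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tr2, _ = model_mod.simulate_tau_leap(p, prog)
    burn = tr2.times > 20.0
    return {"msn2_equilibrium": float(ode2[-1]),
            "msn4_equilibrium": float(ode4[-1]),
            "msn2_expected": 200.0 / 3.0,
            "msn4_expected": 1200.0 * 200.0 / 1202.0,
            "tau_leap_msn2_mean": float(tr2.values[burn].mean())}


PKA_SWEEP_VALUES = (6.0, 7.2, 8.4, 9.6, 10.8, 12.0)
KD_SWEEP_VALUES = (0.5, 0.875, 1.25, 1.625, 2.0)


def model_sweeps(seed: int, n_cells_pka: int = 400, n_cells_kd: int = 200) -> dict:
    """Qualitative model predictions: coincidence-rate trends.

    Coincidence rate rises with the basal PKA level (weak PKA dips stop
    producing Msn2-only pulses) and falls as the PKA-affinity ratio between
    the paralogs grows (their effective PKA inputs diverge).  The PKA trend
    is the subtler of the two, so it gets the larger population per level.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = model_mod.ModelParams(seed=_sub(seed, 5))
        _, rho_pka, p_pka = model_mod.sweep("pka_basal", PKA_SWEEP_VALUES,
                                            n_cells=n_cells_pka, params=base)
        base2 = model_mod.ModelParams(seed=_sub(seed, 6))
        _, rho_kd, p_kd = model_mod.sweep("kd_ratio", KD_SWEEP_VALUES,
                                          n_cells=n_cells_kd, params=base2)
    return {"pka_rho": rho_pka, "pka_p": p_pka,
            "kd_rho": rho_kd, "kd_p": p_kd,
            "n_cells_pka": n_cells_pka, "n_cells_kd": n_cells_kd}


# ---------------------------------------------------------------------------
# bimodality

def bimodality_recovery(seed: int, n_cells: int = 500) -> dict:
    """Trough classifier on a 0.3/0.7 mixture of N(0.2,0.05)/N(0.8,0.05)."""
    rng = np.random.default_rng(_sub(seed, 7))
    n_low = rng.binomial(n_cells, 0.3)
    rates = np.concatenate([rng.normal(0.2, 0.05, n_low),
                            rng.normal(0.8, 0.05, n_cells - n_low)])
    truth = np.concatenate([np.zeros(n_low, bool),
                            np.ones(n_cells - n_low, bool)])
    thr, labels, flag = coin.classify_bimodal(rates)
    return {"bimodal": bool(flag), "threshold": float(thr) if thr else np.nan,
            "high_weight": float(labels.mean()),
            "label_accuracy": float((labels == truth).mean()),
            "n_cells": n_cells}


# ---------------------------------------------------------------------------
# survival

def _survival_cohort(seed: int, n: int = 1676, beta0: float = -3.0,
                     beta1: float = 0.35) -> pd.DataFrame:
    """Cohort whose survival depends on effective pulses only (so the
    coincident-pulse count carries a negative effect at fixed total)."""
    rng = np.random.default_rng(seed)
    n2 = rng.poisson(5, n)
    n4 = rng.poisson(5, n)
    n_coinc = rng.binomial(np.minimum(n2, n4), 0.5)
    total = n2 + n4
    eff = total - n_coinc
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * eff)))
    survived = rng.uniform(size=n) < p
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "n2": n2, "n4": n4, "n_coinc": n_coinc, "total": total,
        "effective": eff,
        "sc_rate": np.where(total > 0, 2 * n_coinc / np.maximum(total, 1), np.nan),
        "survived_horizon": survived,
    })


def survival_recovery(seed: int, n_cohorts: int = 100, n_cells: int = 1676) -> dict:
    """Regression sign/fit recovery over repeated cohorts + subgroup contrast."""
    sign_ok = fit_ok = 0
    for c in range(n_cohorts):
        cells = _survival_cohort(_sub(seed, 8000 + c), n=n_cells)
        cmp_ = surv.regression_compare(cells)
        sign_ok += (cmp_.params_a["n_coinc"] < 0) and (cmp_.pvalues_a["n_coinc"] < 0.05)
        fit_ok += cmp_.adj_r2_a > cmp_.adj_r2_b
    cells = _survival_cohort(_sub(seed, 8), n=n_cells)
    split = surv.group_and_split(cells[cells["total"] >= 2],
                                 pulse_bins=[1, 5, 7, 9, 11, 13, 40],
                                 seed=_sub(seed, 9))
    piv = split[split["subgroup"].isin(["low", "high"])].pivot_table(
        index="bin", columns="subgroup", values="survival_fraction").dropna()
    return {"sign_recovery_fraction": sign_ok / n_cohorts,
            "adjr2_improvement_fraction": fit_ok / n_cohorts,
            "low_rate_wins": int((piv["low"] >= piv["high"]).sum()),
            "n_split_bins": int(len(piv)),
            "n_cohorts": n_cohorts}


# ---------------------------------------------------------------------------
# redundancy

def redundancy_recovery(seed: int, n_genes: int = 436,
                        redundant_fraction: float = 0.85) -> dict:
    """Exact rule checks plus recovery on a noisy 436-gene table."""
    from .redundancy import classify_redundant, classify_table
    exact = [
        classify_redundant({"fc_wt": 2.0, "fc_msn2": 2.0, "fc_msn4": 2.0}) == "redundant",
        classify_redundant({"fc_wt": 4.0, "fc_msn2": 1.0, "fc_msn4": 1.0}) == "nonredundant",
        classify_redundant({"fc_wt": 2.0, "fc_msn2": 1.0, "fc_msn4": 1.0}) == "nonredundant",
    ]
    n_red = int(round(n_genes * redundant_fraction))
    table, _ = synth.generate_foldchange_table(n_red, n_genes - n_red,
                                               noise_cv=0.2, seed=_sub(seed, 10))
    labeled = classify_table(table)
    frac = float((labeled["label"] == "redundant").mean())
    return {"exact_labels_correct": int(sum(exact)),
            "recovered_fraction": frac,
            "true_fraction": n_red / n_genes, "n_genes": n_genes}


# ---------------------------------------------------------------------------
# triggered averaging

def _triggered_events(mode: str, seed: int, n_cells: int) -> pd.DataFrame:
    # sparse pulse trains so reporter bursts rarely overlap: with denser
    # trains, co-pulses systematically pick up neighbouring bursts inside
    # their 8-min window (only-pulses cannot, by their isolation rule),
    # which would bias the class comparison
    cfg = SynthConfig(n_cells=n_cells, rate_shared=0.35, rate_msn2_only=0.25,
                      rate_msn4_only=0.25, noise_sd=0.5, seed=seed)
    events, _ = synth.generate_pulse_trains(cfg)
    rng = np.random.default_rng(seed + 1)
    all_events = []
    for cid, per in sorted(events.items()):
        reporter = synth.generate_reporter(per, mode, cfg, cell_id=cid,
                                           rng=np.random.default_rng(rng.integers(2**31)))
        t2 = per["MSN2"]["time_min"].to_numpy()
        t4 = per["MSN4"]["time_min"].to_numpy()
        c2, c4 = coin.classify_pulse_context(t2, t4)
        pulse_rows = []
        for ch, df in (("MSN2", per["MSN2"]), ("MSN4", per["MSN4"])):
            for row in df.itertuples(index=False):
                pulse_rows.append({
                    "cell_id": cid, "channel": ch,
                    "peak_time_min": row.time_min,
                    "left_edge_min": row.time_min - cfg.halfmax_width_min / 2,
                    "area": row.amplitude * cfg.halfmax_width_min,
                })
        if not pulse_rows:
            continue
        ev, _ = triggered.collect_triggered_events(
            reporter, pd.DataFrame(pulse_rows), c2, c4)
        if len(ev):
            all_events.append(ev)
    return pd.concat(all_events, ignore_index=True)


def triggered_averaging(seed: int, n_cells: int = 150) -> dict:
    """OR-gate redundancy at the single-pulse level, and its dose-response.

    With the saturated OR-gate reporter the three pulse classes produce
    statistically indistinguishable mean responses and area bins are flat;
    the unsaturated (linear) control produces a positive area trend.
    """
    ev_sat = _triggered_events("saturated_or", _sub(seed, 11), n_cells)
    means = triggered.triggered_average_by_class(ev_sat, seed=_sub(seed, 12))
    classes = ["co_pulse", "msn2_only", "msn4_only"]
    n_min = min(means[c].n_events for c in classes)
    overlap = all(
        means[a].ci_low <= means[b].ci_high and means[b].ci_low <= means[a].ci_high
        for i, a in enumerate(classes) for b in classes[i + 1:])
    only_sat = ev_sat[ev_sat["class"].isin(["msn2_only", "msn4_only"])]
    _, (slope_sat, lo_sat, hi_sat) = triggered.bin_by_area(
        only_sat, n_bins=5, seed=_sub(seed, 13))
    ev_lin = _triggered_events("linear", _sub(seed, 14), n_cells)
    only_lin = ev_lin[ev_lin["class"].isin(["msn2_only", "msn4_only"])]
    _, (slope_lin, lo_lin, hi_lin) = triggered.bin_by_area(
        only_lin, n_bins=5, seed=_sub(seed, 15))
    ratio = means["msn2_only"].mean / means["co_pulse"].mean
    return {"class_cis_overlap": bool(overlap),
            "min_events_per_class": int(n_min),
            "mean_ratio_only_over_co": float(ratio),
            "saturated_slope_ci": (float(lo_sat), float(hi_sat)),
            "saturated_slope_contains_zero": bool(lo_sat <= 0.0 <= hi_sat),
            "linear_slope_lo": float(lo_lin),
            "linear_slope_positive": bool(lo_lin > 0.0)}
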