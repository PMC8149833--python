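# copulse

Quantitative analysis of **temporal redundancy between pulsatile
transcription-factor paralogs** in single cells — motivated by the
budding-yeast general stress regulators Msn2 and Msn4.

Both factors enter the nucleus in stochastic, minutes-long pulses, and a
single pulse of either factor saturates most shared target promoters (an
OR-gate).  The dose delivered to those targets is therefore set not by the
total pulse count but by the number of *effective* pulses,
`n2 + n4 - n_coincident`: tuning how often the two pulse trains coincide
modulates the factors' functional redundancy in time.  `copulse` provides
the full analysis chain for this question:

* **Trace quantification** — nuclear-localization score (mean of the five
  brightest pixels minus the pixel median), focus-compactness gating, cubic
  background subtraction, transient response amplitude, z-projected
  reporter activity.
* **Pulse detection** — thresholded strict local maxima, shoulder merging,
  half-maximum edges on monotone cubic flank interpolants, pulse width and
  area.
* **Coincidence statistics** — two pulses coincide when their peaks are
  ≤ 2 min apart (one-to-one greedy matching).  Population rates via a
  frequency-controlled bootstrap (equal pulse numbers resampled per
  channel) and a chance-corrected variant subtracting
  `N_Msn4 × window / total time`; single-cell rates
  `2·n_pairs/(n2+n4)` with bimodal classification at the density trough.
* **Pulse-triggered averaging** — reporter response = max within 8 min
  after a pulse minus the mean within 8 min before, averaged by pulse class
  (co-pulse / Msn2-only / Msn4-only) and binned by pulse area.
* **Survival analysis** — DRAQ7-based death calling, coincidence-rate
  subgroup splits within total-pulse bins, survival vs effective/total
  pulse counts, and the binned two-variable vs one-variable regression
  comparison (adjusted R², coefficient t-tests).
* **Redundancy classification** — a target is redundant when
  `fc_msn2 + fc_msn4 > fc_wt` (fold changes measured in the two single
  mutants and wild type), with ternary coordinates and one-sided K–S
  dynamic-range comparisons.
* **Stochastic circuit model** — Hill-repressed nuclear import/export of
  both factors under a common kinase (PKA, with paralog-specific affinity
  ratio `Kd(Msn4)/Kd(Msn2)`) plus a second kinase X acting on Msn4 only,
  simulated by tau-leaping and swept over PKA level and affinity ratio.
* **Synthetic data generator** — ground-truthed pulse trains, traces,
  reporters, survival outcomes and fold-change tables with the statistical
  structure the analysis assumes, so the whole chain is testable offline.

## Worked example

```python
import numpy as np
from copulse import synth, pulse_detect, coincidence as coin

# 200 synthetic cells, 7 h at 2-min frames; two thirds of pulses shared
cfg = synth.SynthConfig(n_cells=200, rate_shared=1.0, rate_msn2_only=0.5,
                        rate_msn4_only=0.5, seed=1)
events, truth = synth.generate_pulse_trains(cfg)
traces = synth.render_cells(events, cfg)

# detect pulses and summarize per-cell coincidence
pulses = []
for tr in traces:
    pulses.extend(pulse_detect.detect_pulses(tr))
pulse_df = pulse_detect.pulses_to_frame(pulses)
summaries = coin.summarize_cells(pulse_df, tol_min=2.0)

rates, n_empty = coin.single_cell_rates(summaries)
print(f"{len(pulse_df)} pulses in {len(summaries)} cells")
print(f"mean single-cell coincidence rate: {rates.mean():.3f}")

lab2 = np.concatenate([np.r_[np.ones(r.n_coinc, bool), np.zeros(r.n2 - r.n_coinc, bool)]
                       for r in summaries.itertuples()])
lab4 = np.concatenate([np.r_[np.ones(r.n_coinc, bool), np.zeros(r.n4 - r.n_coinc, bool)]
                       for r in summaries.itertuples()])
ss = coin.effective_sample_size(lab2.size, lab4.size, lab2.mean())
est = coin.population_rate_frequency_controlled(lab2, lab4, ss, seed=1)
print(f"population rate: {est.mean_rate:.3f} "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
```

Output:

```
3703 pulses in 200 cells
mean single-cell coincidence rate: 0.594
population rate: 0.601 [0.583, 0.619]
```

The detected population coincidence rate (~0.60) sits close to the
generator's design: with shared rate 1.0/h against 0.5/h of channel-only
pulses per factor, two thirds of pulses are truly shared; detection misses
(which break pairs more often than they spare them) pull the measured rate
slightly below that, while chance overlaps (the quantity the
chance-corrected estimator removes) push it up a little.

A command-line surface mirrors the library (`copulse synth`, `detect`,
`coincidence`, `correlate`, `triggered`, `survival`, `redundancy`,
`simulate`, `sweep`, `run`); see `copulse --help`.

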