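# Methods

`copulse` implements the quantitative machinery for analyzing *temporal
redundancy* between paralogous pulsatile transcription factors — the
budding-yeast general stress regulators Msn2 and Msn4 being the motivating
system.  Both factors shuttle into the nucleus in minutes-long pulses;
because individual pulses of either factor activate most shared targets to
saturation (an OR gate), the *coincidence* of the two pulse trains sets the
effective dose delivered to those targets.  The package covers the whole
chain: trace/pixel quantification, pulse detection, coincidence statistics,
pulse-triggered transcription, survival analyses, target-redundancy
classification, and a stochastic two-kinase circuit model — plus a
ground-truthed synthetic generator so every stage is testable without the
original microscopy data.

## Trace and pixel quantification (`trace_quant`)

Nuclear localization of a tagged factor is scored per frame as the mean of
the five brightest pixels minus the median of all pixels in the cell; a
frame counts as *positive* (a genuine nuclear focus) when the mean pairwise
distance of the ten brightest pixels falls strictly below a compactness
threshold (default 3 pixel units; the underlying criterion is empirical and
always config-exposed).  Slow baseline drift is removed by a least-squares
cubic fitted to the non-positive frames only.  The transient stress
response is the maximum localization in the 20 min after stress minus the
median in the 20 min before; windows are half-open (peak side inclusive) so
the stress frame is never double-counted.  Nascent-transcription activity
from the PP7/PCP reporter uses the same top-5-minus-median score on a
per-pixel maximum z-projection.  Ties among "brightest" pixels are broken
by pixel index for determinism.

## Pulse detection (`pulse_detect`)

Pulses are strict local maxima of the background-subtracted trace that
exceed an amplitude threshold and sit on a positive frame.  Shoulder-like
peaks are merged into their higher neighbour when the minimum between two
adjacent peaks exceeds half (config: `trough_fraction`) of the lower peak's
amplitude, iterated to stability.  Each flank, from the adjacent trough to
the peak, is fitted with a monotone cubic (PCHIP) interpolant; the half-max
edges are the innermost crossings of half the peak amplitude, the width is
the edge distance, and the area is the trapezoid integral of the flank
interpolants between the edges on a 0.1-min grid.  The monotone interpolant
is a deliberate choice over a free cubic spline: it guarantees a unique
innermost crossing and cannot overshoot the data.

The amplitude threshold defaults to 4x a robust noise estimate (median
absolute deviation of first differences, Gaussian-scaled).  The 4x factor
calibrates a trade-off specific to 2-min sampling of ~6-min-wide pulses:
the sampled peak sits up to 1 min off the apex (x0.83 attenuation), so with
realistically dispersed amplitudes a 5-sigma cutoff loses ~14% of true
pulses while 4-sigma recovers F1~0.94 at a negligible noise
false-positive rate (<1% of pure-noise cells yield any detection even at
5-sigma).  The threshold remains config-exposed.

## Coincidence statistics (`coincidence`)

Two pulses are *coincident* when their peaks differ by at most 2 min (one
frame).  Pairing is one-to-one and greedy in ascending |lag| (ties resolved
symmetrically in the two channels), so no pulse is counted twice.  Per
cell, the coincidence rate is `2*n_pairs/(n2+n4)` — both members of a pair
are coincident pulses.  The *effective* pulse number is `n2+n4-n_pairs`: a
co-pulse delivers one dose to saturated shared targets.

Population rates use the frequency-controlled bootstrap: equal numbers of
pulses per channel are resampled with replacement from the pooled,
pre-labelled pulses of a condition, with the same resample size across
conditions, so conditions with different pulse frequencies are comparable.
One subtlety is derived and corrected here: both members of a coincident
pair enter the pools (one per channel), making the two per-channel
coincident fractions positively correlated across cohorts.  The estimator's
true sampling variance is `f(1-f)(2-f)/(2N)` for coincident fraction `f`
and per-channel pool size `N` (we verified this by Monte Carlo), while
resampling `N` pulses per channel reproduces only the binomial
`f(1-f)/(2N)`.  `effective_sample_size` therefore recommends resampling
`N/(2-f)` pulses per channel, which restores nominal 95% CI coverage.

The chance-corrected variant resamples cells with replacement; the raw
statistic (fraction of Msn2 pulses with an Msn4 peak within tolerance) is
reduced by the first-order expected-by-chance term
`(number of Msn4 pulses x window)/(total time)` with window = 2x tolerance
= 4 min.  The correction is first-order by construction and may leave the
corrected rate slightly negative on null data.

Cell populations are split into high/low-coincidence classes at the trough
of a Gaussian kernel density estimate (Silverman bandwidth) of the
single-cell rates, between the two highest modes; a unimodal density is
flagged rather than split.  For triggered averaging, each pulse is
classified as `co_pulse` (matched within 2 min), `msn2_only`/`msn4_only`
(no other-factor peak within 8 min, i.e. a 16-min exclusion window), or
`ambiguous` (other-factor peak at 2-8 min lag; excluded).

## Correlation analysis (`trace_stats`)

Auto- and cross-correlations use the biased (1/n) estimator on
mean-subtracted steady-state segments, at integer-frame lags up to 30 min,
averaged across cells with a 95% cell-resampling bootstrap CI.  The
steady-state response starts at twice the median right-edge time of the
transient pulses (peaks within 8 min of stress arrival), measured from
stress arrival; with no transient pulses a configured fallback offset is
used and flagged.

## Pulse-triggered averaging (`triggered`)

The transcriptional response to a pulse is the maximum reporter signal in
the 8 min after the trigger minus the mean in the 8 min before.  Triggers
anchor at the pulse peak — the most precisely estimated landmark — and at
the mean of the two peaks for co-pulses; a left-edge anchor is available.
Class means carry percentile bootstrap CIs; only-pulses can additionally be
binned by pulse area (equal-count bins) to probe saturation: a flat bin
profile (OLS slope CI containing zero) indicates the promoter saturates at
the single-pulse level.

## Survival analyses (`survival`)

Death is called from the live/dead dye trace at the first threshold
crossing persisting for two frames (an automated, reproducible stand-in for
manual curation).  Cells surviving a 7-h observation window are analyzed
for survival over a further 6-h horizon.  Three complementary analyses:
(1) within total-pulse bins, cells are split at the median single-cell
coincidence rate — never separating equal rates, so bins can be
unsplittable — and subgroup survival fractions compared; (2) survival
fractions vs effective and vs total pulse count, with per-pulse
contributions defined as forward differences and their ratio as the
contribution fold change; (3) cells binned on the integer pair (total,
coincident) with bins of >= 20 cells contributing their survival fraction
to two OLS models — on (total, coincident) and on total alone — compared by
coefficient t-tests and adjusted R².  Unweighted OLS is the default; a
bin-size-weighted variant is available.

## Redundancy classification (`redundancy`)

A candidate target (the list is an input file, never fetched live) is
retained when its wild-type stress fold change strictly exceeds 1.2, and
called *redundant* when the sum of its fold changes in the two single
mutants strictly exceeds the wild-type fold change — each paralog alone
recapitulates activation.  Ternary coordinates are the sum-normalized
genotype triple (centre = full redundancy).  Dynamic ranges of redundant vs
nonredundant targets are compared per stress level by a one-sided
two-sample Kolmogorov-Smirnov test (redundant stochastically larger), with
no multiple-testing correction, noted in the output.

## Stochastic model (`model`)

Nuclear copy numbers follow Hill-repressed import/export kinetics (see the
module docstring for the equations) with defaults `a2=1`, `a4=1200`,
`b2=b4=2`, `n2=n4=nX=4`, totals 200, basal X activity 6, `amp_weak=4`,
step 0.001, duration 300 time units (1 unit = 1 min by convention; output
sampled on the 2-min analysis grid).  Kinase activities fluctuate as
square events on a shared clock (period 10), each event drawing a PKA
scenario (up +U(0, 0.1 basal); strong down -U(0, basal); weak down
-U(0, amp_weak); equal probabilities) and, with probability 1/3, an X
down-regulation (-U(0, basal)).  Simulation is tau-leaping: per step the
four reaction counts are Poisson draws at current propensities, applied and
clamped to [0, total]; a leap-condition check warns when the basal per-step
mean count reaches 0.1.  The deterministic limit (`integrate_deterministic`)
integrates the same equations segment-by-segment with `solve_ivp` and is
the oracle the tau-leap mean must approach as copy numbers grow.

Event duration defaults to 4 time units: with export rate 2, a 1-unit
event's pulse decays by e^-2 before the next 2-min frame and would be
invisible on the analysis grid; 4-unit events produce well-sampled 5-8-min
pulses like the experimental ones.  Detection on simulated trajectories
uses an absolute threshold of 10 copies (5% of total) because the two
factors' demographic baseline noise differs too much for a shared
noise-scaled threshold.

Basal PKA (default 6) and the affinity ratio `kd_ratio = Kd(Msn4)/Kd(Msn2)`
(default 0.5; below 1 because Msn2 binds PKA more weakly) are free
parameters explored by `sweep`, which simulates a population per value,
runs detection and coincidence, and reports Spearman's trend over per-cell
coincidence rates.  Model exploration locates the regimes of the two
qualitative predictions: coincidence falls monotonically as `kd_ratio`
grows from 0.5 to 2 (the factors' effective PKA inputs diverge), and rises
with basal PKA over 6-12 at `kd_ratio` 0.5 — the regime where weak PKA dips
(bounded by `amp_weak`) stop clearing Msn2's derepression point, squeezing
out Msn2-only pulses, while X-dip-driven Msn4-only pulses shrink below
detectability at high basal PKA.  Below basal 6 the trend reverses (weak
dips drive abundant only-pulses), so the increasing-coincidence prediction
is a statement about the high-PKA regime; the rise is modest
(rho ~ +0.1 over cells) and tested with 400 cells per level.

## Synthetic data generator (`synth`)

The generator emulates the statistical structure of the study's inputs:
two-channel pulse trains at 2-min frames over 7 h, with shared events
(one Poisson process copied to both channels with Gaussian jitter,
truncated at the 2-min tolerance so "shared" equals "coincident" in ground
truth) and channel-only events, an 8-min within-channel refractory gap,
triangular pulse kernels parameterized directly by FWHM (default 6 min) so
half-max edge recovery has an exact analytic answer, lognormal amplitudes
(mean 10, CV 0.3) over cubic drift and Gaussian noise (sd 1; peak
signal-to-noise 10), mixture subpopulations with distinct rates, a
reporter with saturated-OR / factor-specific / additive / linear response
modes, logistic survival in the effective pulse number, and fold-change
tables mixing redundant genes (equal activation in all genotypes) with
nonredundant ones (activation collapsing in both single mutants — the
pattern the classification rule identifies; a gene responding fully in one
single mutant is redundant under the rule by arithmetic).  Amplitude and
width defaults are placeholders for unpublished pulse-shape statistics and
are config-exposed.

What the generator does *not* emulate: segmentation/tracking errors,
photobleaching, cell growth and division, non-triangular pulse shapes,
correlated noise, and regulatory feedback from targets to the factors.
Passing tests therefore demonstrate correctness of the analysis chain under
the stated statistical assumptions, not performance on raw microscopy.

## Benchmark experiment sizes (`benchmarks`)

The packaged experiments run at the study's design scale: 300 imaging
cells for detection F1, 500 cells per setting for estimator calibration
(coverage measured over 200 cohorts of 200 cells), 500 cells for the
chance-corrected null, 1676-cell survival cohorts (100 of them for the
regression-recovery rate), a 436-gene fold-change table at 85% redundant,
150-cell reporter cohorts at sparse pulse rates (so reporter bursts rarely
overlap; denser trains let co-pulses capture neighbouring bursts in their
post-window, a conditioning artifact unrelated to saturation), and 5-6
sweep levels of 200-400 model cells.  The survival generator uses
beta0=-3, beta1=0.35, placing survival fractions mid-range over the
observed effective-pulse span; with saturating parameters the
coincident-pulse effect is unidentifiable from binned fractions.

## Known limitations

* The detection F1 >= 0.9 operating point holds for mean peak
  signal-to-noise >= ~8 at 2-min frames; at mean SNR 5 the lower lognormal
  amplitude tail is unresolvable at any threshold.
* The chance correction is first-order and the matcher counts chance
  overlaps (~rate x 4 min) as coincident; on independent trains the two
  cancel to within bootstrap error.
* At the default simulation length (300 min) model cells carry ~5-15
  pulses, so single-cell coincidence rates are too granular for the KDE
  trough classifier to resolve sub-population structure between model
  regimes; bimodality detection is validated on mixtures with continuous
  rates instead.
* The regression comparison treats bin survival fractions as homoskedastic
  observations (unweighted OLS), matching the analysis it reproduces, not
  best practice for proportion data.
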