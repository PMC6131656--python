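# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind each `dgquant` stage, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Spatial cluster statistic

**Model.** Within each 40-um histological section, labelled cells form a
2-D point set (sections are treated as planes; no cross-section edges,
because serial sections are sampled 200 um apart precisely so that the
same cell population is never counted twice). The proximity graph joins
cells at distance d strictly below a threshold (default 25 um) with
weight w = 1 − d/threshold.

**Choices the literature leaves open, fixed here.**

- *Weight function.* Any monotone decreasing function of distance would
  do; we use the linear form because it is the simplest bounded choice
  that vanishes exactly at the cutoff and lies in (0, 1].
- *Betweenness on weighted graphs.* Shortest paths use edge length 1/w,
  so strongly-coupled (close) pairs are "short". Betweenness is
  unnormalised; ties in the maximum are broken by removing the edge with
  the lexicographically smallest (i, j) node pair, which makes the whole
  procedure deterministic.
- *Canonical node order.* Cells are sorted by (section, x, y) before
  node indexing, so results are independent of input row order.
- *Cluster-size cap.* Biologically, a clone in a proliferation assay has
  1–5 cells. Communities larger than 5 are split by continuing the
  Girvan–Newman edge removal inside the community until every component
  has ≤ 5 members. The alternative — discarding oversized communities —
  would silently drop cells and was rejected; splitting keeps the
  partition exhaustive.

**Partition selection.** Along the removal sequence the partition with
maximal weighted Newman modularity Q is returned (edgeless graphs have
Q = 0 by convention; on Q ties the earliest partition wins). An
exhaustive replay oracle verifies the dendrogram maximum, and brute-force
enumeration of all set partitions (feasible to 8 nodes) verifies global
optimality on the sparse, tightly-clustered graphs this statistic is
designed for. On dense graphs with strongly overlapping clusters the
greedy removal sequence can miss the global modularity optimum — a known
property of the algorithm, not of this implementation.

## Membrane simulation and current-clamp features

**Model.** Leaky integrate-and-fire with a spike-triggered AHP
conductance: C dV/dt = (E − V)/R + I_inj + g(t)(E_AHP − V), with g
incremented by a fixed amount at each spike and decaying exponentially
(tau_AHP). At threshold crossing a stereotyped 2-ms spike waveform is
spliced in: a linear rise (0.6 ms) from the threshold voltage to
threshold + 90 mV, then a linear fall to the reset potential. The splice
gives dV/dt-based threshold extraction an exact target: the voltage at
which the stereotyped upstroke begins is the configured threshold.

Defaults approximate an immature granule cell: E = −67 mV, R = 400 MΩ,
tau = 30 ms, threshold = −40 mV, reset = −52 mV, AHP increment 4 nS with
tau 15 ms and reversal −75 mV. The analytic rheobase is
(V_th − E)/R = 67.5 pA, between the 50 and 100 pA steps of the default
protocol.

**Integration.** Exponential Euler at a 0.02 ms internal step (the AHP
conductance is held constant across each step), linearly resampled to the
output sampling interval. Output sampling defaults to 0.05 ms (20 kHz), a
common current-clamp acquisition rate; no acquisition rate is prescribed
by the assays themselves, so this is a convention. Noise, when enabled,
is an Ornstein–Uhlenbeck-like voltage perturbation scaled so its
stationary SD equals `noise_sd`.

**Protocols.** Steps default to 500 ms: first-spike latencies of newborn
granule cells commonly exceed 100 ms, so short steps would truncate the
latency and AHP measurements. The step family is −100…+400 pA in 50 pA
increments; the ramp is −50→200 pA in 1500 ms.

**Feature conventions.**

- *AP threshold*: walking back from the point of maximal dV/dt on the
  upstroke, the voltage at which the centred-difference dV/dt last
  exceeds 20 mV/ms, linearly interpolated between bracketing samples. An
  optional 3-point median filter before differentiation is off by
  default. A zero criterion degenerates to the search-window start.
- *AHP amplitude*: post-peak voltage minimum minus threshold voltage
  (negative). *AHP duration*: from the downward threshold crossing after
  the peak to the recovery back to threshold, truncated at the next
  spike onset. An independent oracle integrates the same ODE with an
  adaptive solver (rtol 1e−10) and root-finds the recovery; the
  trace-based measurement agrees within 2%.
- *Input resistance*: steady-state deflection of the −100 pA step (mean
  of the last 20% of the step) divided by the current.
- *Rise time*: threshold-to-peak time by default. A 10–90% variant is
  available; the threshold-to-peak convention is the one consistent with
  rise times of tens of ms reported for immature cells, which a 10–90%
  AP upstroke measure (sub-ms) cannot produce.
- *Latency*: step onset to first spike peak. *ISI*: mean adjacent-spike
  interval on the sweep with the most spikes.
- *f–I slope*: each adjacent spike pair contributes instantaneous
  frequency 1/ISI paired with the ramp current at the interval midpoint;
  ordinary least squares gives the slope. Fewer than two spikes is an
  error (the cell is reported as non-fitting).
- *Firing class*: silent if no sweep spikes; single if the busiest sweep
  has exactly one spike; repetitive otherwise.

## sEPSC template detection

**Template.** T(t) ∝ exp(−t/τ_decay) − exp(−t/τ_rise), normalised by the
analytic peak value so the continuous-time peak is 1 (the discrete grid
maximum undershoots by at most ~2×10⁻⁴ at the default grid). Defaults
τ_rise = 0.5 ms, τ_decay = 5 ms, window 20 ms — typical granule-cell EPSC
kinetics.

**Detection.** Pearson correlation r(t) between the template and each
trace window, computed with FFT convolution (O(N log L)); correlation is
mean-subtracted, so the detector is exactly invariant to baseline
offsets. Candidates are local maxima of r above the threshold (default
0.6) at least one refractory period (2 ms) apart; an upward-crossing rule
would miss the second event of pairs closer than one template length.
Candidates are validated in time order against the residual trace after
subtracting already-accepted fitted events: windows that correlated only
because they sat on a predecessor's decay tail lose their correlation on
the residual and are rejected. Amplitude is the least-squares template
scale on the residual; events below the minimum amplitude (default 3× a
MAD-based noise SD estimated from first differences) are discarded.
Half-width is the time the event spends above half its fitted amplitude.

**Polarity.** Voltage clamp at −60 mV gives inward (negative) EPSCs; the
trace is sign-flipped internally and amplitudes are reported as absolute
values.

**Calibration.** The threshold/refractory/minimum-amplitude defaults are
calibrated on the generator: at 1 Hz, 50 pA mean amplitude and 5 pA
noise (60 s traces) the detector reaches ≈0.99 sensitivity and ≈1.0
precision with a 2 ms match window, and produces no false positives on
event-free noise (the 12-sigma correlation threshold at the 200-sample
window makes noise-only detections essentially impossible). Sensitivity
losses are dominated by event pairs closer than the refractory period.

**Generator.** Poisson event count over the trace, uniform onsets,
Gaussian amplitudes truncated at 0 (negligible truncation at the default
50 ± 10 pA), each event adding a scaled copy of the detection template to
Gaussian baseline noise, sampled at 10 kHz (a standard voltage-clamp
acquisition rate). Using the same kernel for generation and detection is
deliberate — the generator is the detector's ground-truth oracle, not a
model of kinetic variability; real events vary in kinetics, so the
measured operating point is an upper bound on real-data performance.

## Morphometry

SWC files are parsed with strict validation (exactly one root, parents
defined before children — which also excludes cycles — and error
messages naming the offending line). Branch tips are non-soma nodes with
no children. Sholl intersections at radius r count parent→child segments
whose endpoint distances from the soma straddle r
(min < r ≤ max); a segment spanning several shells counts once per
shell, and no resampling is performed. Distances are 3-D Euclidean from
the root node; a planar option collapses z for single-plane tracings.
Soma- and axon-typed nodes are excluded. Radii run from one step (10 um
default) to the smallest multiple covering the farthest dendritic point.

The tree generator grows fixed-length (20 um) segments breadth-first
from `n_stems` primary dendrites, bifurcating with a per-segment
probability (default 0.3, ±30° branch angles with Gaussian jitter) until
a total cable-length budget (default 600 um) is exhausted. It produces
granule-cell-scale arbors with known topology; it does not model
tortuosity, tapering, spines, or boundary effects of the granule-cell
layer.

## Group statistics

- *Pooled (Student) rather than Welch t-test* as the default: group
  comparisons in this field are reported as mean ± SEM with small n, and
  the pooled test is the one whose p-values are exactly recomputable
  from printed summaries (sd = sem·√n, df = n₁ + n₂ − 2). A Welch flag
  is provided. All tests are two-tailed.
- *Recomputation precision.* The six cohort comparisons shipped with the
  acceptance script reproduce their two-tailed p-values from printed
  summaries; since the summaries are themselves rounded to 3–4 figures,
  agreement is asserted to ±5×10⁻⁴ (e.g. cells-per-cluster gives 0.0520
  from rounded inputs where unrounded data gave 0.0523).
- *D'Agostino–Pearson K²* combines the finite-sample skewness and
  kurtosis z-transforms; it matches `scipy.stats.normaltest` to
  numerical precision for n ≥ 8. Below n = 8 the transforms are
  undefined and the implementation falls back to large-sample normal
  approximations, with a warning below n = 20 either way.
- *Sholl ANOVA.* Two-factor fixed-effects ANOVA (treatment × radius,
  type-II sums of squares via statsmodels OLS) treating each
  (cell, radius) count as an independent observation — consistent with
  per-radius mean ± SEM reporting, but anticonservative for the radius
  factor because within-cell correlation across radii is ignored; a
  repeated-measures treatment is out of scope and flagged here. Per-
  radius pooled t-tests are adjusted by the Holm–Šídák step-down
  (adjusted p for ascending rank k of m: 1 − (1−p)^(m−k+1), with a
  running maximum; rejection stops at the first non-significant rank).
- *Two-proportion z-test*: pooled standard error, two-tailed normal p.
  Note that for small counts with a zero cell (e.g. 3/20 vs 0/16) the
  pooled z gives p ≈ 0.11; no standard two-proportion formula produces
  extreme significance for such counts, and an exact (Fisher) test is
  even more conservative.

## Pipeline, seeds and outputs

One global seed fans out to named per-stage seeds through SHA-256, so
every generator stream is independent and stable under changes to other
stages' parameters; all derived seeds are below 2³¹. All outputs are
plain CSV/JSON (diffable in tests); each run writes a manifest with the
tool version, a config echo, and SHA-256 checksums of inputs. The YAML
run config rejects unknown keys by name and validates ranges.

## Problem sizes in the acceptance script

The shipped acceptance computation uses: 200 community-detection
instances of 3–8 nodes (brute force enumerates ≤ 4140 partitions each);
50 Thomas-process maps of 8 sections each for cluster recovery; 20
sixty-second sEPSC traces plus 100 event-free traces; single noise-free
cells for electrophysiology recovery; and 10,000 null replicates (n = 10
per group) for t-test calibration. These sizes give Monte-Carlo standard
errors comfortably below the tolerances they are compared against.

## Known limitations

- The LIF + splice membrane is a measurement target, not a biophysical
  model: no Na/K channel kinetics, no spike-height adaptation, no Ih.
- The cluster statistic is 2-D and per-section by design; stereological
  corrections and 3-D reconstruction across sections are out of scope.
- The detector estimates kinetics only through the fixed template; it is
  not a deconvolution method and does not fit per-event time constants.
- Synthetic data share the analysis's own structural assumptions
  (Gaussian scatter, Poisson timing, template-shaped events); passing
  recovery tests demonstrates correctness of the measurement chain, not
  robustness to model mismatch in real recordings.
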