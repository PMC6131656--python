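"""Current-clamp feature extraction for granule-cell recordings.

Extracts the standard passive and active membrane properties used to stage
adult-born granule cell maturation: input resistance and resting baseline
from hyperpolarizing steps; action-potential threshold by the 20 mV/ms
rate-of-rise criterion; AP peak amplitude, half-width, rise time and
latency; afterhyperpolarization amplitude and duration; the instantaneous
frequency-current (f-I) slope from ramp injections; and a coarse firing
class (silent / single / repetitive) from a step family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .core import Trace

__all__ = [
    "StepProtocol", "RampProtocol", "ApFeatures", "CellFeatures",
    "detect_spikes", "ap_threshold", "ahp_metrics", "passive_properties",
    "fi_ramp_slope", "classify_firing", "extract_cell_features",
]

DVDT_CRITERION = 20.0  # mV/ms, the rate-of-rise threshold criterion


@dataclass(frozen=True)
class StepProtocol:
    """Family of square current steps.

    Defaults: 50 pA increments from -100 to +400 pA. The step length is
    configurable and defaults to 500 ms (first-spike latencies above 100 ms
    are routinely observed in immature granule cells, so shorter steps
    would truncate the latency measurement).
    """

    step_start_ms: float = 100.0
    step_duration_ms: float = 500.0
    post_ms: float = 200.0
    amplitudes_pa: tuple = tuple(range(-100, 401, 50))

    def __post_init__(self):
        if self.step_duration_ms <= 0:
            raise ValueError("step duration must be positive")
        if not np.all(np.isfinite(self.amplitudes_pa)):
            raise ValueError("step amplitudes must be finite")

    def current(self, t_ms: np.ndarray, amplitude_pa: float) -> np.ndarray:
        on = (t_ms >= self.step_start_ms) & (
            t_ms < self.step_start_ms + self.step_duration_ms
        )
        return np.where(on, amplitude_pa, 0.0)

    @property
    def total_ms(self) -> float:
        return self.step_start_ms + self.step_duration_ms + self.post_ms


@dataclass(frozen=True)
class RampProtocol:
    """Linear current ramp, default -50 -> +200 pA over 1500 ms."""

    start_pa: float = -50.0
    end_pa: float = 200.0
    ramp_duration_ms: float = 1500.0
    baseline_ms: float = 100.0
    post_ms: float = 100.0

    def __post_init__(self):
        if self.ramp_duration_ms <= 0:
            raise ValueError("ramp duration must be positive")

    def current(self, t_ms: np.ndarray) -> np.ndarray:
        rel = (t_ms - self.baseline_ms) / self.ramp_duration_ms
        ramp = self.start_pa + (self.end_pa - self.start_pa) * rel
        out = np.where((rel >= 0) & (rel <= 1), ramp, 0.0)
        return out

    def current_at(self, t_ms: float) -> float:
        return float(self.current(np.asarray([t_ms]))[0])

    @property
    def total_ms(self) -> float:
        return self.baseline_ms + self.ramp_duration_ms + self.post_ms


@dataclass
class ApFeatures:
    """Single-AP and spike-train features from one sweep (Table-style set)."""

    threshold_mv: float = np.nan
    peak_amplitude_mv: float = np.nan
    half_width_ms: float = np.nan
    rise_time_ms: float = np.nan
    latency_ms: float = np.nan
    rate_of_rise_mv_per_ms: float = np.nan
    ahp_amplitude_mv: float = np.nan
    ahp_duration_ms: float = np.nan
    isi_ms: float = np.nan
    n_spikes: int = 0


@dataclass
class CellFeatures:
    input_resistance_mohm: float = np.nan
    baseline_mv: float = np.nan
    ap: ApFeatures = field(default_factory=ApFeatures)
    fi_slope_hz_per_pa: float = np.nan
    firing_class: str = "silent"


def _require_voltage(trace: Trace):
    if trace.units != "mV":
        raise ValueError("expected a voltage (mV) trace")


def detect_spikes(trace: Trace, peak_cut_mv: float = 0.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Spike peak times (ms): local maxima above ``peak_cut_mv`` separated
    by at least ``refractory_ms``."""
    _require_voltage(trace)
    dist = max(1, int(round(refractory_ms / trace.sampling_interval)))
    peaks, _ = _signal.find_peaks(trace.values, height=peak_cut_mv, distance=dist)
    return peaks * trace.sampling_interval


def _dvdt(values: np.ndarray, dt: float, median_filter: bool) -> np.ndarray:
    v = values
    if median_filter:
        v = _signal.medfilt(v, kernel_size=3)
    return np.gradient(v, dt)


def ap_threshold(
    trace: Trace,
    spike_time_ms: float,
    criterion_mv_per_ms: float = DVDT_CRITERION,
    search_window_ms: float = 5.0,
    median_filter: bool = False,
) -> float:
    """AP threshold: voltage at which the rate of rise exceeds the criterion.

    Walks backward from the spike peak through the upstroke; the threshold
    is the voltage at the last point (closest to rest) where the
    centred-difference dV/dt still exceeds ``criterion_mv_per_ms``, linearly
    interpolated between the bracketing samples. ``criterion=0`` degenerates
    to the voltage at the start of the search window.
    """
    _require_voltage(trace)
    dt = trace.sampling_interval
    peak_idx = int(round(spike_time_ms / dt))
    start_idx = max(0, peak_idx - int(round(search_window_ms / dt)))
    if peak_idx - start_idx < 2:
        raise ValueError("insufficient pre-spike window for threshold search")
    dvdt = _dvdt(trace.values, dt, median_filter)
    if criterion_mv_per_ms <= 0:
        return float(trace.values[start_idx])
    # the crest of the AP flattens (dV/dt -> 0 at the peak), so start the
    # backward walk from the point of maximal rate of rise on the upstroke
    j = start_idx + int(np.argmax(dvdt[start_idx : peak_idx + 1]))
    if dvdt[j] <= criterion_mv_per_ms:
        raise ValueError("dV/dt never exceeds the criterion before the peak "
                         "(malformed spike)")
    i = j
    while i > start_idx and dvdt[i - 1] > criterion_mv_per_ms:
        i -= 1
    if i == 0 or dvdt[i - 1] > criterion_mv_per_ms:  # still rising at window edge
        raise ValueError("dV/dt exceeds the criterion throughout the search window")
    # bracketing samples: i-1 (below criterion) and i (above); interpolate
    d0, d1 = dvdt[i - 1], dvdt[i]
    frac = (criterion_mv_per_ms - d0) / (d1 - d0)
    v0, v1 = trace.values[i - 1], trace.values[i]
    return float(v0 + frac * (v1 - v0))


def ahp_metrics(
    trace: Trace,
    spike_time_ms: float,
    threshold_mv: float,
    next_spike_time_ms: float | None = None,
    max_window_ms: float = 200.0,
) -> tuple[float, float]:
    """Afterhyperpolarization amplitude (mV, negative) and duration (ms).

    Amplitude is the post-peak voltage minimum minus the AP threshold
    voltage (negative by convention). Duration runs from the downward
    crossing of the threshold voltage after the peak to the recovery back
    up to that voltage, truncated at the next spike onset when firing is
    repetitive.
    """
    _require_voltage(trace)
    dt = trace.sampling_interval
    peak_idx = int(round(spike_time_ms / dt))
    if next_spike_time_ms is not None:
        end_idx = int(round(next_spike_time_ms / dt))
    else:
        end_idx = min(trace.values.size, peak_idx + int(round(max_window_ms / dt)))
    seg = trace.values[peak_idx:end_idx]
    if seg.size < 3:
        raise ValueError("insufficient post-spike trace for AHP measurement")

    below = np.flatnonzero(seg < threshold_mv)
    if below.size == 0:
        raise ValueError("voltage never re-crosses threshold downward (plateau)")
    down = below[0]
    amplitude = float(seg.min() - threshold_mv)

    after_min = seg[down:]
    recross = np.flatnonzero(after_min >= threshold_mv)
    if recross.size:
        up = down + recross[0]
    else:
        up = seg.size  # truncated at next spike onset / window end
    duration = float((up - down) * dt)
    return amplitude, duration


def passive_properties(
    sweeps: dict[float, Trace],
    step: StepProtocol,
    probe_pa: float = -100.0,
    tail_fraction: float = 0.2,
) -> tuple[float, float]:
    """(input resistance in MOhm, baseline in mV) from a hyperpolarizing step.

    Baseline is the mean pre-step voltage; the steady-state deflection is
    the mean over the last ``tail_fraction`` of the step. R = dV / I.
    """
    if probe_pa not in sweeps:
        candidates = [a for a in sweeps if a < 0]
        if not candidates:
            raise ValueError("no subthreshold hyperpolarizing sweep available")
        probe_pa = max(candidates, key=abs)
    trace = sweeps[probe_pa]
    _require_voltage(trace)
    dt = trace.sampling_interval
    i0 = int(round(step.step_start_ms / dt))
    i1 = int(round((step.step_start_ms + step.step_duration_ms) / dt))
    baseline = float(np.mean(trace.values[:i0]))
    tail = trace.values[i1 - int(tail_fraction * (i1 - i0)) : i1]
    dv = float(np.mean(tail)) - baseline
    # dV[mV] / I[pA] -> GOhm; x1000 -> MOhm
    r_mohm = dv / probe_pa * 1000.0
    if r_mohm <= 0:
        raise ValueError("non-positive input resistance estimate")
    return r_mohm, baseline


def fi_ramp_slope(trace: Trace, ramp: RampProtocol) -> float:
    """OLS slope (Hz/pA) of instantaneous frequency vs ramp current.

    Each adjacent spike pair contributes f = 1/ISI at the current injected
    at the midpoint of that interval. Requires >= 2 spikes.
    """
    spikes = detect_spikes(trace)
    if spikes.size < 2:
        raise ValueError("fewer than 2 spikes during the ramp: slope undefined")
    isi_s = np.diff(spikes) / 1000.0
    freq = 1.0 / isi_s
    mids = (spikes[:-1] + spikes[1:]) / 2.0
    currents = np.array([ramp.current_at(t) for t in mids])
    slope = np.polyfit(currents, freq, 1)[0]
    return float(slope)


def classify_firing(sweeps: dict[float, Trace]) -> str:
    """'silent' | 'single' | 'repetitive' from a step-family response."""
    max_spikes = 0
    for trace in sweeps.values():
        max_spikes = max(max_spikes, detect_spikes(trace).size)
    if max_spikes == 0:
        return "silent"
    return "single" if max_spikes == 1 else "repetitive"


def _ap_features_from_sweep(
    trace: Trace, step: StepProtocol, rise_variant: str
) -> ApFeatures:
    dt = trace.sampling_interval
    spikes = detect_spikes(trace)
    feats = ApFeatures(n_spikes=int(spikes.size))
    if spikes.size == 0:
        return feats
    t0 = spikes[0]
    thr = ap_threshold(trace, t0)
    feats.threshold_mv = thr
    peak_idx = int(round(t0 / dt))
    peak_v = trace.values[peak_idx]
    feats.peak_amplitude_mv = float(peak_v - thr)
    feats.latency_ms = float(t0 - step.step_start_ms)

    # upstroke landmarks between threshold crossing and peak
    seg_start = max(0, peak_idx - int(round(5.0 / dt)))
    upstroke = trace.values[seg_start : peak_idx + 1]
    above = np.flatnonzero(upstroke >= thr)
    onset_idx = seg_start + (above[0] if above.size else 0)
    if rise_variant == "threshold-to-peak":
        feats.rise_time_ms = float((peak_idx - onset_idx) * dt)
    else:  # 10-90% of threshold-to-peak amplitude
        lo = thr + 0.1 * (peak_v - thr)
        hi = thr + 0.9 * (peak_v - thr)
        seg = trace.values[onset_idx : peak_idx + 1]
        i_lo = np.flatnonzero(seg >= lo)
        i_hi = np.flatnonzero(seg >= hi)
        if i_lo.size and i_hi.size:
            feats.rise_time_ms = float((i_hi[0] - i_lo[0]) * dt)
    dvdt = _dvdt(trace.values, dt, False)
    feats.rate_of_rise_mv_per_ms = float(dvdt[onset_idx : peak_idx + 1].max())

    # half-width at half of threshold-to-peak amplitude
    half = thr + 0.5 * (peak_v - thr)
    left = trace.values[seg_start : peak_idx + 1]
    right_stop = min(trace.values.size, peak_idx + int(round(5.0 / dt)))
    right = trace.values[peak_idx:right_stop]
    l_idx = np.flatnonzero(left >= half)
    r_idx = np.flatnonzero(right < half)
    if l_idx.size and r_idx.size:
        t_left = (seg_start + l_idx[0]) * dt
        t_right = (peak_idx + r_idx[0]) * dt
        feats.half_width_ms = float(t_right - t_left)

    nxt = spikes[1] if spikes.size > 1 else None
    try:
        feats.ahp_amplitude_mv, feats.ahp_duration_ms = ahp_metrics(
            trace, t0, thr, next_spike_time_ms=nxt
        )
    except ValueError:
        pass
    if spikes.size > 1:
        feats.isi_ms = float(np.mean(np.diff(spikes)))
    return feats


def extract_cell_features(
    step_sweeps: dict[float, Trace],
    step: StepProtocol,
    ramp_trace: Trace | None = None,
    ramp: RampProtocol | None = None,
    ap_sweep_pa: float = 100.0,
    rise_variant: str = "threshold-to-peak",
) -> CellFeatures:
    """Full per-cell feature set from a step family plus optional ramp.

    Single-AP features come from the ``ap_sweep_pa`` sweep (100 pA by
    convention); ISI from the sweep with the most spikes.
    """
    feats = CellFeatures()
    feats.input_resistance_mohm, feats.baseline_mv = passive_properties(
        step_sweeps, step
    )
    feats.firing_class = classify_firing(step_sweeps)

    if ap_sweep_pa in step_sweeps:
        feats.ap = _ap_features_from_sweep(
            step_sweeps[ap_sweep_pa], step, rise_variant
        )
    busiest = max(step_sweeps, key=lambda a: detect_spikes(step_sweeps[a]).size)
    busiest_spikes = detect_spikes(step_sweeps[busiest])
    if busiest_spikes.size > 1:
        feats.ap.isi_ms = float(np.mean(np.diff(busiest_spikes)))

    if ramp_trace is not None and ramp is not None:
        try:
            feats.fi_slope_hz_per_pa = fi_ramp_slope(ramp_trace, ramp)
        except ValueError:
            feats.fi_slope_hz_per_pa = np.nan
    return feats
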