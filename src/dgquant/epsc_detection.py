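"""Template-correlation detection of spontaneous EPSCs.

The detector slides a unit-peak double-exponential template along a
voltage-clamp current trace and computes the Pearson correlation between
the template and each trace window. Upward threshold crossings of the
correlation, refined to the local correlation maximum, give candidate
event onsets; the event amplitude is the least-squares scale of the
template fitted to the window. Because the correlation is mean-subtracted
the detector is insensitive to the holding-current baseline.

Cells are held at -60 mV, so EPSCs are inward (negative) deflections; the
trace is sign-flipped internally and amplitudes are reported as absolute
values in pA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EventList, Trace

__all__ = ["PscTemplate", "DetectionParams", "make_template", "detect_events",
           "event_metrics", "robust_noise_sd"]


@dataclass
class PscTemplate:
    """Unit-peak double-exponential difference template.

    T(t) = N * (exp(-t/tau_decay) - exp(-t/tau_rise)), with N chosen so
    max(T) = 1; T(0) = 0 by construction.
    """

    tau_rise: float
    tau_decay: float
    sampling_interval: float
    values: np.ndarray

    @property
    def length_ms(self) -> float:
        return self.values.size * self.sampling_interval

    @property
    def peak_time_ms(self) -> float:
        """Analytic time-to-peak: t* = ln(tau_d/tau_r) * tau_r*tau_d/(tau_d-tau_r)."""
        tr, td = self.tau_rise, self.tau_decay
        return np.log(td / tr) * tr * td / (td - tr)


def make_template(
    tau_rise: float = 0.5,
    tau_decay: float = 5.0,
    dt: float = 0.1,
    length: float = 20.0,
) -> PscTemplate:
    """Build a unit-peak EPSC template (times in ms)."""
    if not (tau_decay > tau_rise > 0):
        raise ValueError("require tau_decay > tau_rise > 0")
    t = np.arange(0.0, length, dt)
    raw = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    # analytic peak of the double exponential, avoids grid-dependent norm
    t_star = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    peak = np.exp(-t_star / tau_decay) - np.exp(-t_star / tau_rise)
    return PscTemplate(tau_rise, tau_decay, dt, raw / peak)


@dataclass
class DetectionParams:
    """Operating point of the sliding-window correlation detector.

    ``min_amplitude=None`` uses 3x the robust (MAD-based) noise SD of the
    trace, estimated from first differences so events barely inflate it.
    """

    correlation_threshold: float = 0.6
    refractory_ms: float = 2.0
    min_amplitude_pa: float | None = None
    polarity: str = "inward"

    def __post_init__(self):
        if not (0 < self.correlation_threshold < 1):
            raise ValueError("correlation_threshold must lie in (0, 1)")
        if self.refractory_ms < 0:
            raise ValueError("refractory must be non-negative")
        if self.polarity not in ("inward", "outward"):
            raise ValueError("polarity must be 'inward' or 'outward'")


def robust_noise_sd(values: np.ndarray) -> float:
    """MAD-based noise SD from first differences (event-resistant)."""
    d = np.diff(np.asarray(values, dtype=float))
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _sliding_correlation(y: np.ndarray, template: np.ndarray):
    """Pearson r between each length-L window of y and the template.

    Returns (r, scale) where scale[t] is the least-squares template
    amplitude fitted at offset t. Vectorised with FFT convolution; O(N log L).
    """
    L = template.size
    tc = template - template.mean()
    ss_t = float(np.dot(tc, tc))
    # sliding dot product sum_k y[t+k] * tc[k]
    dot = signal.oaconvolve(y, tc[::-1], mode="valid")
    win = np.ones(L)
    s1 = signal.oaconvolve(y, win, mode="valid")
    s2 = signal.oaconvolve(y * y, win, mode="valid")
    ss_y = np.maximum(s2 - s1 * s1 / L, 0.0)
    den = np.sqrt(ss_y * ss_t)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, dot / den, 0.0)
    scale = dot / ss_t
    return r, scale


def detect_events(
    trace: Trace,
    template: PscTemplate,
    params: DetectionParams | None = None,
) -> EventList:
    """Run the sliding-window correlation detector on a current trace."""
    params = params or DetectionParams()
    if trace.units != "pA":
        raise ValueError("detector expects a current (pA) trace")
    if abs(trace.sampling_interval - template.sampling_interval) > 1e-12:
        raise ValueError("template and trace sampling intervals differ")
    y = trace.values.astype(float)
    if params.polarity == "inward":
        y = -y
    L = template.values.size
    if L >= y.size:
        raise ValueError("template must be shorter than the trace")

    min_amp = params.min_amplitude_pa
    if min_amp is None:
        min_amp = 3.0 * robust_noise_sd(y)

    r, _ = _sliding_correlation(y, template.values)
    thr = params.correlation_threshold
    dt = trace.sampling_interval
    refractory = max(1, int(round(params.refractory_ms / dt)))
    # candidate onsets: local maxima of r above the threshold; a plain
    # upward-crossing rule would miss the second event of a pair closer
    # than one template length, where r never dips below the threshold
    peaks, _props = signal.find_peaks(r, height=thr, distance=refractory)

    # validate candidates in time order against the residual trace with
    # already-accepted events subtracted: windows that correlated only
    # because they sat on the decay tail of an earlier event lose their
    # correlation once that event is removed
    tmpl_v = template.values
    tc = tmpl_v - tmpl_v.mean()
    ss_t = float(np.dot(tc, tc))
    residual = y.copy()
    onsets_idx: list[int] = []
    amplitudes: list[float] = []
    last = -np.inf
    for k in peaks:
        if k - last < refractory:
            continue
        win = residual[k : k + L]
        wc = win - win.mean()
        ss_w = float(np.dot(wc, wc))
        if ss_w <= 0:
            continue
        dot = float(np.dot(wc, tc))
        if dot / np.sqrt(ss_w * ss_t) < thr:
            continue
        amp = dot / ss_t  # least-squares template scale
        if amp < min_amp:
            continue
        residual[k : k + L] -= amp * tmpl_v
        onsets_idx.append(int(k))
        amplitudes.append(float(amp))
        last = k

    half_widths = [
        _half_width_ms(y, k, L, amp, dt) for k, amp in zip(onsets_idx, amplitudes)
    ]
    duration_s = trace.values.size * dt / 1000.0
    return EventList(
        onsets_s=np.asarray(onsets_idx, dtype=float) * dt / 1000.0,
        amplitudes_pa=np.asarray(amplitudes),
        half_widths_ms=np.asarray(half_widths),
        duration_s=duration_s,
        params={
            "correlation_threshold": thr,
            "refractory_ms": params.refractory_ms,
            "min_amplitude_pa": float(min_amp),
            "polarity": params.polarity,
            "tau_rise": template.tau_rise,
            "tau_decay": template.tau_decay,
        },
    )


def _half_width_ms(y, onset, L, amp, dt) -> float:
    """Width of the event above half its fitted amplitude, in ms."""
    win = y[onset : onset + L]
    base = win[0]
    rel = win - base
    half = amp / 2.0
    above = np.flatnonzero(rel >= half)
    if above.size == 0:
        return np.nan
    return float((above[-1] - above[0] + 1) * dt)


def event_metrics(events: EventList) -> dict:
    """Per-cell summary: mean |amplitude| (pA), mean half-width (ms), frequency (Hz)."""
    out = {"n_events": len(events), "frequency_hz": events.frequency_hz}
    if len(events) == 0:
        warnings.warn("empty event list: amplitude/half-width undefined")
        out["mean_amplitude_pa"] = np.nan
        out["mean_half_width_ms"] = np.nan
    else:
        out["mean_amplitude_pa"] = float(np.mean(np.abs(events.amplitudes_pa)))
        out["mean_half_width_ms"] = float(np.nanmean(events.half_widths_ms))
    return out
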