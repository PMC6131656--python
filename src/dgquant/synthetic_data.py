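"""Ground-truth synthetic data for every pipeline stage.

Four generators replace the study's animals and microscopes:

* a Thomas cluster process (Poisson parents, Poisson offspring counts,
  isotropic Gaussian scatter) for progenitor-derived labelled-cell maps —
  parent identity is kept as ground truth for the cluster statistic;
* a leaky integrate-and-fire membrane with a spike-triggered
  afterhyperpolarization conductance and a stereotyped 2-ms spike
  waveform spliced at threshold crossings, so that dV/dt-based threshold
  extraction has an exact target;
* Poisson-timed synaptic currents built from the detector's own unit-peak
  double-exponential kernel, embedded in Gaussian noise, with exact onset
  times and amplitudes as ground truth;
* random branching dendritic trees grown breadth-first in segments, with
  Gaussian direction jitter, emitted as standard SWC.

Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellMap, EventList, Trace
from .ephys_features import RampProtocol, StepProtocol
from .epsc_detection import make_template
from .morphometry import SWC_COLUMNS, Morphology

__all__ = [
    "PointPatternConfig", "MembraneConfig", "SynapticTrainConfig", "TreeConfig",
    "generate_clustered_points", "simulate_membrane", "generate_epsc_trace",
    "generate_tree", "rheobase_pa",
    "SPIKE_WAVEFORM_MS", "SPIKE_RISE_MS", "SPIKE_OVERSHOOT_MV",
]

# ---------------------------------------------------------------------------
# clustered point patterns


@dataclass(frozen=True)
class PointPatternConfig:
    """Thomas-process parameters for labelled-cell maps.

    Defaults emulate sparse proliferative labelling in 40-um sections of
    the ventral dentate gyrus: a handful of progenitors per section, small
    clone sizes, and a few microns of post-mitotic dispersal.
    """

    n_sections: int = 8
    field_width_um: float = 400.0
    field_height_um: float = 400.0
    n_parents_per_section: int = 10
    offspring_mean: float = 2.0
    dispersion_sigma_um: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_sections < 1 or self.n_parents_per_section < 0:
            raise ValueError("counts must be non-negative (sections >= 1)")
        if self.offspring_mean < 0 or self.dispersion_sigma_um < 0:
            raise ValueError("offspring_mean and dispersion_sigma must be >= 0")


def generate_clustered_points(config: PointPatternConfig) -> CellMap:
    """Sample a clustered cell map; each cell carries its parent label.

    Parents are uniform over the field; each parent emits
    Poisson(offspring_mean) cells scattered with isotropic Gaussian sigma
    and clipped to the field. Parents with zero offspring leave no cells.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for sec in range(config.n_sections):
        for p in range(config.n_parents_per_section):
            px = rng.uniform(0, config.field_width_um)
            py = rng.uniform(0, config.field_height_um)
            k = rng.poisson(config.offspring_mean)
            offs = rng.normal(0.0, config.dispersion_sigma_um, size=(k, 2))
            for ox, oy in offs:
                rows.append(
                    {
                        "section": sec,
                        "x_um": float(np.clip(px + ox, 0, config.field_width_um)),
                        "y_um": float(np.clip(py + oy, 0, config.field_height_um)),
                        "parent_id": f"s{sec}p{p}",
                    }
                )
    df = pd.DataFrame(rows, columns=["section", "x_um", "y_um", "parent_id"])
    return CellMap(df)


# ---------------------------------------------------------------------------
# membrane simulation

SPIKE_WAVEFORM_MS = 2.0  # total stereotyped spike duration
SPIKE_RISE_MS = 0.6  # threshold -> peak
SPIKE_OVERSHOOT_MV = 90.0  # peak above threshold

INTERNAL_DT_MS = 0.02  # exponential-Euler integration step


@dataclass(frozen=True)
class MembraneConfig:
    """Leaky integrate-and-fire granule-cell stand-in.

    Defaults approximate an immature dentate granule cell: high input
    resistance, slow membrane, depolarized threshold relative to mature
    cells, and a spike-triggered AHP conductance decaying with ahp_tau.
    """

    resting_potential_mv: float = -67.0
    membrane_resistance_mohm: float = 400.0
    membrane_tau_ms: float = 30.0
    spike_threshold_mv: float = -40.0
    reset_potential_mv: float = -52.0
    ahp_conductance_increment_ns: float = 4.0
    ahp_tau_ms: float = 15.0
    ahp_reversal_mv: float = -75.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.membrane_tau_ms <= 0 or self.ahp_tau_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd must be >= 0")


def _spike_waveform(threshold_v: float, reset_v: float, dt: float) -> np.ndarray:
    """Stereotyped spike: linear rise threshold->peak, linear fall to reset."""
    n_rise = int(round(SPIKE_RISE_MS / dt))
    n_fall = int(round((SPIKE_WAVEFORM_MS - SPIKE_RISE_MS) / dt))
    peak = threshold_v + SPIKE_OVERSHOOT_MV
    rise = np.linspace(threshold_v, peak, n_rise, endpoint=False)
    fall = np.linspace(peak, reset_v, n_fall + 1)  # ends exactly at reset
    return np.concatenate([rise, fall])


def _integrate(
    config: MembraneConfig,
    current_fn,
    total_ms: float,
    sampling_interval_ms: float,
    rng: np.random.Generator,
) -> Trace:
    dt = INTERNAL_DT_MS
    if dt > sampling_interval_ms:
        raise ValueError("integration step exceeds sampling interval")
    n = int(round(total_ms / dt))
    t_int = np.arange(n) * dt
    i_inj = current_fn(t_int)
    tau = config.membrane_tau_ms
    r = config.membrane_resistance_mohm
    e = config.resting_potential_mv
    gr = r * 1e-3  # nS*MOhm*mV -> mV scaling for conductance currents
    decay_g = np.exp(-dt / config.ahp_tau_ms)

    v = np.empty(n)
    v[0] = e
    g = 0.0
    waveform = _spike_waveform(
        config.spike_threshold_mv, config.reset_potential_mv, dt
    )
    spike_onsets = []
    splice_left = 0
    noise = (
        rng.normal(0.0, config.noise_sd_mv * np.sqrt(2.0 * dt / tau), size=n)
        if config.noise_sd_mv > 0
        else None
    )
    k = 0
    while k < n - 1:
        if splice_left > 0:
            v[k + 1] = waveform[len(waveform) - splice_left]
            splice_left -= 1
            g *= decay_g
            k += 1
            if splice_left == 0:
                g += config.ahp_conductance_increment_ns
            continue
        # exponential Euler on dV/dt = -(V - Vss) / tau_eff, where the AHP
        # conductance both shortens tau and pulls Vss toward its reversal
        denom = 1.0 + g * gr
        a = denom / tau
        vss = (e + i_inj[k] * r * 1e-3 + g * gr * config.ahp_reversal_mv) / denom
        nxt = vss + (v[k] - vss) * np.exp(-a * dt)
        if noise is not None:
            nxt += noise[k]
        g *= decay_g
        if nxt >= config.spike_threshold_mv:
            spike_onsets.append((k + 1) * dt)
            splice_left = len(waveform)
            v[k + 1] = waveform[0]
            splice_left -= 1
            k += 1
            continue
        v[k + 1] = nxt
        k += 1

    t_out = np.arange(0.0, total_ms - dt / 2, sampling_interval_ms)
    v_out = np.interp(t_out, t_int, v)
    return Trace(
        v_out,
        sampling_interval_ms,
        units="mV",
        meta={"spike_onsets_ms": spike_onsets, "config": config},
    )


def simulate_membrane(
    config: MembraneConfig,
    protocol: StepProtocol | RampProtocol,
    sampling_interval_ms: float = 0.05,
):
    """Simulate membrane voltage under a step family or a current ramp.

    Returns ``{amplitude_pa: Trace}`` for a :class:`StepProtocol` and a
    single :class:`Trace` for a :class:`RampProtocol`. Noise-free
    simulations are deterministic; spike onset times (threshold
    crossings) are recorded in ``trace.meta['spike_onsets_ms']``.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(protocol, StepProtocol):
        sweeps = {}
        for amp in protocol.amplitudes_pa:
            tr = _integrate(
                config,
                lambda t, a=amp: protocol.current(t, a),
                protocol.total_ms,
                sampling_interval_ms,
                rng,
            )
            tr.protocol = protocol
            tr.meta["amplitude_pa"] = amp
            sweeps[amp] = tr
        return sweeps
    if isinstance(protocol, RampProtocol):
        tr = _integrate(
            config, protocol.current, protocol.total_ms, sampling_interval_ms, rng
        )
        tr.protocol = protocol
        return tr
    raise TypeError(f"unsupported protocol {type(protocol)!r}")


def rheobase_pa(config: MembraneConfig) -> float:
    """Analytic sustained-current rheobase (V_th - E) / R, in pA."""
    return (
        (config.spike_threshold_mv - config.resting_potential_mv)
        / config.membrane_resistance_mohm
        * 1000.0
    )


# ---------------------------------------------------------------------------
# synaptic currents


@dataclass(frozen=True)
class SynapticTrainConfig:
    """Poisson sEPSC train in Gaussian noise (voltage-clamp convention:
    inward events are negative deflections).

    Kinetics default to fast granule-cell EPSCs (rise 0.5 ms, decay 5 ms);
    sampling defaults to 10 kHz, a standard acquisition rate for
    voltage-clamp minis.
    """

    event_rate_hz: float = 1.0
    amplitude_mean_pa: float = 50.0
    amplitude_sd_pa: float = 10.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    baseline_noise_sd_pa: float = 5.0
    duration_s: float = 60.0
    sampling_interval_ms: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("require tau_decay > tau_rise > 0")
        if self.event_rate_hz < 0 or self.duration_s <= 0:
            raise ValueError("rate must be >= 0 and duration positive")


def generate_epsc_trace(
    config: SynapticTrainConfig, template_length_ms: float = 20.0
) -> tuple[Trace, EventList]:
    """Simulate a voltage-clamp trace plus its exact ground truth.

    Event count ~ Poisson(rate * duration); onsets uniform over the trace;
    amplitudes Gaussian truncated at 0. Each event adds
    -amplitude * unit-peak double-exponential to the (zero-baseline) trace.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.sampling_interval_ms
    n = int(round(config.duration_s * 1000.0 / dt))
    tmpl = make_template(
        config.tau_rise_ms, config.tau_decay_ms, dt, template_length_ms
    )
    values = (
        rng.normal(0.0, config.baseline_noise_sd_pa, size=n)
        if config.baseline_noise_sd_pa > 0
        else np.zeros(n)
    )
    n_events = rng.poisson(config.event_rate_hz * config.duration_s)
    onset_idx = np.sort(
        rng.integers(0, max(1, n - tmpl.values.size), size=n_events)
    )
    # collapse duplicate onsets (zero-probability at realistic rates)
    onset_idx = np.unique(onset_idx)
    amps = np.maximum(
        rng.normal(config.amplitude_mean_pa, config.amplitude_sd_pa,
                   size=onset_idx.size),
        0.0,
    )
    for idx, amp in zip(onset_idx, amps):
        stop = min(n, idx + tmpl.values.size)
        values[idx:stop] -= amp * tmpl.values[: stop - idx]

    trace = Trace(values, dt, units="pA", meta={"config": config})
    truth = EventList(
        onsets_s=onset_idx * dt / 1000.0,
        amplitudes_pa=amps,
        half_widths_ms=np.full(onset_idx.size, np.nan),
        duration_s=config.duration_s,
        params={"ground_truth": True},
    ) if onset_idx.size else EventList(
        np.empty(0), np.empty(0), np.empty(0), config.duration_s,
        params={"ground_truth": True},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# dendritic trees


@dataclass(frozen=True)
class TreeConfig:
    """Breadth-first random binary-branching dendritic tree.

    Growth proceeds in fixed-length segments from ``n_stems`` primary
    dendrites; after each segment the branch bifurcates with probability
    ``branch_probability_per_segment``; growth stops when the total cable
    length budget is exhausted. Defaults give granule-cell-like trees with
    a handful of tips within ~150 um of the soma.
    """

    n_stems: int = 2
    branch_probability_per_segment: float = 0.3
    segment_length_um: float = 20.0
    max_total_length_um: float = 600.0
    branch_angle_sd_deg: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.branch_probability_per_segment <= 1.0):
            raise ValueError("branch probability must lie in [0, 1]")
        if self.segment_length_um <= 0:
            raise ValueError("segment length must be positive")


def _rotate_toward(direction: np.ndarray, angle_deg: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Rotate a unit vector by angle_deg about a random perpendicular axis."""
    if angle_deg == 0.0:
        return direction
    perp = np.cross(direction, rng.normal(size=3))
    norm = np.linalg.norm(perp)
    if norm < 1e-12:
        return direction
    perp /= norm
    theta = np.deg2rad(angle_deg)
    rotated = direction * np.cos(theta) + np.cross(perp, direction) * np.sin(theta)
    return rotated / np.linalg.norm(rotated)


def generate_tree(config: TreeConfig) -> Morphology:
    """Grow a random dendritic tree rooted at a soma node (SWC type 1);
    dendrites are SWC type 3. Reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    rows = [(1, 1, 0.0, 0.0, 0.0, 5.0, -1)]
    positions = {1: np.zeros(3)}
    next_id = 2
    budget = config.max_total_length_um
    queue: list[tuple[int, np.ndarray]] = []
    for _ in range(config.n_stems):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        queue.append((1, d))
    while queue and budget >= config.segment_length_um:
        parent_id, direction = queue.pop(0)
        direction = _rotate_toward(
            direction, abs(rng.normal(0.0, config.branch_angle_sd_deg)), rng
        )
        pos = positions[parent_id] + direction * config.segment_length_um
        rows.append((next_id, 3, float(pos[0]), float(pos[1]), float(pos[2]),
                     0.5, parent_id))
        positions[next_id] = pos
        budget -= config.segment_length_um
        if rng.uniform() < config.branch_probability_per_segment:
            queue.append((next_id, _rotate_toward(direction, 30.0, rng)))
            queue.append((next_id, _rotate_toward(direction, -30.0, rng)))
        else:
            queue.append((next_id, direction))
        next_id += 1
    nodes = pd.DataFrame(rows, columns=SWC_COLUMNS)
    return Morphology(nodes)
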