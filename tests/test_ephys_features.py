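"""Current-clamp feature extraction: constructed-trace identities, generator
parameter recovery, and an independent ODE oracle for AHP recovery."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dgquant.ephys_features import (
    RampProtocol,
    StepProtocol,
    ahp_metrics,
    ap_threshold,
    classify_firing,
    detect_spikes,
    fi_ramp_slope,
    passive_properties,
)
from dgquant.synthetic_data import (
    SPIKE_OVERSHOOT_MV,
    SPIKE_RISE_MS,
    SPIKE_WAVEFORM_MS,
    MembraneConfig,
    simulate_membrane,
)
from conftest import make_trace


def splice_spike(values, dt, onset_ms, v_th=-40.0, reset=-52.0):
    """Insert the generator's stereotyped spike shape into a flat trace."""
    n_rise = int(round(SPIKE_RISE_MS / dt))
    n_fall = int(round((SPIKE_WAVEFORM_MS - SPIKE_RISE_MS) / dt))
    peak = v_th + SPIKE_OVERSHOOT_MV
    wf = np.concatenate([
        np.linspace(v_th, peak, n_rise, endpoint=False),
        np.linspace(peak, reset, n_fall + 1),
    ])
    k = int(round(onset_ms / dt))
    values[k:k + wf.size] = wf[: max(0, values.size - k)]
    return values


class TestDetectSpikes:
    def test_flat_trace_silent(self):
        tr = make_trace(np.full(4000, -70.0))
        assert detect_spikes(tr).size == 0

    def test_three_spliced_spikes_detected_at_splice_times(self):
        dt = 0.05
        v = np.full(8000, -70.0)
        for onset in (50.0, 150.0, 250.0):
            splice_spike(v, dt, onset)
        tr = make_trace(v, dt)
        peaks = detect_spikes(tr)
        assert peaks.size == 3
        expected = np.array([50.0, 150.0, 250.0]) + SPIKE_RISE_MS
        assert np.all(np.abs(peaks - expected) <= dt + 1e-9)

    def test_refractory_merges_half_ms_doublet(self):
        dt = 0.05
        v = np.full(2000, -70.0)
        # two narrow peaks 0.5 ms apart
        for onset in (20.0, 20.5):
            k = int(round(onset / dt))
            v[k] = 30.0
        assert detect_spikes(make_trace(v, dt)).size == 1

    def test_current_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(make_trace(np.zeros(100), units="pA"))


class TestApThreshold:
    def test_piecewise_linear_crossing(self):
        # rise at 10 mV/ms then 40 mV/ms switching at -42 mV
        dt = 0.05
        seg1 = np.arange(-50, -42, 10 * dt)
        seg2 = np.arange(-42, 20, 40 * dt)
        v = np.concatenate([np.full(200, -50.0), seg1, seg2])
        tr = make_trace(v, dt)
        peak_t = (v.size - 1) * dt
        thr = ap_threshold(tr, peak_t, criterion_mv_per_ms=20.0)
        assert thr == pytest.approx(-42.0, abs=0.75)

    def test_zero_criterion_returns_window_start_voltage(self):
        dt = 0.05
        v = np.full(400, -60.0)
        splice_spike(v, dt, 10.0)
        tr = make_trace(v, dt)
        peak = detect_spikes(tr)[0]
        assert ap_threshold(tr, peak, criterion_mv_per_ms=0.0) == pytest.approx(
            -60.0, abs=0.1)

    def test_generator_spike_recovers_configured_threshold(self, noiseless_sweeps,
                                                           noiseless_membrane):
        tr = noiseless_sweeps[100]
        peak = detect_spikes(tr)[0]
        thr = ap_threshold(tr, peak)
        assert thr == pytest.approx(noiseless_membrane.spike_threshold_mv, abs=0.5)

    def test_criterion_monotonicity(self, noiseless_sweeps):
        # a stricter (higher) dV/dt criterion can only move the threshold up
        tr = noiseless_sweeps[100]
        peak = detect_spikes(tr)[0]
        thresholds = [ap_threshold(tr, peak, criterion_mv_per_ms=c)
                      for c in (5.0, 20.0, 60.0, 120.0)]
        assert np.all(np.diff(thresholds) >= -1e-9)

    def test_never_exceeding_criterion_raises(self):
        dt = 0.05
        v = np.concatenate([np.full(200, -60.0), np.arange(-60, 10, 5 * dt)])
        tr = make_trace(v, dt)
        with pytest.raises(ValueError):
            ap_threshold(tr, (v.size - 1) * dt, criterion_mv_per_ms=500.0)


def ahp_recovery_oracle(config: MembraneConfig, i_pa: float) -> float:
    """Independent prediction of the AHP duration for the first spike under a
    sustained current step: remaining stereotyped-fall time below threshold
    plus the membrane ODE recovery time from reset back to threshold, solved
    with an adaptive integrator."""
    peak = config.spike_threshold_mv + SPIKE_OVERSHOOT_MV
    fall_ms = SPIKE_WAVEFORM_MS - SPIKE_RISE_MS
    t_cross = fall_ms * (peak - config.spike_threshold_mv) / (
        peak - config.reset_potential_mv)
    remaining_fall = fall_ms - t_cross

    gr = config.membrane_resistance_mohm * 1e-3
    tau = config.membrane_tau_ms

    def rhs(t, y):
        g = config.ahp_conductance_increment_ns * np.exp(-t / config.ahp_tau_ms)
        v = y[0]
        return [(config.resting_potential_mv - v + i_pa * gr
                 + g * gr * (config.ahp_reversal_mv - v)) / tau]

    def hit(t, y):
        return y[0] - config.spike_threshold_mv

    hit.terminal = True
    hit.direction = 1
    sol = solve_ivp(rhs, (0, 2000), [config.reset_potential_mv], events=hit,
                    rtol=1e-10, atol=1e-10, max_step=1.0)
    assert sol.t_events[0].size == 1, "membrane never recovers to threshold"
    return remaining_fall + float(sol.t_events[0][0])


class TestAhp:
    def test_amplitude_definition_identity(self):
        dt = 0.05
        v = np.full(6000, -60.0)
        splice_spike(v, dt, 20.0, v_th=-40.0, reset=-48.0)
        k_end = int(round((20.0 + SPIKE_WAVEFORM_MS) / dt))
        v[k_end:] = -48.0
        dip = int(round(40.0 / dt))
        v[dip:dip + 100] = -48.0  # minimum dips to threshold - 8
        v[dip + 100:dip + 200] = np.linspace(-48, -35, 100)
        v[dip + 200:] = -35.0
        tr = make_trace(v, dt)
        amp, _ = ahp_metrics(tr, detect_spikes(tr)[0], threshold_mv=-40.0)
        assert amp == pytest.approx(-8.0, abs=0.01)

    def test_duration_matches_ode_oracle(self, noiseless_membrane):
        step = StepProtocol()
        sweeps = simulate_membrane(noiseless_membrane, step)
        tr = sweeps[100]
        spikes = detect_spikes(tr)
        thr = ap_threshold(tr, spikes[0])
        _, duration = ahp_metrics(tr, spikes[0], thr,
                                  next_spike_time_ms=spikes[1])
        predicted = ahp_recovery_oracle(noiseless_membrane, 100.0)
        assert duration == pytest.approx(predicted, rel=0.02)

    def test_truncation_at_next_spike(self):
        dt = 0.05
        v = np.full(2000, -60.0)
        splice_spike(v, dt, 10.0)
        splice_spike(v, dt, 25.0)
        tr = make_trace(v, dt)
        spikes = detect_spikes(tr)
        _, duration = ahp_metrics(tr, spikes[0], threshold_mv=-40.0,
                                  next_spike_time_ms=spikes[1])
        assert duration <= spikes[1] - spikes[0]

    def test_plateau_raises(self):
        dt = 0.05
        v = np.full(2000, -60.0)
        splice_spike(v, dt, 10.0, reset=-30.0)  # never dips below threshold
        k_end = int(round((10.0 + SPIKE_WAVEFORM_MS) / dt))
        v[k_end:] = -30.0
        tr = make_trace(v, dt)
        with pytest.raises(ValueError):
            ahp_metrics(tr, detect_spikes(tr)[0], threshold_mv=-40.0)


class TestPassive:
    def test_ohms_law_identity(self, step_protocol):
        dt = 0.05
        n = int(step_protocol.total_ms / dt)
        t = np.arange(n) * dt
        v = np.full(n, -70.0)
        on = (t >= step_protocol.step_start_ms) & (
            t < step_protocol.step_start_ms + step_protocol.step_duration_ms)
        v[on] = -80.0  # dV = -10 mV at -100 pA -> 100 MOhm
        r, base = passive_properties({-100.0: make_trace(v, dt)}, step_protocol)
        assert r == pytest.approx(100.0, abs=0.1)
        assert base == pytest.approx(-70.0)

    def test_generator_recovery_noiseless(self, noiseless_sweeps, step_protocol,
                                          noiseless_membrane):
        r, base = passive_properties(noiseless_sweeps, step_protocol)
        assert r == pytest.approx(noiseless_membrane.membrane_resistance_mohm,
                                  rel=0.02)
        assert base == pytest.approx(noiseless_membrane.resting_potential_mv,
                                     abs=0.1)

    def test_noise_recovery_within_five_percent(self, step_protocol):
        ests = []
        for seed in range(20):
            cfg = MembraneConfig(noise_sd_mv=0.5, seed=seed)
            sweeps = simulate_membrane(
                cfg, StepProtocol(amplitudes_pa=(-100,)))
            r, _ = passive_properties(sweeps, step_protocol)
            ests.append(r)
        assert abs(np.mean(ests) - 400.0) < 0.05 * 400.0

    def test_no_subthreshold_sweep_raises(self, step_protocol):
        with pytest.raises(ValueError):
            passive_properties({100.0: make_trace(np.full(100, -70.0))},
                               step_protocol)


class TestFiSlope:
    def test_exact_linear_construction(self):
        # ramp I(t) = 0.1 * t pA; spike times satisfying
        # t_{k+1}^2 - t_k^2 = 2000/(s*0.1) make 1/ISI = s * I(midpoint)
        # exactly, so the OLS slope must equal s (up to sample snapping)
        ramp = RampProtocol(start_pa=0, end_pa=200, ramp_duration_ms=2000,
                            baseline_ms=0, post_ms=0)
        s = 0.1  # Hz/pA
        dt = 0.005
        n = int(2000 / dt)
        v = np.full(n, -70.0)
        t, times = 300.0, []
        while t < 1950.0:
            times.append(t)
            t = np.sqrt(t**2 + 2000.0 / (s * 0.1))
        for st in times:
            v[int(round(st / dt))] = 20.0
        slope = fi_ramp_slope(make_trace(v, dt), ramp)
        assert slope == pytest.approx(s, rel=1e-3)

    def test_single_spike_raises(self):
        dt = 0.05
        v = np.full(10000, -70.0)
        v[5000] = 20.0
        with pytest.raises(ValueError):
            fi_ramp_slope(make_trace(v, dt), RampProtocol())

    def test_lif_ramp_matches_analytic_linearization(self):
        # without adaptation the LIF f-I curve is closed-form; the measured
        # OLS slope should match the slope of the analytic curve sampled at
        # the same currents
        cfg = MembraneConfig(noise_sd_mv=0.0, ahp_conductance_increment_ns=0.0)
        ramp = RampProtocol()
        tr = simulate_membrane(cfg, ramp)
        spikes = detect_spikes(tr)
        assert spikes.size >= 2
        mids = (spikes[:-1] + spikes[1:]) / 2
        currents = np.array([ramp.current_at(t) for t in mids])
        meas_f = 1000.0 / np.diff(spikes)

        tau, r = cfg.membrane_tau_ms, cfg.membrane_resistance_mohm
        vinf = cfg.resting_potential_mv + currents * r * 1e-3

        def f_analytic(vi):
            isi = SPIKE_WAVEFORM_MS + tau * np.log(
                (vi - cfg.reset_potential_mv) / (vi - cfg.spike_threshold_mv))
            return 1000.0 / isi

        slope_meas = np.polyfit(currents, meas_f, 1)[0]
        slope_analytic = np.polyfit(currents, f_analytic(vinf), 1)[0]
        assert slope_meas == pytest.approx(slope_analytic, rel=0.15)


class TestFiringClass:
    def test_all_silent(self):
        sweeps = {a: make_trace(np.full(1000, -70.0)) for a in (0.0, 100.0)}
        assert classify_firing(sweeps) == "silent"

    def test_single_spike_everywhere(self):
        dt = 0.05
        v = np.full(2000, -70.0)
        splice_spike(v, dt, 20.0)
        sweeps = {100.0: make_trace(v, dt)}
        assert classify_firing(sweeps) == "single"

    def test_lif_with_weak_ahp_is_repetitive(self):
        cfg = MembraneConfig(noise_sd_mv=0.0, ahp_conductance_increment_ns=0.5)
        sweeps = simulate_membrane(cfg, StepProtocol(amplitudes_pa=(400,)))
        assert classify_firing(sweeps) == "repetitive"
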