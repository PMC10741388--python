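"""Per-spike parameter extraction against analytic and generator oracles."""

import numpy as np
import pytest

from ampero import (
    AnalysisConfig,
    ELEMENTARY_CHARGE_C,
    EventParams,
    analyze_channel,
    ground_truth,
)
from ampero.detection import SpikeCandidate
from ampero.spike_metrics import (
    compute_charge_and_molecules,
    compute_duration,
    compute_imax,
    compute_t_half,
    fit_decay,
    fit_rise,
    fit_spike_baseline,
)

from conftest import FS, DT_MS, clean_trace, make_noise
from ampero import render_events
from ampero.preprocess import FilteredTrace


def _cand(start, apex, end, thr=6.0):
    return SpikeCandidate(
        channel_id="ch1", apex_index=apex, start_index=start, end_index=end,
        threshold_used=thr, sampling_rate=FS,
    )


def _trace_of(y, sigma=1.0):
    y = np.asarray(y, dtype=float)
    return FilteredTrace(
        raw=y.copy(), filtered=y, baseline=np.zeros_like(y),
        baseline_sigma=sigma, noise_mean=0.0, sampling_rate=FS,
    )


def triangle(height=100.0, rise_ms=5.0, fall_ms=5.0, pad=2000):
    """Noiseless triangular spike starting at sample ``pad``; returns
    (trace, candidate) with exact boundaries."""
    r, f = int(rise_ms / DT_MS), int(fall_ms / DT_MS)
    y = np.zeros(2 * pad + r + f + 1)
    y[pad : pad + r] = np.linspace(0, height, r, endpoint=False)
    y[pad + r] = height
    y[pad + r + 1 : pad + r + f + 1] = np.linspace(height, 0, f + 1)[1:]
    return _trace_of(y), _cand(pad - 1, pad + r, pad + r + f + 1)


class TestBaseline:
    def test_exact_zero_on_noiseless_flat_background(self):
        trace, cand = triangle()
        slope, intercept, flags = fit_spike_baseline(trace, cand)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert not flags

    def test_small_on_noisy_flat_background(self):
        trace, cand = triangle()
        trace.filtered += make_noise(8, 2.0, trace.n_samples)
        slope, intercept, _ = fit_spike_baseline(trace, cand)
        t_mid = cand.apex_index * DT_MS
        assert abs(slope * t_mid + intercept) < 1.5  # pA at the spike

    def test_recovers_linear_drift(self):
        trace, cand = triangle()
        t = np.arange(trace.n_samples) * DT_MS
        trace.filtered = trace.filtered + 1.0 * t  # +1 pA/ms drift
        slope, _, _ = fit_spike_baseline(trace, cand)
        assert slope == pytest.approx(1.0, rel=0.10)


class TestImaxDuration:
    def test_imax_is_apex_minus_baseline(self):
        trace, cand = triangle(height=100.0)
        assert compute_imax(trace, cand, (0.0, 0.0)) == pytest.approx(100.0)
        assert compute_imax(trace, cand, (0.0, 4.0)) == pytest.approx(96.0)

    def test_duration_arithmetic(self):
        assert compute_duration(_cand(0, 100, 250), FS) == pytest.approx(10.0)
        assert compute_duration(_cand(0, 1, 2), FS) == pytest.approx(2 * DT_MS)

    def test_noiseless_generator_spike_recovers_amplitude_within_1pct(self):
        """Detection-free check: the rendered waveform's sampled apex equals
        the injected amplitude to better than 1% (filter droop bounded by
        the pipeline recovery suite)."""
        ev = EventParams(onset_ms=40.0, amp_pA=120.0, rise_ms=2.0, taus_ms=(5.0,))
        n = int(120 / DT_MS)
        trace = clean_trace([ev], n)
        apex = int(np.argmax(trace.filtered))
        cand = _cand(int(38.0 / DT_MS), apex, n - 1)
        imax = compute_imax(trace, cand, (0.0, 0.0))
        assert imax == pytest.approx(120.0, rel=0.01)


class TestCharge:
    def test_triangle_charge_half_base_times_height(self):
        trace, cand = triangle(height=100.0, rise_ms=5.0, fall_ms=5.0)
        q, n_mol = compute_charge_and_molecules(
            trace, cand, (0.0, 0.0), AnalysisConfig()
        )
        assert q == pytest.approx(0.5, rel=0.01)  # 0.5 * 100 pA * 10 ms = 0.5 pC

    def test_molecule_count_equation(self):
        """Q = 0.32 pC with n = 2 oxidation electrons -> 1e6 molecules."""
        # triangle of height 64 pA over 10 ms -> 320 pA*ms = 0.32 pC
        trace, cand = triangle(height=64.0, rise_ms=5.0, fall_ms=5.0)
        q, n_mol = compute_charge_and_molecules(
            trace, cand, (0.0, 0.0), AnalysisConfig(n_electrons=2)
        )
        assert q == pytest.approx(0.32, rel=0.01)
        assert n_mol == pytest.approx(
            q * 1e-12 / (2 * ELEMENTARY_CHARGE_C), rel=1e-6
        )
        assert n_mol == pytest.approx(1.0e6, rel=0.01)

    def test_zero_amplitude_spike_has_zero_charge(self):
        trace = _trace_of(np.zeros(5000))
        q, n_mol = compute_charge_and_molecules(
            trace, _cand(1000, 1500, 2000), (0.0, 0.0), AnalysisConfig()
        )
        assert q == 0.0 and n_mol == 0.0

    def test_doubling_electron_count_halves_molecules(self):
        trace, cand = triangle(height=200.0)
        q2, n2 = compute_charge_and_molecules(trace, cand, (0.0, 0.0), AnalysisConfig(n_electrons=2))
        q4, n4 = compute_charge_and_molecules(trace, cand, (0.0, 0.0), AnalysisConfig(n_electrons=4))
        assert q2 == q4
        assert n2 == pytest.approx(2 * n4, rel=1e-6)


class TestTHalf:
    def test_symmetric_triangle_half_width_is_half_base(self):
        trace, cand = triangle(height=100.0, rise_ms=5.0, fall_ms=5.0)
        t_half, flags = compute_t_half(trace, cand, (0.0, 0.0))
        assert t_half == pytest.approx(5.0, rel=0.01)
        assert not flags

    def test_rectangular_pulse_half_width_is_pulse_width(self):
        y = np.zeros(10_000)
        w = int(4.0 / DT_MS)
        y[4000 : 4000 + w] = 50.0
        trace = _trace_of(y)
        t_half, _ = compute_t_half(trace, _cand(3999, 4000 + w // 2, 4000 + w), (0.0, 0.0))
        assert t_half == pytest.approx(4.0, abs=2 * DT_MS)

    def test_uncrossed_half_level_flags_and_returns_duration(self):
        y = np.zeros(10_000)
        y[4000:4200] = 50.0  # candidate that never drops below half inside bounds
        trace = _trace_of(y)
        cand = _cand(4001, 4100, 4198)
        t_half, flags = compute_t_half(trace, cand, (0.0, 0.0))
        assert "t_half_uncrossed" in flags
        assert t_half == pytest.approx(compute_duration(cand, FS))


class TestRise:
    def test_linear_ramp_slope_and_quarter_crossings(self):
        """0->100 pA in 1 ms: slope 100 pA/ms, 25-75% rise time 0.5 ms."""
        r = int(1.0 / DT_MS)
        y = np.zeros(8000)
        y[3000 : 3000 + r + 1] = np.linspace(0, 100, r + 1)  # apex exactly 100
        y[3000 + r + 1 : 3000 + r + 101] = np.linspace(100, 0, 101)[1:]
        trace = _trace_of(y)
        cand = _cand(2999, 3000 + r, 3000 + r + 100)
        slope, rise_time, t25, t75, intercept, flags = fit_rise(trace, cand, (0.0, 0.0))
        assert slope == pytest.approx(100.0, rel=0.02)
        assert rise_time == pytest.approx(0.5, rel=0.03)
        assert not flags

    def test_instantaneous_rise_bounded_by_sample_interval(self):
        y = np.zeros(8000)
        y[3000] = 100.0
        y[3001:3101] = np.linspace(100, 0, 100)
        trace = _trace_of(y)
        slope, rise_time, *_, flags = fit_rise(trace, _cand(2999, 3000, 3100), (0.0, 0.0))
        assert rise_time <= DT_MS + 1e-12
        assert "rise_chord" in flags


class TestDecay:
    def test_noiseless_single_exponential_recovered_within_1pct(self):
        tau = 5.0
        n_dec = int(40.0 / DT_MS)
        y = np.zeros(8000 + n_dec)
        y[2000] = 100.0  # apex
        t = np.arange(1, n_dec) * DT_MS
        y[2001 : 2000 + n_dec] = 100.0 * np.exp(-t / tau)
        trace = _trace_of(y)
        out = fit_decay(trace, _cand(1999, 2000, 2000 + n_dec), (0.0, 0.0))
        assert out["model"] == "single"
        assert out["tau1"] == pytest.approx(tau, rel=0.01)

    def test_noiseless_double_exponential_recovered_within_5pct(self):
        t1, t2 = 2.0, 12.0
        n_dec = int(90.0 / DT_MS)
        y = np.zeros(6000 + n_dec)
        t = np.arange(n_dec) * DT_MS
        y[2000 : 2000 + n_dec] = 50.0 * np.exp(-t / t1) + 50.0 * np.exp(-t / t2)
        y[1995:2000] = np.linspace(0, 90, 5)  # short rise to the apex
        trace = _trace_of(y)
        out = fit_decay(trace, _cand(1994, 2000, 2000 + n_dec - 1), (0.0, 0.0))
        assert out["model"] == "double"
        assert out["tau1"] == pytest.approx(t1, rel=0.05)
        assert out["tau2"] == pytest.approx(t2, rel=0.05)

    def test_constant_zero_decay_is_flagged_not_fit(self):
        y = np.zeros(6000)
        y[2000] = 100.0
        trace = _trace_of(y)
        out = fit_decay(trace, _cand(1999, 2000, 3000), (0.0, 0.0))
        assert out["model"] == ""
        assert any("decay" in f for f in out["flags"])


class TestScalingAndRecovery:
    def test_amplitude_scaling_scales_currents_not_times(self):
        """Scaling the trace by c scales I_max, Q, rise slope and decay
        amplitudes by c and leaves t_half, rise time and tau unchanged."""
        ev = EventParams(onset_ms=60.0, amp_pA=80.0, rise_ms=1.5, taus_ms=(4.0,))
        n = int(200 / DT_MS)
        base = clean_trace([ev], n)
        apex = int(np.argmax(base.filtered))
        end = int(ev.end_ms / DT_MS)
        cand = _cand(int(58.0 / DT_MS), apex, end)
        cfg = AnalysisConfig()
        c = 3.0
        scaled = _trace_of(base.filtered * c)
        ref: dict = {}
        for name, tr in (("base", base), ("scaled", scaled)):
            imax = compute_imax(tr, cand, (0.0, 0.0))
            q, _ = compute_charge_and_molecules(tr, cand, (0.0, 0.0), cfg)
            th, _ = compute_t_half(tr, cand, (0.0, 0.0))
            slope, rt, *_ = fit_rise(tr, cand, (0.0, 0.0))
            dec = fit_decay(tr, cand, (0.0, 0.0))
            ref[name] = (imax, q, th, slope, rt, dec["tau1"], dec["amp1"])
        b, s = ref["base"], ref["scaled"]
        assert s[0] == pytest.approx(c * b[0], rel=1e-9)  # i_max
        assert s[1] == pytest.approx(c * b[1], rel=1e-9)  # Q
        assert s[3] == pytest.approx(c * b[3], rel=1e-9)  # rise slope
        assert s[6] == pytest.approx(c * b[6], rel=1e-3)  # decay amplitude
        assert s[2] == pytest.approx(b[2], rel=1e-9)  # t_half
        assert s[4] == pytest.approx(b[4], rel=1e-9)  # rise time
        assert s[5] == pytest.approx(b[5], rel=1e-3)  # tau

    def test_pipeline_recovers_generator_parameters(self):
        """End-to-end on 12 seeded spikes: I_max/Q/t_half recovered within
        the recovery bands on sigma = 2 pA noise."""
        events = [
            EventParams(
                onset_ms=500.0 + 900.0 * k,
                amp_pA=float(a),
                rise_ms=1.2,
                taus_ms=(float(tau),),
            )
            for k, (a, tau) in enumerate(
                [(40, 3), (80, 5), (150, 8), (250, 2), (60, 10), (110, 4)] * 2
            )
        ]
        n = int((events[-1].onset_ms + 500.0) / DT_MS)
        raw = make_noise(77, 2.0, n) + render_events(events, n, FS)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        assert len(res.spikes) == len(events)
        truths = [ground_truth(e) for e in events]
        rel = lambda got, want: abs(got - want) / want
        assert np.median([rel(s.i_max, t.i_max_true) for s, t in zip(res.spikes, truths)]) <= 0.05
        assert np.median([rel(s.charge_q, t.q_true_pC) for s, t in zip(res.spikes, truths)]) <= 0.05
        assert np.median([rel(s.t_half, t.t_half_true) for s, t in zip(res.spikes, truths)]) <= 0.10
        assert np.median([rel(s.decay_tau1, t.decay_tau1_ms) for s, t in zip(res.spikes, truths)]) <= 0.10
        assert np.median([rel(s.rise_slope, t.rise_slope_true) for s, t in zip(res.spikes, truths)]) <= 0.10
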