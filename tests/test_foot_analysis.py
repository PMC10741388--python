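"""Pre-spike foot: end location, the n-point counting rule, quantification."""

import numpy as np
import pytest

from ampero import (
    AnalysisConfig,
    EventParams,
    analyze_channel,
    detect_foot,
    quantify_foot,
    render_events,
    summarize_feet,
)
from ampero.foot_analysis import line_intersection_time, locate_foot_end
from ampero.detection import SpikeCandidate
from ampero.spike_metrics import SpikeRecord

from conftest import FS, DT_MS, clean_trace, make_noise


def test_line_intersection_algebra():
    # rise y = 100 (t - 10), baseline y = 0 -> t = 10 ms
    assert line_intersection_time(100.0, -1000.0) == pytest.approx(10.0)
    # baseline y = 2 -> t = 10.02 ms
    assert line_intersection_time(100.0, -1000.0, 0.0, 2.0) == pytest.approx(10.02)
    assert line_intersection_time(5.0, 1.0, 5.0, 0.0) is None  # parallel


def _spiky_raw(onset_ms, foot_amp, foot_dur, n, seed=13, sigma=0.5, amp=100.0):
    ev = EventParams(
        onset_ms=onset_ms, amp_pA=amp, rise_ms=1.5, taus_ms=(4.0,),
        foot_amp_pA=foot_amp, foot_dur_ms=foot_dur,
    )
    return make_noise(seed, sigma, n) + render_events([ev], n, FS), ev


def test_locate_foot_end_near_rise_onset():
    """On a raised-cosine rise the 25-75% chord meets the baseline about
    rise/6 after onset; well within 0.5 ms of the injected onset."""
    n = int(2 * FS)
    raw, ev = _spiky_raw(1000.0, 0.0, 0.0, n, sigma=0.5)
    res = analyze_channel(raw, "ch1", AnalysisConfig())
    assert len(res.spikes) == 1
    t_end = locate_foot_end(res.spikes[0])
    assert t_end is not None
    assert abs(t_end - ev.onset_ms) < 0.5


def test_locate_foot_end_requires_positive_rise():
    cand = SpikeCandidate("ch1", 100, 50, 200, 6.0, FS)
    spike = SpikeRecord(candidate=cand, rise_slope=-3.0, rise_intercept=1.0)
    assert locate_foot_end(spike) is None


class TestNPointRule:
    n = int(4 * FS)

    def _run(self, foot_dur_ms, seed=13):
        raw, ev = _spiky_raw(2000.0, 4.0, foot_dur_ms, self.n, seed=seed)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        assert len(res.spikes) == 1
        return res, ev

    def test_long_plateau_foot_detected(self):
        """A 5 ms (125-sample) 4 pA plateau clears n_point = 40."""
        res, ev = self._run(5.0)
        assert len(res.feet) == 1
        foot = res.feet[0]
        assert foot.i_foot == pytest.approx(4.0, abs=1.0)
        assert foot.t_foot == pytest.approx(5.0, abs=1.2)
        assert foot.foot_start_ms == pytest.approx(ev.start_ms, abs=1.0)

    def test_short_plateau_rejected_by_count(self):
        """A 1 ms (25-sample) plateau fails the 40-point requirement."""
        res, _ = self._run(1.0)
        assert res.feet == []

    def test_no_foot_on_clean_rise(self):
        raw, _ = _spiky_raw(2000.0, 0.0, 0.0, self.n)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        assert len(res.spikes) == 1 and res.feet == []

    def test_lower_n_point_recovers_short_plateau(self):
        """The same 25-sample plateau is accepted once n_point <= 25."""
        raw, _ = _spiky_raw(2000.0, 4.0, 1.0, self.n)
        res = analyze_channel(raw, "ch1", AnalysisConfig(foot_n_point=15))
        assert len(res.feet) == 1


class TestQuantify:
    def _noiseless_spike_record(self, trace):
        apex = max(int(np.argmax(trace.filtered)), trace.n_samples // 2)
        cand = SpikeCandidate("ch1", apex, 10, trace.n_samples - 2, 6.0, FS)
        return SpikeRecord(candidate=cand)  # zero baseline

    def test_ideal_plateau_values_exact(self):
        """4 pA x 5 ms plateau: I_foot = 4 pA, t_foot = 5 ms, Q_foot = 0.02 pC."""
        n = 8000
        y = np.zeros(n)
        start = 2000
        dur = int(5.0 / DT_MS)
        y[start : start + dur + 1] = 4.0
        trace = clean_trace([], n)
        trace.filtered = y
        spike = self._noiseless_spike_record(trace)
        foot = quantify_foot(trace, spike, (start, (start + dur) * DT_MS))
        assert foot.i_foot == pytest.approx(4.0, rel=1e-9)
        assert foot.t_foot == pytest.approx(5.0, rel=1e-9)
        assert foot.q_foot == pytest.approx(0.020, rel=0.01)

    def test_ideal_ramp_mean_and_area(self):
        """0->4 pA ramp over 5 ms: I_foot = 2 pA, Q_foot = 0.01 pC."""
        n = 8000
        y = np.zeros(n)
        start = 2000
        dur = int(5.0 / DT_MS)
        y[start : start + dur + 1] = np.linspace(0, 4.0, dur + 1)
        trace = clean_trace([], n)
        trace.filtered = y
        spike = self._noiseless_spike_record(trace)
        foot = quantify_foot(trace, spike, (start, (start + dur) * DT_MS))
        assert foot.i_foot == pytest.approx(2.0, rel=0.01)
        assert foot.q_foot == pytest.approx(0.010, rel=0.01)

    def test_degenerate_bounds_rejected(self):
        trace = clean_trace([], 4000)
        spike = self._noiseless_spike_record(trace)
        with pytest.raises(ValueError):
            quantify_foot(trace, spike, (2000, 2000 * DT_MS))


class TestSummaries:
    def test_fraction_and_degenerate_cases(self):
        cand = lambda ch: SpikeCandidate(ch, 100, 50, 200, 6.0, FS)
        spikes = [SpikeRecord(candidate=cand("ch1"), spike_id=i) for i in range(4)]
        feet = [
            type("F", (), dict(channel_id="ch1", spike_id=0, i_foot=4.0, t_foot=3.0, q_foot=0.012))()
        ]
        s = summarize_feet(spikes, feet)
        assert s["ch1"]["foot_fraction"] == pytest.approx(0.25)
        assert s["pooled"]["n_spikes"] == 4
        empty = summarize_feet([], [])
        assert empty["pooled"]["foot_fraction"] is None

    def test_pooled_fraction_tracks_generation_probability(self):
        """~150 seeded spikes with detectable feet at p = 0.3: the pooled
        fraction lands inside the binomial 99% interval."""
        from scipy.stats import binom

        rng = np.random.default_rng(42)
        events = []
        for k in range(150):
            has = rng.random() < 0.3
            events.append(
                EventParams(
                    onset_ms=400.0 + 400.0 * k,
                    amp_pA=float(rng.uniform(60, 200)),
                    rise_ms=1.2,
                    taus_ms=(3.0,),
                    foot_amp_pA=4.5 if has else 0.0,
                    foot_dur_ms=4.0 if has else 0.0,
                )
            )
        n = int((events[-1].onset_ms + 400.0) / DT_MS)
        raw = make_noise(43, 1.0, n) + render_events(events, n, FS)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        assert len(res.spikes) == 150
        frac = len(res.feet) / len(res.spikes)
        lo, hi = binom.interval(0.99, 150, 0.3)
        assert lo / 150 <= frac <= hi / 150


class TestInvariants:
    def test_no_false_feet_on_footless_spikes(self):
        """<=2% false feet over 100 seeded no-foot spikes on 2 pA noise."""
        events = [
            EventParams(
                onset_ms=400.0 + 450.0 * k, amp_pA=80.0, rise_ms=1.2, taus_ms=(4.0,)
            )
            for k in range(100)
        ]
        n = int((events[-1].onset_ms + 450.0) / DT_MS)
        raw = make_noise(17, 2.0, n) + render_events(events, n, FS)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        assert len(res.spikes) >= 98
        assert len(res.feet) <= 2

    def test_foot_charge_within_spike_charge_and_mean_consistency(self):
        n = int(4 * FS)
        raw, _ = _spiky_raw(2000.0, 4.0, 5.0, n)
        res = analyze_channel(raw, "ch1", AnalysisConfig())
        (spike,), (foot,) = res.spikes, res.feet
        assert foot.q_foot <= spike.charge_q
        assert foot.i_foot * foot.t_foot / 1000.0 == pytest.approx(foot.q_foot, rel=0.25)

    def test_detection_invariant_to_constant_offset(self):
        n = int(4 * FS)
        raw, _ = _spiky_raw(2000.0, 4.0, 5.0, n)
        base = analyze_channel(raw, "ch1", AnalysisConfig())
        shifted = analyze_channel(raw + 30.0, "ch1", AnalysisConfig())
        assert len(base.feet) == len(shifted.feet) == 1
        assert shifted.feet[0].t_foot == pytest.approx(base.feet[0].t_foot, abs=0.2)
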