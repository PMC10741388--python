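"""Per-spike parameter extraction.

For each detected event this module fits a linear baseline to the
background immediately flanking the spike, then measures everything a
quantal-release study needs: the peak oxidation current I_max above
baseline, the event duration, the charge Q (trapezoidal area between the
trace and the baseline, in pC) and the molecule count N = Q / (n * e),
the half-height width t_1/2, the rising-phase slope and 25-75% rise
time, and the falling-phase kinetics via single- or double-exponential
fits selected by their sum of squared errors (SSE).

Times are reported in ms relative to recording start (0-based sample
indexing); currents in pA; charges in pC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .config import ELEMENTARY_CHARGE_C
from .detection import SpikeCandidate
from .preprocess import FilteredTrace

__all__ = [
    "SpikeRecord",
    "fit_spike_baseline",
    "compute_imax",
    "compute_duration",
    "compute_charge_and_molecules",
    "compute_t_half",
    "fit_rise",
    "fit_decay",
    "analyze_spike",
]

#: Cap on points passed to the nonlinear decay fit (longer segments are
#: decimated evenly; tau estimates are insensitive to this).
_MAX_FIT_POINTS = 2000


@dataclass
class SpikeRecord:
    """All extracted parameters of one amperometric spike."""

    candidate: SpikeCandidate
    spike_id: int = 0
    baseline_slope: float = 0.0  # pA/ms
    baseline_intercept: float = 0.0  # pA
    i_max: float = np.nan  # pA
    duration_ms: float = np.nan
    charge_q: float = np.nan  # pC
    n_molecules: float = np.nan
    t_half: float = np.nan  # ms
    rise_slope: float = np.nan  # pA/ms
    rise_time: float = np.nan  # ms
    t25_ms: float = np.nan  # ascending 25% I_max crossing
    t75_ms: float = np.nan  # ascending 75% I_max crossing
    rise_intercept: float = np.nan  # pA, of the 25-75% regression line
    decay_model: str = ""  # "single" | "double" | ""
    decay_tau1: float = np.nan  # ms
    decay_tau2: float = np.nan  # ms (double model only)
    decay_amp1: float = np.nan  # pA
    decay_amp2: float = np.nan  # pA
    decay_sse: float = np.nan  # pA^2
    flags: list[str] = field(default_factory=list)

    @property
    def channel_id(self) -> str:
        return self.candidate.channel_id

    @property
    def start_ms(self) -> float:
        return self.candidate.start_index * 1000.0 / self.candidate.sampling_rate

    @property
    def apex_ms(self) -> float:
        return self.candidate.apex_time_ms

    @property
    def end_ms(self) -> float:
        return self.candidate.end_index * 1000.0 / self.candidate.sampling_rate

    @property
    def threshold_pA(self) -> float:
        return self.candidate.threshold_used

    @property
    def decay_tau2_or_none(self):
        return None if self.decay_model != "double" else self.decay_tau2

    @property
    def valid(self) -> bool:
        return "invalid" not in ";".join(self.flags)

    def baseline_at(self, t_ms) -> np.ndarray | float:
        """Baseline current (pA) at time t (ms)."""
        return self.baseline_slope * np.asarray(t_ms) + self.baseline_intercept


def _anchor_indices(n: int, start: int, end: int, anchor: int) -> tuple[np.ndarray, np.ndarray]:
    pre = np.arange(max(start - anchor, 0), start)
    post = np.arange(end + 1, min(end + 1 + anchor, n))
    return pre, post


def fit_spike_baseline(
    trace: FilteredTrace, candidate: SpikeCandidate, anchor_ms: float = 1.0
) -> tuple[float, float, list[str]]:
    """Linear baseline under a spike from its flanking background.

    Least-squares line through the ``anchor_ms`` of background immediately
    preceding the start and following the end of the spike, evaluated
    across the spike.  Anchors shorter than 3 samples are widened (with a
    flag).  Returns (slope pA/ms, intercept pA, flags).
    """
    flags: list[str] = []
    n = trace.n_samples
    anchor = max(int(round(anchor_ms / trace.dt_ms)), 1)
    pre, post = _anchor_indices(n, candidate.start_index, candidate.end_index, anchor)
    if min(pre.size, post.size) < 3:
        flags.append("baseline_anchor_widened")
        pre, post = _anchor_indices(
            n, candidate.start_index, candidate.end_index, 4 * anchor
        )
    idx = np.concatenate([pre, post])
    if idx.size < 2:
        flags.append("baseline_degenerate")
        return 0.0, float(trace.filtered[candidate.apex_index] * 0.0), flags
    t = idx * trace.dt_ms
    y = trace.filtered[idx]
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept), flags


def compute_imax(trace: FilteredTrace, candidate: SpikeCandidate, baseline) -> float:
    """Peak current above baseline: filtered[apex] - baseline(t_apex)."""
    slope, intercept = baseline
    t_apex = candidate.apex_index * trace.dt_ms
    return float(trace.filtered[candidate.apex_index] - (slope * t_apex + intercept))


def compute_duration(candidate: SpikeCandidate, sampling_rate: float) -> float:
    """Spike duration in ms: (end - start) / sampling_rate."""
    return (candidate.end_index - candidate.start_index) / sampling_rate * 1000.0


def compute_charge_and_molecules(
    trace: FilteredTrace, candidate: SpikeCandidate, baseline, config
) -> tuple[float, float]:
    """Charge Q (pC) above baseline and molecule count N = Q / (n * e).

    Q is the trapezoidal integral of (filtered - baseline) over
    [start, end]; 1 pA*ms = 1e-15 C = 1e-3 pC.  N is rounded to the
    nearest integer.
    """
    idx = np.arange(candidate.start_index, candidate.end_index + 1)
    t = idx * trace.dt_ms
    slope, intercept = baseline
    amp = trace.filtered[idx] - (slope * t + intercept)
    q_pa_ms = float(np.trapezoid(amp, t))
    q_pc = q_pa_ms / 1000.0
    n_mol = round(q_pc * 1e-12 / (config.n_electrons * ELEMENTARY_CHARGE_C))
    return q_pc, float(n_mol)


def _cross_backward(amp: np.ndarray, t: np.ndarray, i0: int, level: float) -> float | None:
    """Interpolated time of the first sample at/below ``level`` walking
    backward from ``i0`` (local indices); None when never crossed."""
    for i in range(i0, -1, -1):
        if amp[i] <= level:
            if i == i0:
                return float(t[i])
            frac = (level - amp[i]) / (amp[i + 1] - amp[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return None


def _cross_forward(amp: np.ndarray, t: np.ndarray, i0: int, level: float) -> float | None:
    for i in range(i0, amp.size):
        if amp[i] <= level:
            if i == i0:
                return float(t[i])
            frac = (amp[i - 1] - level) / (amp[i - 1] - amp[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def _spike_amp(trace: FilteredTrace, candidate: SpikeCandidate, baseline):
    idx = np.arange(candidate.start_index, candidate.end_index + 1)
    t = idx * trace.dt_ms
    slope, intercept = baseline
    return trace.filtered[idx] - (slope * t + intercept), t


def compute_t_half(
    trace: FilteredTrace, candidate: SpikeCandidate, baseline
) -> tuple[float, list[str]]:
    """Width at half of I_max (ms), with linear interpolation.

    Searches forward and backward from the apex for the first point at or
    below half-maximum; if a side never crosses inside the boundaries the
    full duration is returned with a flag.
    """
    amp, t = _spike_amp(trace, candidate, baseline)
    apex_local = candidate.apex_index - candidate.start_index
    half = amp[apex_local] / 2.0
    t_back = _cross_backward(amp, t, apex_local, half)
    t_fwd = _cross_forward(amp, t, apex_local, half)
    flags: list[str] = []
    if t_back is None or t_fwd is None:
        flags.append("t_half_uncrossed")
        return compute_duration(candidate, trace.sampling_rate), flags
    return float(t_fwd - t_back), flags


def fit_rise(
    trace: FilteredTrace, candidate: SpikeCandidate, baseline
) -> tuple[float, float, float, float, float, list[str]]:
    """Rising-phase linear fit between 25% and 75% of I_max.

    Returns (slope pA/ms, rise_time ms, t25 ms, t75 ms, intercept pA,
    flags).  Crossing times are interpolated between samples; the slope is
    a least-squares fit on ascending-limb samples inside the 25-75% band
    (or the two-crossing chord, flagged, when fewer than 2 samples fall in
    the band).
    """
    amp, t = _spike_amp(trace, candidate, baseline)
    apex_local = candidate.apex_index - candidate.start_index
    imax = amp[apex_local]
    lv25, lv75 = 0.25 * imax, 0.75 * imax
    t75 = _cross_backward(amp, t, apex_local, lv75)
    t25 = _cross_backward(amp, t, apex_local, lv25)
    flags: list[str] = []
    if t75 is None or t25 is None or t75 <= t25:
        flags.append("rise_degenerate")
        return np.nan, np.nan, np.nan, np.nan, np.nan, flags
    in_band = (t > t25) & (t < t75) & (np.arange(t.size) <= apex_local)
    if in_band.sum() >= 2:
        slope, intercept = np.polyfit(t[in_band], amp[in_band], 1)
    else:
        flags.append("rise_chord")
        slope = (lv75 - lv25) / (t75 - t25)
        intercept = lv25 - slope * t25
    return float(slope), float(t75 - t25), float(t25), float(t75), float(intercept), flags


def _single_exp(t, a, tau):
    return a * np.exp(-t / tau)


def _double_exp(t, a1, a2, tau1, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_decay(
    trace: FilteredTrace,
    candidate: SpikeCandidate,
    baseline,
    sse_margin: float = 0.05,
) -> dict:
    """Falling-phase exponential fit with SSE-based model selection.

    The baseline-subtracted data between the descending 75%-of-I_max
    crossing and the spike end are fitted with A*exp(-t/tau) and with
    A1*exp(-t/tau1) + A2*exp(-t/tau2) (nonlinear least squares; tau
    bounded to [0.1, 1e4] ms, deterministic log-linear initialisation).
    The double model is selected only when its SSE is below
    ``(1 - sse_margin)`` times the single-model SSE: the nested double
    model never fits worse in exact arithmetic, so a margin is needed for
    "best represents the data" to be meaningful.

    Returns a dict with keys model, tau1, tau2, amp1, amp2, sse, flags.
    """
    out = dict(
        model="", tau1=np.nan, tau2=np.nan, amp1=np.nan, amp2=np.nan,
        sse=np.nan, flags=[],
    )
    amp, t = _spike_amp(trace, candidate, baseline)
    apex_local = candidate.apex_index - candidate.start_index
    imax = amp[apex_local]
    if imax <= 0:
        out["flags"].append("decay_degenerate")
        return out
    # first sample at/below 75% of I_max after the apex
    desc = np.flatnonzero(amp[apex_local:] <= 0.75 * imax)
    i0 = apex_local + (int(desc[0]) if desc.size else 0)
    y = amp[i0:]
    ts = t[i0:] - t[i0]
    if y.size < 8:
        out["flags"].append("decay_too_short")
        return out
    if np.allclose(y, 0.0):
        out["flags"].append("decay_degenerate")
        return out
    if y.size > _MAX_FIT_POINTS:
        step = int(np.ceil(y.size / _MAX_FIT_POINTS))
        y, ts = y[::step], ts[::step]

    # deterministic initialisation: log-linear fit on the upper half
    upper = (y > 0) & (y >= y.max() / 2.0)
    if upper.sum() >= 2:
        sl = np.polyfit(ts[upper], np.log(y[upper]), 1)[0]
        tau0 = float(np.clip(-1.0 / sl if sl < 0 else 1.0, 0.1, 1e4))
    else:
        tau0 = 1.0
    a0 = max(float(y[0]), 1e-6)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single = double = None
        try:
            p_s, _ = curve_fit(
                _single_exp, ts, y, p0=[a0, tau0],
                bounds=([0.0, 0.1], [np.inf, 1e4]), maxfev=2000,
            )
            sse_s = float(np.sum((y - _single_exp(ts, *p_s)) ** 2))
            single = (p_s, sse_s)
        except (RuntimeError, ValueError):
            out["flags"].append("decay_single_nonconverged")
        try:
            p_d, _ = curve_fit(
                _double_exp, ts, y,
                p0=[a0 / 2, a0 / 2, max(tau0 / 2, 0.1), min(2 * tau0, 1e4)],
                bounds=([0.0, 0.0, 0.1, 0.1], [np.inf, np.inf, 1e4, 1e4]),
                maxfev=4000,
            )
            sse_d = float(np.sum((y - _double_exp(ts, *p_d)) ** 2))
            double = (p_d, sse_d)
        except (RuntimeError, ValueError):
            out["flags"].append("decay_double_nonconverged")

    if single is None and double is None:
        out["flags"].append("decay_invalid_fit")
        return out
    use_double = (
        double is not None
        and single is not None
        and double[1] < (1.0 - sse_margin) * single[1]
    ) or (single is None)
    if use_double:
        (a1, a2, tau1, tau2), sse = double
        if tau1 > tau2:  # report the fast component first
            a1, a2, tau1, tau2 = a2, a1, tau2, tau1
        out.update(model="double", tau1=float(tau1), tau2=float(tau2),
                   amp1=float(a1), amp2=float(a2), sse=sse)
    else:
        (a1, tau1), sse = single
        out.update(model="single", tau1=float(tau1), amp1=float(a1), sse=sse)
    return out


def analyze_spike(
    trace: FilteredTrace, candidate: SpikeCandidate, config, spike_id: int = 0
) -> SpikeRecord:
    """Run the full parameter-extraction chain on one candidate."""
    record = SpikeRecord(candidate=candidate, spike_id=spike_id)
    slope, intercept, flags = fit_spike_baseline(
        trace, candidate, config.baseline_anchor_ms
    )
    record.baseline_slope, record.baseline_intercept = slope, intercept
    record.flags.extend(flags)
    baseline = (slope, intercept)

    record.i_max = compute_imax(trace, candidate, baseline)
    record.duration_ms = compute_duration(candidate, trace.sampling_rate)
    if record.i_max <= 0:
        record.flags.append("invalid_nonpositive_imax")
        return record
    record.charge_q, record.n_molecules = compute_charge_and_molecules(
        trace, candidate, baseline, config
    )
    if record.charge_q <= 0:
        record.flags.append("invalid_negative_charge")
        return record
    record.t_half, th_flags = compute_t_half(trace, candidate, baseline)
    record.flags.extend(th_flags)
    (
        record.rise_slope,
        record.rise_time,
        record.t25_ms,
        record.t75_ms,
        record.rise_intercept,
        rise_flags,
    ) = fit_rise(trace, candidate, baseline)
    record.flags.extend(rise_flags)
    decay = fit_decay(trace, candidate, baseline, config.decay_sse_margin)
    record.decay_model = decay["model"]
    record.decay_tau1 = decay["tau1"]
    record.decay_tau2 = decay["tau2"]
    record.decay_amp1 = decay["amp1"]
    record.decay_amp2 = decay["amp2"]
    record.decay_sse = decay["sse"]
    record.flags.extend(decay["flags"])
    return record
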