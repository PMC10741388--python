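"""Pre-spike foot detection and quantification.

A pre-spike foot is the small current shoulder that sometimes precedes a
full fusion event, attributed to transmitter leaking through the narrow
fusion pore before it dilates.  The foot's end is placed at the
intersection of the spike's rising-phase regression line with its linear
baseline; from there the routine scans backward counting samples whose
baseline-subtracted amplitude exceeds the signal-noise average (with a
small sigma-fraction margin: on a zeroed baseline the bare mean would be
exceeded by half of all noise samples).  A foot is declared when at
least ``foot_n_point`` such samples form a contiguous run (gaps of up to
``foot_gap_tolerance_points`` below-average samples are tolerated), and
is then quantified by its mean current I_foot, duration t_foot and
charge Q_foot (trapezoidal area, pC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import FilteredTrace
from .spike_metrics import SpikeRecord

__all__ = [
    "FootRecord",
    "line_intersection_time",
    "locate_foot_end",
    "detect_foot",
    "quantify_foot",
    "summarize_feet",
]


@dataclass
class FootRecord:
    """Boundaries and parameters of one pre-spike foot."""

    channel_id: str
    spike_id: int
    foot_start_index: int
    foot_start_ms: float
    foot_end_ms: float  # baseline/rise intersection, generally between samples
    i_foot: float  # pA, mean baseline-subtracted current over the foot
    t_foot: float  # ms
    q_foot: float  # pC

    def __post_init__(self) -> None:
        if self.t_foot <= 0:
            raise ValueError("t_foot must be > 0")
        if self.q_foot < 0:
            raise ValueError("q_foot must be >= 0")


def line_intersection_time(
    rise_slope: float,
    rise_intercept: float,
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
) -> float | None:
    """Time (ms) where the rise line meets the baseline line; None if parallel."""
    dm = rise_slope - baseline_slope
    if dm == 0:
        return None
    return (baseline_intercept - rise_intercept) / dm


def locate_foot_end(spike: SpikeRecord) -> float | None:
    """End time of the foot: rise-line / baseline intersection (ms).

    The spike's 25-75% rise regression was fitted on baseline-subtracted
    current, so the intersection with the (subtracted) baseline is where
    that regression line crosses zero.  Returns None (foot analysis
    skipped) when the rise fit is missing, the lines are parallel, or the
    intersection falls at/after the apex.
    """
    if not np.isfinite(spike.rise_slope) or spike.rise_slope <= 0:
        return None
    t = line_intersection_time(spike.rise_slope, spike.rise_intercept)
    if t is None or t >= spike.apex_ms:
        return None
    return float(t)


def detect_foot(
    trace: FilteredTrace,
    spike: SpikeRecord,
    config,
    prev_end_index: int | None = None,
    spike_id: int | None = None,
) -> FootRecord | None:
    """Detect (and quantify) the pre-spike foot of one spike.

    Scans backward from the foot end counting samples whose
    baseline-subtracted amplitude exceeds
    ``noise_mean + foot_noise_margin_sigma * baseline_sigma``; the scan
    stops at the first run of more than ``foot_gap_tolerance_points``
    consecutive samples at/below that level.  A foot exists iff the count
    reaches ``config.foot_n_point``; its start is the earliest
    above-average sample of the run.  Feet whose start lies within 2 ms
    of the preceding spike's end are rejected (decay tails are not feet).
    """
    t_end = locate_foot_end(spike)
    if t_end is None or t_end <= 0:
        return None
    dt = trace.dt_ms
    end_idx = int(math.floor(t_end / dt))
    if end_idx < 1 or end_idx >= trace.n_samples:
        return None

    margin = trace.noise_mean + config.foot_noise_margin_sigma * trace.baseline_sigma
    filtered = trace.filtered
    count = 0
    gap = 0
    run_start = None
    i = end_idx - 1
    while i >= 0:
        amp = filtered[i] - spike.baseline_at(i * dt)
        if amp > margin:
            count += 1
            run_start = i
            gap = 0
        else:
            gap += 1
            if gap > config.foot_gap_tolerance_points:
                break
        i -= 1
    if count < config.foot_n_point or run_start is None:
        return None
    if prev_end_index is not None and (run_start - prev_end_index) * dt < 2.0:
        return None
    try:
        return quantify_foot(
            trace,
            spike,
            (run_start, t_end),
            spike_id=spike.spike_id if spike_id is None else spike_id,
        )
    except ValueError:
        # degenerate bounds or a net-negative noise integral: no foot
        return None


def quantify_foot(
    trace: FilteredTrace,
    spike: SpikeRecord,
    foot_bounds: tuple[int, float],
    spike_id: int = 0,
) -> FootRecord:
    """I_foot, t_foot and Q_foot for validated foot bounds.

    ``foot_bounds`` is (start sample index, end time in ms).  Q_foot is
    the trapezoidal integral of baseline-subtracted current from the
    start sample to the (generally fractional) end time; I_foot is that
    area divided by t_foot, i.e. the mean current over the foot.
    """
    start_idx, t_end = foot_bounds
    dt = trace.dt_ms
    t_start = start_idx * dt
    if t_end <= t_start:
        raise ValueError("foot end must lie after foot start")
    last_full = int(math.floor(t_end / dt))
    idx = np.arange(start_idx, last_full + 1)
    t = idx * dt
    amp = trace.filtered[idx] - spike.baseline_at(t)
    t_foot = t_end - t_start
    if idx.size >= 2:
        q_pa_ms = float(np.trapezoid(amp, t))
    else:
        q_pa_ms = 0.0
    # partial interval up to the fractional end time
    if t_end > t[-1] and last_full + 1 < trace.n_samples:
        t_next = (last_full + 1) * dt
        amp_next = trace.filtered[last_full + 1] - spike.baseline_at(t_next)
        frac = (t_end - t[-1]) / dt
        amp_end = amp[-1] + frac * (amp_next - amp[-1])
        q_pa_ms += 0.5 * (amp[-1] + amp_end) * (t_end - t[-1])
    i_foot = q_pa_ms / t_foot
    return FootRecord(
        channel_id=trace.channel_id,
        spike_id=spike_id,
        foot_start_index=int(start_idx),
        foot_start_ms=float(t_start),
        foot_end_ms=float(t_end),
        i_foot=float(i_foot),
        t_foot=float(t_foot),
        q_foot=float(q_pa_ms / 1000.0),
    )


def summarize_feet(spikes, feet) -> dict:
    """Per-channel and pooled foot statistics.

    Returns a dict keyed by channel id plus ``"pooled"``; each value holds
    spike/foot counts, the foot fraction (None when a channel has no
    spikes) and mean +/- standard error of I_foot, t_foot, Q_foot.
    """

    def _stats(spike_list, foot_list) -> dict:
        n_spikes = len(spike_list)
        n_feet = len(foot_list)
        entry = {
            "n_spikes": n_spikes,
            "n_feet": n_feet,
            "foot_fraction": (n_feet / n_spikes) if n_spikes else None,
        }
        for name, attr in (("i_foot", "i_foot"), ("t_foot", "t_foot"), ("q_foot", "q_foot")):
            vals = np.array([getattr(f, attr) for f in foot_list], dtype=float)
            if vals.size:
                entry[f"{name}_mean"] = float(vals.mean())
                entry[f"{name}_sem"] = float(
                    vals.std(ddof=1) / np.sqrt(vals.size)
                ) if vals.size > 1 else 0.0
            else:
                entry[f"{name}_mean"] = None
                entry[f"{name}_sem"] = None
        return entry

    channels = sorted({s.channel_id for s in spikes} | {f.channel_id for f in feet})
    out = {}
    for ch in channels:
        out[ch] = _stats(
            [s for s in spikes if s.channel_id == ch],
            [f for f in feet if f.channel_id == ch],
        )
    out["pooled"] = _stats(list(spikes), list(feet))
    return out
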