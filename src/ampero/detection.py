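"""Spike detection on conditioned traces.

Spikes are positive-going excursions of the filtered trace above an
automatic threshold (a user-chosen multiple of the background-noise
sigma).  Each contiguous supra-threshold excursion yields one apex; the
event's start and end are then found by walking outward from the apex
until the signal no longer exceeds the statistical mode of the nearby
background.  Events longer than the configured maximum duration are
discarded as convolved (simultaneous) exocytotic events rather than
deconvolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import FilteredTrace

__all__ = [
    "SpikeCandidate",
    "Rejection",
    "compute_threshold",
    "find_spike_apices",
    "local_background_mode",
    "find_spike_boundaries",
    "detect_spikes",
]

#: Minimum gap (samples) between separate excursions; shorter gaps are
#: merged to suppress single-sample threshold chatter.
REFRACTORY_SAMPLES = 2

#: Minimum background samples needed for a valid local mode estimate.
MIN_MODE_SAMPLES = 100


@dataclass
class SpikeCandidate:
    """One detected spike before parameter extraction (indices inclusive)."""

    channel_id: str
    apex_index: int
    start_index: int
    end_index: int
    threshold_used: float
    sampling_rate: float
    background_mode: float = 0.0
    mode_fallback: bool = False

    def __post_init__(self) -> None:
        if not (self.start_index < self.apex_index < self.end_index):
            raise ValueError("candidate must satisfy start < apex < end")

    @property
    def apex_time_ms(self) -> float:
        return self.apex_index * 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return (self.end_index - self.start_index) * 1000.0 / self.sampling_rate


@dataclass
class Rejection:
    """A discarded candidate and why it was discarded."""

    channel_id: str
    apex_index: int
    reason: str


def compute_threshold(trace: FilteredTrace, sigma_multiplier: float) -> float:
    """Detection threshold: ``sigma_multiplier`` x noise sigma above zero.

    Assumes Gaussian background noise; with the baseline zeroed the
    threshold is an absolute current in pA.
    """
    if sigma_multiplier <= 0:
        raise ValueError("sigma_multiplier must be > 0")
    if trace.baseline_sigma <= 0 or trace.degenerate_noise:
        raise ValueError(
            "degenerate (zero) noise sigma on channel "
            f"{trace.channel_id!r}: check that the channel carries signal"
        )
    return sigma_multiplier * trace.baseline_sigma


def _runs_from_mask(above: np.ndarray) -> np.ndarray:
    """(n_runs, 2) array of [first, last] indices of True runs."""
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return np.column_stack([starts, ends])


def find_spike_apices(trace: FilteredTrace, threshold: float, sampling_rate: float | None = None) -> np.ndarray:
    """One apex per contiguous supra-threshold excursion.

    The apex is the index of the maximum filtered value within the
    excursion; only positive-going excursions are considered (quantal
    oxidation spikes are exclusively upward).  Runs separated by fewer
    than two sub-threshold samples are treated as one excursion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    filtered = trace.filtered
    runs = _runs_from_mask(filtered > threshold)
    if runs.size == 0:
        return np.empty(0, dtype=int)
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < REFRACTORY_SAMPLES:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    apices = np.array(
        [s + int(np.argmax(filtered[s : e + 1])) for s, e in merged], dtype=int
    )
    return apices


def local_background_mode(
    trace: FilteredTrace,
    around_index: int,
    exclusion: tuple[int, int],
    *,
    threshold: float,
    window_ms: float = 200.0,
    bin_sigma_fraction: float = 0.5,
) -> tuple[float, bool]:
    """Statistical mode of the background flanking a spike.

    Background samples are taken from a ``window_ms`` stretch on each side
    of ``around_index``, excluding the ``exclusion`` index range and every
    supra-threshold sample (other spikes).  The mode is the center of the
    tallest bin of a histogram with bin width ``bin_sigma_fraction`` x
    noise sigma; ties are broken toward zero.  Falls back to the global
    ``noise_mean`` (flagged) when fewer than 100 background samples remain.

    Returns
    -------
    (mode, fallback)
        The mode in pA and whether the global fallback was used.
    """
    filtered = trace.filtered
    win = int(round(window_ms / 1000.0 * trace.sampling_rate))
    lo = max(around_index - win, 0)
    hi = min(around_index + win + 1, filtered.size)
    idx = np.arange(lo, hi)
    excl_lo, excl_hi = exclusion
    keep = (idx < excl_lo) | (idx > excl_hi)
    values = filtered[idx[keep]]
    values = values[values <= threshold]
    if values.size < MIN_MODE_SAMPLES:
        return trace.noise_mean, True
    if trace.baseline_sigma > 0:
        bw = bin_sigma_fraction * trace.baseline_sigma
    else:
        bw = max(values.std(), 1e-12)
    if bw == 0 or np.ptp(values) == 0:
        return float(values[0]), False
    bins = np.round(values / bw).astype(np.int64)
    uniq, counts = np.unique(bins, return_counts=True)
    top = counts == counts.max()
    centers = uniq[top] * bw
    order = np.lexsort((centers, np.abs(centers)))
    return float(centers[order[0]]), False


def find_spike_boundaries(
    trace: FilteredTrace,
    apex_index: int,
    config,
    threshold: float,
) -> SpikeCandidate | Rejection:
    """Walk outward from an apex to locate the spike's start and end.

    A sample belongs to the spike while its filtered amplitude strictly
    exceeds the local background mode; the first failing sample on each
    side becomes the boundary.  Candidates longer than
    ``config.max_spike_duration_ms`` are rejected as convolved events;
    walks reaching the trace edge are rejected rather than truncated
    (their charge and decay fit would be biased).
    """
    filtered = trace.filtered
    n = filtered.size
    max_len = int(round(config.max_spike_duration_ms / 1000.0 * config.sampling_rate))

    # Preliminary exclusion zone for the mode: the spike's own supra-
    # threshold excursion, then the mode-based walk refines the extent.
    lo = apex_index
    while lo > 0 and filtered[lo - 1] > threshold:
        lo -= 1
    hi = apex_index
    while hi < n - 1 and filtered[hi + 1] > threshold:
        hi += 1
    mode, fallback = local_background_mode(
        trace,
        apex_index,
        (lo, hi),
        threshold=threshold,
        window_ms=config.background_window_ms,
        bin_sigma_fraction=config.histogram_bin_sigma_fraction,
    )

    start = apex_index
    while start > 0 and filtered[start - 1] > mode:
        start -= 1
        if apex_index - start > max_len:
            return Rejection(trace.channel_id, apex_index, "convolved/over-long")
    start -= 1  # first failing sample
    if start < 0:
        return Rejection(trace.channel_id, apex_index, "edge")

    end = apex_index
    while end < n - 1 and filtered[end + 1] > mode:
        end += 1
        if end - start > max_len:
            return Rejection(trace.channel_id, apex_index, "convolved/over-long")
    end += 1
    if end > n - 1:
        return Rejection(trace.channel_id, apex_index, "edge")

    if (end - start) > max_len:
        return Rejection(trace.channel_id, apex_index, "convolved/over-long")
    return SpikeCandidate(
        channel_id=trace.channel_id,
        apex_index=int(apex_index),
        start_index=int(start),
        end_index=int(end),
        threshold_used=threshold,
        sampling_rate=trace.sampling_rate,
        background_mode=mode,
        mode_fallback=fallback,
    )


def detect_spikes(
    trace: FilteredTrace,
    config,
    threshold: float | None = None,
) -> tuple[list[SpikeCandidate], list[Rejection]]:
    """Full detection on one conditioned channel.

    Computes the automatic threshold (unless given), finds apices, walks
    boundaries, merges candidates that share samples (one apex per merged
    event, the larger one) and applies the over-long rejection to merged
    extents.
    """
    if threshold is None:
        threshold = compute_threshold(trace, config.sigma_multiplier)
    apices = find_spike_apices(trace, threshold)
    candidates: list[SpikeCandidate] = []
    rejections: list[Rejection] = []
    for apex in apices:
        res = find_spike_boundaries(trace, int(apex), config, threshold)
        if isinstance(res, Rejection):
            rejections.append(res)
        else:
            candidates.append(res)

    # Merge overlapping candidates (shared samples -> one event).
    candidates.sort(key=lambda c: c.start_index)
    merged: list[SpikeCandidate] = []
    max_len = int(round(config.max_spike_duration_ms / 1000.0 * config.sampling_rate))
    filtered = trace.filtered
    for cand in candidates:
        if merged and cand.start_index <= merged[-1].end_index:
            prev = merged.pop()
            start = prev.start_index
            end = max(prev.end_index, cand.end_index)
            apex = (
                prev.apex_index
                if filtered[prev.apex_index] >= filtered[cand.apex_index]
                else cand.apex_index
            )
            if end - start > max_len:
                rejections.append(
                    Rejection(trace.channel_id, apex, "convolved/over-long")
                )
                continue
            merged.append(
                SpikeCandidate(
                    channel_id=cand.channel_id,
                    apex_index=apex,
                    start_index=start,
                    end_index=end,
                    threshold_used=threshold,
                    sampling_rate=cand.sampling_rate,
                    background_mode=prev.background_mode,
                    mode_fallback=prev.mode_fallback or cand.mode_fallback,
                )
            )
        else:
            merged.append(cand)
    return merged, rejections
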