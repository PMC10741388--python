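"""Per-channel signal conditioning.

Each selected channel is passed through a first-order (PT1) low-pass
filter, its slowly varying baseline is estimated with a spike-robust
running median and subtracted (so background noise fluctuates around
zero), and the background-noise level is characterised:

* ``baseline_sigma`` — a robust (MAD-based) standard deviation of the
  zeroed *raw* trace.  Threshold multiples refer to this number, i.e. to
  the instrument's actual noise amplitude, while detection itself runs on
  the cleaner filtered trace.
* ``noise_mean`` — the average of the zeroed filtered signal over
  background samples (|value| < 3 sigma), used by the foot routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilteredTrace",
    "pt1_filter",
    "running_baseline",
    "estimate_noise_sigma",
    "zero_baseline",
    "condition_trace",
]

#: MAD -> sigma for a Gaussian distribution.
_MAD_SCALE = 1.4826


@dataclass
class FilteredTrace:
    """A conditioned single-channel trace.

    ``filtered`` is the PT1-filtered, baseline-zeroed signal that all
    detection and quantification steps operate on; ``raw`` is the
    baseline-zeroed unfiltered signal kept for reference.
    """

    raw: np.ndarray
    filtered: np.ndarray
    baseline: np.ndarray
    baseline_sigma: float
    noise_mean: float
    sampling_rate: float
    degenerate_noise: bool = False
    channel_id: str = "ch1"

    def __post_init__(self) -> None:
        if len(self.filtered) != len(self.raw):
            raise ValueError("raw and filtered traces must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.filtered)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def time_ms(self, index) -> np.ndarray | float:
        """Time of a sample index in ms from recording start (0-based)."""
        return np.asarray(index) * self.dt_ms


def pt1_filter(trace, sampling_rate: float, time_constant_ms: float) -> np.ndarray:
    """First-order low-pass (PT1) filter with unity DC gain.

    Discrete form ``y[k] = y[k-1] + alpha * (x[k] - y[k-1])`` with
    ``alpha = dt / (tau + dt)``; warm-up ``y[0] = x[0]`` so no startup
    transient can masquerade as a spike.
    """
    x = np.asarray(trace, dtype=float)
    if time_constant_ms <= 0:
        raise ValueError("time_constant_ms must be > 0")
    if x.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    dt = 1000.0 / sampling_rate
    alpha = dt / (time_constant_ms + dt)
    # y[k] - (1 - alpha) y[k-1] = alpha x[k]; zi chosen so that y[0] = x[0]
    zi = np.array([(1.0 - alpha) * x[0]])
    y, _ = sps.lfilter([alpha], [1.0, alpha - 1.0], x, zi=zi)
    return y


def running_baseline(trace, sampling_rate: float, window_ms: float = 500.0) -> np.ndarray:
    """Slowly varying baseline via strided running medians.

    Medians over ``window_ms`` windows are computed on a coarse grid
    (one center per ``window_ms / 10``) and linearly interpolated back to
    the full time base; the median makes the estimate robust to spikes
    occupying a minority of samples.
    """
    x = np.asarray(trace, dtype=float)
    win = int(round(window_ms / 1000.0 * sampling_rate))
    if x.size < win:
        raise ValueError(
            f"trace of {x.size} samples is shorter than the {win}-sample baseline window"
        )
    stride = max(win // 10, 1)
    centers = np.arange(0, x.size, stride)
    half = win // 2
    meds = np.empty(centers.size)
    for i, c in enumerate(centers):
        lo = max(c - half, 0)
        hi = min(c + half, x.size)
        meds[i] = np.median(x[lo:hi])
    return np.interp(np.arange(x.size), centers, meds)


def estimate_noise_sigma(trace) -> float:
    """Robust noise standard deviation (median absolute deviation x 1.4826).

    Insensitive to spikes covering a minority of samples; returns 0.0 for a
    constant trace (callers should treat that as degenerate noise).
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    med = np.median(x)
    return _MAD_SCALE * float(np.median(np.abs(x - med)))


def zero_baseline(
    filtered,
    sampling_rate: float,
    window_ms: float = 500.0,
    raw=None,
    channel_id: str = "ch1",
) -> FilteredTrace:
    """Subtract the running-median baseline and characterise the noise.

    ``baseline_sigma`` is estimated on the zeroed raw trace when ``raw``
    is provided (otherwise on the zeroed filtered trace); ``noise_mean``
    is the mean of zeroed filtered samples within 3 sigma of zero.
    """
    filt = np.asarray(filtered, dtype=float)
    base = running_baseline(filt, sampling_rate, window_ms)
    zeroed = filt - base
    raw_zeroed = (np.asarray(raw, dtype=float) - base) if raw is not None else zeroed
    sigma = estimate_noise_sigma(raw_zeroed)
    degenerate = sigma == 0.0
    if degenerate:
        noise_mean = 0.0
    else:
        background = zeroed[np.abs(zeroed) < 3.0 * sigma]
        noise_mean = float(background.mean()) if background.size else 0.0
    return FilteredTrace(
        raw=raw_zeroed,
        filtered=zeroed,
        baseline=base,
        baseline_sigma=float(sigma),
        noise_mean=noise_mean,
        sampling_rate=sampling_rate,
        degenerate_noise=degenerate,
        channel_id=channel_id,
    )


def condition_trace(raw, config, channel_id: str = "ch1") -> FilteredTrace:
    """Full conditioning of one channel: PT1 filter + baseline zeroing."""
    filt = pt1_filter(raw, config.sampling_rate, config.pt1_time_constant_ms)
    return zero_baseline(
        filt,
        config.sampling_rate,
        window_ms=config.baseline_window_ms,
        raw=raw,
        channel_id=channel_id,
    )
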