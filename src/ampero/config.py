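"""Run configuration for chronoamperogram analysis.

All user-settable knobs of the pipeline live in :class:`AnalysisConfig`.
Units follow the conventions used throughout the package: currents in pA,
times in ms, charges in pC, sampling rate in Hz.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

#: Elementary charge in coulomb, used in N = Q / (n * e).  Fixed physical
#: constant, deliberately not a configuration field.
ELEMENTARY_CHARGE_C: float = 1.6e-19


@dataclass
class AnalysisConfig:
    """Parameters of the spike/foot analysis pipeline.

    Parameters
    ----------
    sampling_rate : float
        Acquisition rate in Hz (default 25 kHz, the rate of the ADC
        front end the method was designed for).
    gain : float
        Multiplication factor of the amplification chain.  Recorded values
        are divided by this on load; set to 1 if no external gain applies.
    max_spike_duration_ms : float
        Events whose start-to-end extent exceeds this are discarded as
        convolved (overlapping) exocytotic events.
    sigma_multiplier : float
        The detection threshold is this multiple of the background-noise
        standard deviation (3 is the usual optimum: ~99% of Gaussian noise
        stays below it).
    n_electrons : int
        Electrons transferred per oxidised molecule (2 for dopamine);
        enters N = Q / (n * e).
    foot_n_point : int
        Minimum number of above-noise-average points required for a
        pre-spike foot (a point count at the native sampling rate, not
        rescaled automatically).
    pt1_time_constant_ms : float
        Time constant of the first-order (PT1) low-pass filter.
    baseline_window_ms : float
        Window of the running-median baseline used to zero the trace.
    background_window_ms : float
        Half-window flanking a spike over which the local background mode
        is computed for boundary finding.
    histogram_bin_sigma_fraction : float
        Bin width of the background-mode histogram, as a fraction of the
        noise sigma.
    decay_sse_margin : float
        The double-exponential decay model is selected only if its SSE is
        below (1 - margin) times the single-exponential SSE.
    baseline_anchor_ms : float
        Extent of the background stretches immediately before/after a
        spike to which its linear baseline is fitted.
    foot_gap_tolerance_points : int
        Maximum run of consecutive below-average samples tolerated inside
        a foot before the backward scan stops.
    foot_noise_margin_sigma : float
        The "above the noise average" foot criterion uses
        noise_mean + this * baseline_sigma (a zeroed baseline makes the
        bare mean criterion fire on half of all noise samples).
    noisy_channel_sigma_ratio : float
        A channel is flagged noisy when its noise sigma exceeds this
        multiple of the median sigma across channels.
    selected_channels : list[str] | None
        Channel labels to analyze; ``None`` means all.
    """

    sampling_rate: float = 25_000.0
    gain: float = 1.0
    max_spike_duration_ms: float = 100.0
    sigma_multiplier: float = 3.0
    n_electrons: int = 2
    foot_n_point: int = 40
    pt1_time_constant_ms: float = 0.1
    baseline_window_ms: float = 500.0
    background_window_ms: float = 200.0
    histogram_bin_sigma_fraction: float = 0.5
    decay_sse_margin: float = 0.05
    baseline_anchor_ms: float = 1.0
    foot_gap_tolerance_points: int = 3
    foot_noise_margin_sigma: float = 0.5
    noisy_channel_sigma_ratio: float = 5.0
    selected_channels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.gain == 0:
            raise ValueError("gain must be nonzero (use 1 if no amplification)")
        if self.max_spike_duration_ms <= 0:
            raise ValueError("max_spike_duration_ms must be > 0")
        if self.sigma_multiplier <= 0:
            raise ValueError("sigma_multiplier must be > 0")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")
        if self.foot_n_point < 1:
            raise ValueError("foot_n_point must be >= 1")
        if self.pt1_time_constant_ms <= 0:
            raise ValueError("pt1_time_constant_ms must be > 0")

    @property
    def dt_ms(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def foot_n_point_ms(self) -> float:
        """The foot point-count threshold expressed as a duration (ms)."""
        return self.foot_n_point * self.dt_ms

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a JSON file; missing fields take defaults."""
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
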