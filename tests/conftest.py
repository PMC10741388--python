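"""Shared fixtures: deterministic noise traces and single-spike recordings."""

import numpy as np
import pytest

from ampero import (
    AnalysisConfig,
    EventParams,
    FilteredTrace,
    condition_trace,
    render_events,
)

FS = 25_000.0
DT_MS = 1000.0 / FS


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_noise(seed: int, sigma: float, n: int) -> np.ndarray:
    return np.random.default_rng(seed).normal(0.0, sigma, n)


def conditioned(raw: np.ndarray, config: AnalysisConfig | None = None) -> FilteredTrace:
    cfg = config or AnalysisConfig()
    return condition_trace(raw, cfg)


def clean_trace(events: list[EventParams], n: int, sigma_fake: float = 1.0) -> FilteredTrace:
    """A noiseless FilteredTrace (raw == filtered == clean waveform).

    Lets metric extraction be tested in isolation with exact expected
    values; ``sigma_fake`` only feeds histogram bin widths downstream.
    """
    clean = render_events(events, n, FS)
    return FilteredTrace(
        raw=clean.copy(),
        filtered=clean,
        baseline=np.zeros(n),
        baseline_sigma=sigma_fake,
        noise_mean=0.0,
        sampling_rate=FS,
    )


@pytest.fixture
def spiky_trace():
    """Five identical 50 pA spikes on sigma = 2 pA noise (seeded)."""
    events = [
        EventParams(onset_ms=500.0 + 800.0 * k, amp_pA=50.0, rise_ms=0.8, taus_ms=(2.5,))
        for k in range(5)
    ]
    n = int(5 * FS)
    raw = make_noise(11, 2.0, n) + render_events(events, n, FS)
    return conditioned(raw), events
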