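# ampero

Automated detection and quantification of quantal exocytotic events in
multi-electrode chronoamperograms.

## The problem

Constant-potential amperometry records the oxidation current produced when a
secretory vesicle releases its catecholamine content onto a polarized
electrode: each fusion event appears as a positive spike of tens to hundreds
of pA lasting a few milliseconds, riding on ~5–8 pA of baseline noise at a
25 kHz sampling rate. Diamond-substrate multi-electrode arrays record up to
16 such channels simultaneously, and hand-scoring them spike by spike takes
hours per electrode. `ampero` is a library (plus a thin CLI) that analyzes
every selected channel automatically and reproducibly: no manually chosen
thresholds or background levels.

For each detected spike it extracts the standard quantal-release parameters:

- **I_max** (pA): peak current above a per-spike linear baseline;
- **duration** and **t_1/2** (ms): spike extent and width at half maximum;
- **Q** (pC): charge, the area between trace and baseline, and the molecule
  count **N = Q / (n·e)** with `e = 1.6·10⁻¹⁹ C` and `n` oxidation electrons
  per molecule (2 for dopamine);
- rising-phase slope and 25–75 % rise time;
- falling-phase kinetics: single vs double exponential fit, chosen by
  sum-of-squared-errors (SSE) with a margin.

It also detects the **pre-spike foot** — the small plateau preceding some
spikes while transmitter leaks through the still-narrow fusion pore — and
reports **I_foot** (mean foot current), **t_foot** (duration) and **Q_foot**
(area), using an n-point counting rule (default 40 samples above the noise
average) with the foot's end placed at the intersection of the rising-phase
fit and the baseline.

The pipeline per channel: PT1 (first-order low-pass) filtering → running-
median baseline zeroing → automatic threshold at a σ-multiple of the
background noise (default 3σ, leaving ≥ 99 % of Gaussian noise below
threshold) → one apex per supra-threshold excursion → boundary walk against
the statistical mode of the nearby background → parameter extraction → foot
analysis → plain CSV reports.

A seeded synthetic generator (`ampero.synthetic`) produces recordings in the
same regime with closed-form ground truth for every injected event, and is
used throughout the test suite to grade recovery.

## Worked example

```python
import numpy as np
from ampero import AnalysisConfig, EventParams, analyze_channel, render_events

FS = 25_000.0
events = [
    EventParams(onset_ms=400.0,  amp_pA=120.0, rise_ms=1.2, taus_ms=(4.0,)),
    EventParams(onset_ms=1300.0, amp_pA=45.0,  rise_ms=0.8, taus_ms=(2.5,)),
    EventParams(onset_ms=2200.0, amp_pA=200.0, rise_ms=1.8,
                taus_ms=(2.0, 10.0), amp_fracs=(0.5, 0.5)),
]
raw = np.random.default_rng(7).normal(0, 2.0, int(3 * FS)) \
    + render_events(events, int(3 * FS), FS)
result = analyze_channel(raw, "ch1", AnalysisConfig())
```

Running `python examples/detect_and_measure.py` (the same computation with
the truth printed alongside) gives:

```
noise sigma 2.04 pA -> 3-sigma threshold 6.12 pA; 3 spikes detected
                I_max pA  t_1/2 ms    Q pC  N molecules   decay  tau1 ms
truth              120.0      3.36   0.541               single     4.00
  recovered        117.4      3.43   0.534     1.67e+06  single     3.83
truth               45.0      2.11   0.125               single     2.50
  recovered         44.2      2.15   0.119     3.73e+05  single     2.23
truth              200.0      3.70   1.351               double     2.00
  recovered        196.6      3.80   1.315     4.11e+06  double     1.75
```

The threshold was derived from the trace itself (3 × the robust noise σ);
all three spikes are found, amplitudes and widths agree to a few percent,
the third spike's biphasic decay is correctly classified, and the 0.534 pC
spike corresponds to ~1.7 million oxidized dopamine molecules. The other
scripts in `examples/` show foot quantification, fixture generation and the
multi-channel pipeline with its CSV reports.

From the shell:

```bash
ampero simulate --out fixture            # seeded synthetic recording
ampero analyze fixture/data.txt --out results --sigma 3 --channels 1-16
```

`results/` then holds `spikes.csv` (one row per spike, foot columns joined),
`feet.csv`, `channels_summary.csv` (spike frequency = count / duration) and
`manifest.json`.

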