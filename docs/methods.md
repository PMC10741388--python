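# Methods

This note records the signal model, the algorithmic choices and their
rationale, and what the synthetic validation does and does not establish.

## Signal model and units

A chronoamperogram is a constant-potential current recording, one column per
electrode, all channels on one time base (`n_samples / sampling_rate`).
Internally all currents are pA, times ms and charges pC (1 pA·ms = 10⁻³ pC);
sample indexing is 0-based and reported times are ms from recording start.
Quantal spikes are strictly positive-going (oxidation); reduction peaks are
out of scope. Recorded values are divided by the front-end gain at load time
(gain 1 when no external amplification applies).

## Conditioning

**PT1 filter.** Detection runs on a first-order low-pass,
`y[k] = y[k-1] + α (x[k] − y[k-1])`, `α = Δt/(τ + Δt)`, warm-started at
`y[0] = x[0]` so the settling transient cannot register as an event. The
default time constant is **τ = 0.1 ms** (≈1.6 kHz cutoff at 25 kHz). The
choice balances two hard constraints: wideband noise must be attenuated
enough that σ-multiple thresholds produce no spurious excursions (at
τ = 0.1 ms the filtered noise σ is ≈0.41× the raw σ, putting a 3σ-of-raw
threshold at ≈7σ of filtered noise — fewer than one false excursion per
hour of recording), while ms-scale spike apices must pass undistorted. A
causal first-order lag displaces an apex by roughly τ and clips it by
~τ²·|curvature|/2; at 0.1 ms both effects stay within ~2 % and ~0.2 ms for
millisecond rises, whereas at 0.2 ms the apex bias exceeds 5 % for fast
spikes. Apex timing can never beat the causal lag bound: recovered apices
agree with injected ones to ≈0.3 ms (not to the sampling grid).

**Baseline zeroing.** The slowly varying baseline is a running median
(500 ms window, evaluated on a window/10 grid and linearly interpolated) —
robust to spikes occupying a minority of samples — subtracted from both raw
and filtered traces so background fluctuates around zero. Traces shorter
than the window are an error; analyses of sub-second fixtures pass a
smaller `baseline_window_ms`.

**Noise statistics.** `baseline_sigma` is a robust σ (median absolute
deviation × 1.4826) of the **zeroed raw trace**: threshold multiples refer
to the instrument's actual noise amplitude, which is also what an
experimenter reads off the trace, while detection itself operates on the
cleaner filtered signal. `noise_mean` (used by the foot rule) is the mean of
zeroed filtered samples within 3σ of zero, i.e. the background excluding
events.

## Detection

The threshold is `sigma_multiplier × baseline_sigma` above the zeroed
baseline (default 3; ≥ 99 % of Gaussian noise lies below it). Each
contiguous supra-threshold excursion of the filtered trace yields one apex
(its argmax); excursions separated by fewer than 2 samples are merged to
suppress chatter. Slowly decaying spikes can re-cross the threshold a few
times in noise; the resulting satellite candidates are absorbed when
overlapping candidate extents are merged (the taller apex represents the
event).

Boundaries are walked outward from the apex: a sample belongs to the spike
while it strictly exceeds the **statistical mode of the nearby background**,
and the first failing sample on each side becomes the (inclusive) boundary.
The mode is computed from a histogram of background samples within 200 ms on
each side of the event, excluding all supra-threshold samples, with bin
width `baseline_sigma / 2`; ties break toward zero; fewer than 100
background samples fall back to the global `noise_mean` (flagged). Events
longer than `max_spike_duration_ms` (default 100 ms) are discarded as
convolved simultaneous events — deconvolution is deliberately not attempted
— and walks that reach the trace edge reject the event rather than truncate
it, since its charge and decay fit would be biased.

## Per-spike parameters

* **Baseline**: least-squares line through the 1 ms of background
  immediately before the start and after the end (the spike body itself
  carries no baseline information); anchors shorter than 3 samples are
  widened and flagged.
* **I_max** = filtered[apex] − baseline(t_apex).
* **Q**: trapezoidal integral of (filtered − baseline) over [start, end];
  **N** = Q/(n·e) rounded to the nearest integer, `e = 1.6·10⁻¹⁹ C` fixed.
* **t_1/2**: first points at/below half of I_max walking forward and
  backward from the apex, linearly interpolated between samples (at 25 kHz
  the grid alone would quantize ms widths by ~4 %).
* **Rise**: least-squares slope over ascending samples between 25 % and
  75 % of I_max; rise time is the interpolated crossing-time difference.
  With fewer than two in-band samples the two-crossing chord is used and
  flagged.
* **Decay**: baseline-subtracted data from the descending 75 % crossing to
  the end, fitted with `A e^{−t/τ}` and `A₁ e^{−t/τ₁} + A₂ e^{−t/τ₂}`
  (trust-region least squares, τ bounded to [0.1, 10⁴] ms, deterministic
  initialisation from a log-linear fit of the upper half; the double starts
  at (τ₀/2, 2τ₀) with the amplitude split evenly). Segments longer than
  2000 points are decimated evenly before fitting. The double model is
  selected only when `SSE_double < (1 − δ)·SSE_single` with δ = 0.05: the
  nested double never fits worse in exact arithmetic, so the margin is what
  makes "best model" meaningful. Non-convergence degrades gracefully
  (single-only, then flagged-no-fit).

## Pre-spike foot

The foot's **end** is where the 25–75 % rise regression line meets the spike
baseline (skipped, flagged, when the lines are parallel or the intersection
falls at/after the apex). Scanning backward from there, samples whose
baseline-subtracted amplitude exceeds `noise_mean + 0.5·baseline_sigma` are
counted; with a zeroed baseline the bare noise average would be exceeded by
half of all noise samples, so the half-σ margin is what makes the published
counting rule operational. Up to 3 consecutive below-average samples are
tolerated inside the run; a longer gap ends it. A foot exists iff the count
reaches `foot_n_point` (default **40**, a point count at the native rate —
1.6 ms at 25 kHz — deliberately not rescaled with sampling rate; a derived
config field exposes the ms equivalent). Feet starting within 2 ms of the
preceding spike's end are rejected so decay tails are never booked as feet.
Then `t_foot` runs from the earliest above-average sample to the
intersection time, `Q_foot` is the trapezoidal area over that interval and
`I_foot = Q_foot / t_foot`, the mean foot current (equal to the plateau
current for steady feet).

## Synthetic generator

Each injected event is, relative to its rise onset: an optional foot
(0.2 ms linear ramp-on, then a plateau of amplitude a_f and duration d_f), a
raised-cosine rise to the apex amplitude A over t_r, and a floor-subtracted
truncated exponential decay `c (g(s) − g(T))` with
`g(s) = Σ Aᵢ e^{−s/τᵢ}`, `g(T) = 0.5 pA` — continuous at the apex, compact
support, smooth approach to zero, closed-form area. A linear rise was
rejected because its slope discontinuity at the apex is clipped 5–10 % by
any causal low-pass, which would corrupt amplitude ground truth; the cosine
apex keeps the clip below ~2 %. All event parameters (q, t_1/2, 25–75 %
rise time, apex and end times) have closed forms, checked in the tests
against dense numerical integration of the clean waveform — the generator
is its own oracle.

Defaults emulate the target regime: 25 kHz, Gaussian σ = 2 pA, spike
amplitudes log-normal (median 80 pA, clipped to 20–300 pA), rises ~1.2 ms,
decay τ ~4 ms (20 % biphasic with the slow component capped at 15 ms so
event extents stay below the convolved-event cutoff), foot probability
0.25 with ~4.5 pA / ~3.3 ms plateaus (floor 3 pA and ≤ 20 % of the apex),
Poisson event times thinned by a 300 ms refractory gap, 400 ms edge
margins, optional slow sinusoidal drift. Seeds fully determine the output.

What the generator does **not** emulate: fusion-pore flicker and ramp-shaped
feet, overlapping (convolved) events beyond the rejection path, baseline
wander from electrode drift beyond a smooth sinusoid, non-Gaussian or
correlated instrument noise, and stimulation artifacts. Passing recovery
tests therefore demonstrates correctness of the measurement chain in the
intended regime, not robustness to every pathology of real recordings.

## Validation problem sizes

The test suite and `scripts/acceptance.py` size their fixtures to exercise
the published behaviors while staying desk-scale: noise coverage on 10⁶
samples; threshold monotonicity on 48 graded-amplitude spikes (10–150 pA,
some below the 10σ = 20 pA line); oracle equivalence on 50 random 10⁴-sample
traces; parameter recovery on 200 single-decay spikes spanning 20–300 pA and
t_1/2 2–30 ms on σ = 2 pA noise; model selection on 60 single + 60 double
(τ ratio 4–6) decays; foot rules on 125- vs 25-point plateaus plus 500
footless spikes; and an end-to-end 16-channel, 120 s fixture for wall-clock
and byte-stability checks. Observed headline numbers (seeded): 99.86 % of
noise below the 3σ threshold, 48/48 spikes at 3σ with 36–37 at 10σ, median
recovery errors ≈1.5 % (I_max), ≈4 % (Q), ≈3 % (t_1/2), ≈6–7 % (τ₁),
≥ 98 % correct model selection, zero false feet in 500, and 100 % detection
with byte-identical reports on the 16-channel run.

## Known limitations

* Boundary walking stops at the first sample at/below the local mode, so
  exponential tails are truncated at roughly twice the filtered-noise σ;
  charge is slightly underestimated for small, slow spikes (the effect is
  inside the recovery bands above but is systematic, not random).
* Double-exponential τ₁ is poorly identifiable on noisy decays even when
  the model is correctly selected; single-decay τ recovery is the reliable
  kinetic readout.
* Overlapping events are rejected, not deconvolved.
* `n_molecules` assumes complete oxidation of released transmitter at the
  electrode face.
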