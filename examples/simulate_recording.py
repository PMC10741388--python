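"""Generate a seeded synthetic chronoamperogram with known ground truth.

Builds a 2-channel, 30 s recording at 25 kHz with ~2 pA Gaussian noise
and quantal spikes at 0.3 Hz per channel (25% preceded by a plateau
foot), then writes the plain-text matrix and the ground-truth event
table.  Every printed number comes from the generator's closed forms, so
the same fixture can grade any detector.
"""

from ampero import SimulationConfig, generate_recording, write_fixture

cfg = SimulationConfig(n_channels=2, duration_s=30.0, spike_rate_hz=0.3, seed=42)
rec, events = generate_recording(cfg)
data_path, truth_path = write_fixture(rec, events, "scratch/example_fixture")

print(f"recording: {rec.n_channels} channels x {rec.duration_s:g} s "
      f"({rec.n_samples} samples at {rec.sampling_rate:g} Hz)")
print(f"{len(events)} injected events -> {data_path} + {truth_path}")
for e in events:
    foot = f" foot {e.foot_amp_true:.1f} pA x {e.foot_dur_true:.1f} ms" if e.has_foot else ""
    print(f"  {e.channel_id} t={e.onset_ms / 1000.0:7.2f} s  I_max={e.i_max_true:6.1f} pA  "
          f"t_1/2={e.t_half_true:5.2f} ms  Q={e.q_true_pC:6.3f} pC  "
          f"decay={e.decay_model}{foot}")
# I_max is the apex current, t_1/2 the width at half height, Q the area
# under the spike: the three standard descriptors of one vesicle's release.
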