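"""Generate one synthetic motor-imagery subject and decode it.

Builds a two-class session (5 runs x 20 trials per class) whose mu-band
sources show event-related desynchronization contralateral to the imagined
hand, then runs the standard decoding chain: 8-30 Hz band-pass, 0.4-2.4 s
post-cue epochs, CSP + Fisher LDA, and the exhaustive 120-separation
cross-validation.
"""

from mipredict import (GeneratorConfig, bandpass, cross_validated_accuracy,
                       epoch, generate_subject, run_wise_accuracy)

config = GeneratorConfig(n_channels=16, sampling_rate=128.0,
                         erd_depth=0.6, snr=0.4, seed=42)
recording = generate_subject(config)
print(f"recording: {recording.n_channels} channels, "
      f"{recording.duration:.0f} s, {len(recording.events)} trials")

epochs = epoch(bandpass(recording, 8, 30), window=(0.4, 2.4))
session = cross_validated_accuracy(epochs, m_filters=10, seed=42)
print(f"session accuracy: {session.mean_accuracy:.2f}% "
      f"+/- {session.accuracy_sd:.2f}% over "
      f"{len(session.per_separation_accuracy)} train/test separations")

runs = run_wise_accuracy(epochs, m_filters=6, seed=42)
print("run-wise accuracy (40 trials each):",
      ", ".join(f"{r.mean_accuracy:.1f}%" for r in runs))

# Reading: with 60% of the contralateral mu amplitude suppressed during
# imagery this subject decodes well above the ~43-57% chance band; run-wise
# estimates are noisier because each uses only 40 trials.
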