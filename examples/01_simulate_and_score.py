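"""Simulate a ground-truthed sleep session and score it from EEG/EMG alone.

Generates 30 minutes of synthetic polysomnography (two EEG channels, EMG,
pontine LFP pair, two-colour photometry), then runs the rule-based scorer on
the spectrogram features and compares its hypnogram with the generator's
truth. The printed accuracy is the fraction of 2.5 s epochs labelled
identically; the state fractions show the session's sleep architecture.
"""

import numpy as np

import pwavekit as pk

cfg = pk.SimConfig(duration_s=1800.0, seed=1)
rec, truth = pk.simulate_session(cfg)

spec_parietal = pk.spectrogram(rec["eeg_parietal"].data, 1000.0, preset="hypnogram")
spec_frontal = pk.spectrogram(rec["eeg_frontal"].data, 1000.0, preset="hypnogram")
_, emg_amp = pk.emg_amplitude(rec["emg"].data, 1000.0, mode="state")

scored = pk.score_states(spec_parietal, emg_amp, eeg_spec_frontal=spec_frontal)

n = min(len(scored), len(truth.hypnogram))
accuracy = np.mean(scored.labels[:n] == truth.hypnogram.labels[:n])
print(f"epochs scored:        {n}")
print(f"epoch accuracy:       {accuracy:.1%} vs ground truth")
print("state fractions (true):",
      {s: round(f, 3) for s, f in truth.hypnogram.fractions().items()})
print("state fractions (scored):",
      {s: round(f, 3) for s, f in scored.fractions().items()})
print(f"REM episodes: true {len(truth.hypnogram.episodes_of('R'))}, "
      f"scored {len(scored.episodes_of('R'))}")
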