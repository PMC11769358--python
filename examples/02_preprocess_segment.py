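"""Preprocess a continuous paired recording and cut labeled segments.

Simulates a 60 s continuous recording with 10 IEDs, applies the standard
pipeline (1 Hz high-pass, 50 Hz notch, common average reference on the scalp,
min-max normalization) and windows it into 320 ms segments: one per IED onset
plus an equal number of onset-free (non-IED) windows.
"""

import numpy as np

from eegtranslate import (
    SimulationConfig,
    extract_segments,
    preprocess_recording,
    simulate_continuous,
)

cfg = SimulationConfig(target_visible_fraction=None)
scalp, intra, rate, onsets = simulate_continuous(cfg, duration_s=60.0, n_ieds=10, seed=1)
print(f"continuous recording: scalp {scalp.shape}, intracranial {intra.shape} at {rate} Hz")
print(f"IED onsets (sample indices): {onsets.tolist()}")

scalp_p, intra_p = preprocess_recording(scalp, intra, rate)
print(f"after preprocessing: scalp CAR residual mean {np.abs(scalp_p.mean(axis=1)).max():.2e}, "
      f"amplitude range [{scalp_p.min():.3f}, {scalp_p.max():.3f}]")

segments = extract_segments(scalp_p, intra_p, rate, onsets, seed=0, subject_id="demo")
n_ied = sum(s.label == "IED" for s in segments)
print(f"{len(segments)} segments: {n_ied} IED + {len(segments) - n_ied} non-IED, "
      f"each {segments[0].scalp.samples.shape} scalp / "
      f"{segments[0].intracranial.samples.shape} intracranial")
# The IED windows span 160 ms before and after each onset (onset at sample 32);
# non-IED windows are drawn from stretches that overlap no IED window.
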