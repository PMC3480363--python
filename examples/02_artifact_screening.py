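"""Inject hardware defects into a clean recording and screen them out.

Saturated samples and flatlined (disconnected) stretches are detected and
excluded together with a +-2 s guard window; surviving signal is tiled
into 2-s analysis blocks.
"""

import attentrain as at

profile = at.StateProfile(theta_amp=4, alpha_amp=6, beta_amp=4,
                          pink_noise_amp=10)
clean = at.simulate_eeg(profile, duration=60.0, fs=128.0, seed=7)
bad = at.inject_artifacts(clean,
                          saturation_times=[12.0],
                          flatline_intervals=[(30.0, 33.0)],
                          rail_value=512.0)

mask = at.detect_artifacts(bad)
print("excluded intervals:")
for (a, b), reason in zip(mask.excluded, mask.reasons):
    print(f"  [{a:6.2f}, {b:6.2f}) s  {reason}")

blocks = at.apply_mask(bad, mask, block_len=2.0)
print(f"retained {len(blocks)} of {int(clean.duration // 2)} blocks "
      f"({mask.total_excluded:.1f} s excluded)")
# Each defect costs its own span plus the 2 s guard on both sides, and any
# 2-s block touching an excluded interval is dropped entirely.
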