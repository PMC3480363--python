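"""Run one closed-loop training session and the full program schedule.

The avatar moves at a speed proportional to the smoothed 0-100 attention
score; masked blocks contribute no movement.  A 4-minute stream with
alternating attentive / inattentive minutes shows the feedback loop.
"""

import datetime as dt

import numpy as np

import attentrain as at

cal = at.simulate_calibration(n_epochs_per_label=10, epoch_len=10.0, seed=3)
model = at.fit_attention_model(cal)

segments = [at.simulate_eeg(p, 60.0, 128.0, seed=10 + i).data
            for i, p in enumerate([at.ATTENTIVE_PROFILE, at.INATTENTIVE_PROFILE] * 2)]
eeg = at.EEGRecording(fs=128.0, data=np.concatenate(segments, axis=1))

trace = at.run_session(model, eeg, v_max=2.0, smoothing=3, level=2, seed=0)
minute = (np.asarray(trace.times) - 1e-9) // 60
for m in range(4):
    s = np.asarray(trace.display_scores)[minute == m]
    print(f"minute {m + 1} ({'attentive' if m % 2 == 0 else 'inattentive'}): "
          f"mean score {s.mean():5.1f}, mean speed "
          f"{np.asarray(trace.speeds)[minute == m].mean():4.2f} units/s")
print(f"total distance {trace.distance:.1f} units, "
      f"fruits collected {trace.fruits_collected}")

sched = at.build_schedule(dt.date(2024, 1, 1))
print(f"program: {len(sched.intensive)} intensive sessions "
      f"({sched.intensive[0]} .. {sched.intensive[-1]}), "
      f"{len(sched.maintenance)} monthly boosters (last {sched.maintenance[-1]})")
# Attentive minutes drive visibly higher speeds; distance is the discrete
# integral of speed over retained 2-s blocks.
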