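"""From R-peak times to a clean 1 Hz heart-rate series.

The instantaneous rate 60/RR is averaged within each second; implausible
samples (outside 40-180 bpm or jumping more than 20 bpm) are flagged and
bridged by the mean of their nearest clean neighbours.
"""

import numpy as np

from audsync import RPeakTrain, correct_artifacts, detect_artifacts, rr_to_heart_rate

rng = np.random.default_rng(0)
# ~75 bpm with beat-to-beat jitter, a bit over a minute of recording
rr = rng.normal(0.8, 0.03, 80)
peaks = RPeakTrain(np.cumsum(rr))
duration = int(np.ceil(peaks.peak_times_s[-1]))

hr = rr_to_heart_rate(peaks, duration_s=duration, participant_id="s01")
hr.values[25] += 55.0  # inject a motion artifact

mask = detect_artifacts(hr)
clean = correct_artifacts(hr, mask)

print(f"mean heart rate: {clean.values.mean():.1f} bpm")
print(f"flagged samples: {np.flatnonzero(mask).tolist()}")
print(f"second 25 before/after repair: {hr.values[25]:.1f} -> {clean.values[25]:.1f} bpm")
print("The spike is replaced by the mean of its clean neighbours, the same")
print("rule a technician would apply to an obscured R-R interval.")
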