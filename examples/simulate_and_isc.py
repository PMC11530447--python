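"""Simulate a two-modality audience and measure narrative heart-rate synchrony.

Two groups of subjects receive the same story through different senses;
the only structure their 1 Hz heart-rate series share is the narrative
signal.  Between-group inter-subject correlation (ISC) therefore isolates
story-driven synchrony.
"""

import numpy as np

from audsync import (
    AudienceSpec,
    between_group_pairs,
    generate_audience,
    group_isc_test,
    participant_isc,
    windowed_pairwise_isc,
)

spec = AudienceSpec(
    n_subjects_per_group=30,
    duration_s=1200,
    shared_loading=0.38,   # calibrated so mean between-group ISC is ~0.05
    modality_loading=0.6,
    ar_coef=0.5,
    seed=1,
)
series, truth = generate_audience(spec)

audio = [s.participant_id for s in series if s.group == "audio"]
visual = [s.participant_id for s in series if s.group == "visual"]
pairs = windowed_pairwise_isc(series, between_group_pairs(audio, visual))
mat = participant_isc(pairs)
test = group_isc_test(mat.participant_isc.to_numpy(), tails=1)

print(f"{len(series)} subjects, {spec.duration_s} s, {pairs.n_windows} sliding windows")
print(f"mean between-group ISC: r = {test.mean_r:.3f}")
print(f"one-tailed t({test.df:.0f}) = {test.t:.2f}, p = {test.p:.2e}, "
      f"d = {test.d:.2f} ({test.d_ci[0]:.2f}, {test.d_ci[1]:.2f})")
print("A positive mean r with a small p says the two modality groups'")
print("heart rates co-fluctuate beyond chance — narrative-driven synchrony.")
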