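"""Narrative vs low-level predictors of condition-level heart rate.

Three nested OLS models predict one condition's mean (z-scored) heart
rate: a time trend; time plus the other condition's heart rate (the
narrative proxy); and additionally the six low-level salience features.
BIC balances fit against parameter count — lower is better.
"""

from audsync import AudienceSpec, generate_audience, generate_stimulus
from audsync.features import feature_table
from audsync.modeling import comparison_table, condition_mean_hr, delta_r2, fit_nested_models

duration = 300
series, _ = generate_audience(AudienceSpec(
    n_subjects_per_group=12, duration_s=duration, shared_loading=0.7,
    modality_loading=0.4, seed=11,
))
frames, wave, _ = generate_stimulus(duration, frame_rate=2, audio_rate=8000, seed=11)
feats = feature_table(frames, 2, wave, 8000)

hr_audio = condition_mean_hr([s for s in series if s.group == "audio"])
hr_visual = condition_mean_hr([s for s in series if s.group == "visual"])

fits = fit_nested_models(hr_visual, hr_audio, feats)
print(comparison_table(fits).to_string(index=False))
d = delta_r2(fits)
print(f"variance added by narrative block: {d['narrative']:.3f}")
print(f"variance added by low-level block: {d['lowlevel']:.3f}")
print("The audience shares only the narrative, so the other condition's")
print("heart rate should dominate the unrelated salience features.")
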