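"""Continuous immersion ratings and their link to heart-rate synchrony.

A separate cohort rates immersion (1-7) every 30 s.  After excluding slow
responses (> 5 s) and high-missingness raters (> 20 %), the cohort-mean
rating is correlated with the ISC time course averaged over each probe's
trailing 30 s bin.  High-synchrony peaks (> mean + 3 SD) mark candidate
narrative events.
"""

from audsync import (
    AudienceSpec,
    between_group_pairs,
    generate_audience,
    generate_rating_cohort,
    isc_timecourse,
    narrative_activity,
    windowed_pairwise_isc,
)
from audsync.ratings import clean_ratings, correlate_isc_ratings, detect_peaks, rating_reliability

duration = 1200
series, truth = generate_audience(AudienceSpec(
    n_subjects_per_group=15, duration_s=duration, shared_loading=0.8,
    modality_loading=0.3, seed=21,
))
audio = [s.participant_id for s in series if s.group == "audio"]
visual = [s.participant_id for s in series if s.group == "visual"]
tc = isc_timecourse(windowed_pairwise_isc(series, between_group_pairs(audio, visual)))

# raters track the narrative's activity envelope, the synchrony-driving trace
table = generate_rating_cohort(
    30, duration, 30, narrative_activity(truth.narrative_signal),
    noise_sd=1.0, missing_rate=0.05, slow_rt_rate=0.05, seed=21,
)
cleaned, report = clean_ratings(table)
print(f"raters retained: {report.n_raters_out}/{report.n_raters_in} "
      f"({report.n_slow_responses} slow responses dropped)")
print(f"inter-rater reliability: mean pairwise r = {rating_reliability(cleaned):.3f}")

link = correlate_isc_ratings(tc, cleaned)
print(f"ISC vs immersion over {link.n_probes} probes: r = {link.r:.3f}, p = {link.p:.3g}")
print(f"high-synchrony runs (> mean + 3 SD): {detect_peaks(tc)}")
print("A positive r says the audience synchronises most during the moments")
print("an independent cohort reports as most immersive.")
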