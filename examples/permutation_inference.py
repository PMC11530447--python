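"""Per-participant significance by circular shuffle with FDR control.

Each participant's series is rotated by random offsets; rotation keeps the
series' autocorrelation but destroys its alignment with the stimulus, so
recomputed ISCs form a faithful null.  Decisions across participants are
corrected with Benjamini-Hochberg FDR at q = 0.05.
"""

from audsync import AudienceSpec, cohort_permutation_tests, generate_audience

spec = AudienceSpec(
    n_subjects_per_group=10, duration_s=600, shared_loading=0.5,
    modality_loading=0.4, seed=3,
)
series, _ = generate_audience(spec)
audio = [s.participant_id for s in series if s.group == "audio"]
visual = [s.participant_id for s in series if s.group == "visual"]
partner_map = {p: visual for p in audio} | {p: audio for p in visual}

results = cohort_permutation_tests(series, partner_map, n_iter=999, rng_seed=3)
n_sig = sum(bool(r.significant) for r in results)
print(f"{n_sig}/{len(results)} participants significant at q = 0.05")
for r in results[:5]:
    mark = "*" if r.significant else " "
    print(f" {mark} {r.participant_id}: observed ISC = {r.observed_isc:+.3f}, "
          f"p = {r.p_value:.4f}")
print("Starred participants synchronise with the other modality group more")
print("than any stimulus-unlocked rotation of their own heart rate would.")
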