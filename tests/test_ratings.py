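"""Rating cleaning, reliability, ISC-rating coupling, peak detection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from audsync.isc import ISCTimecourse, between_group_pairs, isc_timecourse, windowed_pairwise_isc
from audsync.ratings import (
    bin_timecourse_at_probes,
    clean_ratings,
    correlate_isc_ratings,
    detect_peaks,
    rating_reliability,
)
from audsync.synth import (
    AudienceSpec,
    generate_audience,
    generate_rating_cohort,
    narrative_activity,
)


def make_table(ratings, rts=None):
    """ratings: dict rater -> vector (NaN = missing); probes every 30 s."""
    rows = []
    for rid, vals in ratings.items():
        vals = np.asarray(vals, dtype=float)
        rt = np.ones(len(vals)) if rts is None else np.asarray(rts[rid], dtype=float)
        rows.append(pd.DataFrame({
            "rater_id": rid,
            "probe_t_s": 30 * (np.arange(len(vals)) + 1),
            "rating": vals,
            "rt_s": rt,
        }))
    return pd.concat(rows, ignore_index=True)


class TestCleaning:
    def test_cohort_arithmetic_50_to_35(self):
        sig = np.sin(np.linspace(0, 6 * np.pi, 3300))
        miss = np.concatenate([np.full(35, 0.02), np.full(15, 0.30)])
        table = generate_rating_cohort(50, 3300, 30, sig, noise_sd=1.0,
                                       missing_rate=miss, slow_rt_rate=0.02, seed=123)
        cleaned, report = clean_ratings(table)
        assert report.n_raters_in == 50
        assert report.n_raters_out == 35

    def test_clean_table_unchanged(self):
        table = make_table({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        cleaned, report = clean_ratings(table)
        assert report.excluded_raters == [] and report.n_slow_responses == 0
        pd.testing.assert_frame_equal(cleaned, table)

    def test_rt_boundary_is_strict(self):
        rts = {"a": [1.0, 5.01, 1.0, 1.0, 1.0]}
        table = make_table({"a": [3, 3, 3, 3, 3]}, rts)
        cleaned, report = clean_ratings(table)
        assert report.n_slow_responses == 1
        assert cleaned["rating"].isna().sum() == 1
        assert cleaned.loc[cleaned["rating"].isna(), "probe_t_s"].iloc[0] == 60

    def test_idempotent(self):
        rts = {"a": np.r_[np.ones(8), [6.0, 6.0]], "b": np.ones(10)}
        table = make_table({"a": np.full(10, 4.0), "b": np.full(10, 3.0)}, rts)
        once, _ = clean_ratings(table)
        twice, rep2 = clean_ratings(once)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_slow_responses == 0

    def test_all_excluded_errors(self):
        table = make_table({"a": [np.nan] * 5})
        with pytest.raises(ValueError, match="every rater"):
            clean_ratings(table)


class TestReliability:
    def test_identical_raters(self):
        v = [1, 3, 5, 7, 6, 4]
        assert rating_reliability(make_table({"a": v, "b": v, "c": v})) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        means = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            table = make_table({f"r{i}": rng.integers(1, 8, 40) for i in range(6)})
            means.append(rating_reliability(table))
        assert abs(np.mean(means)) < 0.05

    def test_recovers_generative_pairwise_correlation(self):
        """Ratings = scaled common signal + iid noise; pairwise correlation
        should match var(signal) / (var(signal) + noise_sd^2)."""
        rng = np.random.default_rng(9)
        sig = np.convolve(rng.normal(size=3000), np.ones(60) / 60, mode="same")
        noise_sd = 1.0
        table = generate_rating_cohort(
            12, 3000, 30, sig, noise_sd=noise_sd, seed=77, discretize=False
        )
        # analytic pairwise correlation: variance of the scaled probe-mean
        # signal over total variance
        seg = sig[:3000].reshape(100, 30).mean(axis=1)
        scaled = 1 + 6 * (seg - seg.min()) / (seg.max() - seg.min())
        expected = np.var(scaled) / (np.var(scaled) + noise_sd**2)
        assert rating_reliability(table) == pytest.approx(expected, abs=0.05)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        vals = {f"r{i}": rng.integers(1, 8, 20) for i in range(5)}
        r1 = rating_reliability(make_table(vals))
        relabeled = {f"z{9 - i}": v for i, (_, v) in enumerate(vals.items())}
        r2 = rating_reliability(make_table(relabeled))
        assert r1 == pytest.approx(r2, abs=1e-12)


def flat_timecourse(values, start=0):
    values = np.asarray(values, dtype=float)
    return ISCTimecourse(window_starts_s=start + np.arange(len(values)), values=values)


class TestISCRatingLink:
    def test_constant_ratings_undefined(self):
        tc = flat_timecourse(np.random.default_rng(0).normal(size=300))
        table = make_table({"a": [4] * 9, "b": [4] * 9})
        out = correlate_isc_ratings(tc, table)
        assert not out.defined and np.isnan(out.r)

    def test_ratings_equal_binned_isc_give_r_one(self):
        tc = flat_timecourse(np.random.default_rng(1).normal(size=300))
        binned = bin_timecourse_at_probes(tc, 30 * np.arange(1, 10))
        table = make_table({"a": binned.to_numpy(), "b": binned.to_numpy()})
        out = correlate_isc_ratings(tc, table)
        assert out.r == pytest.approx(1.0)

    def test_coupled_generator_recovers_positive_link(self):
        hits = 0
        for rep in range(20):
            spec = AudienceSpec(n_subjects_per_group=10, duration_s=900,
                                shared_loading=0.8, modality_loading=0.3,
                                seed=3000 + rep)
            audience, truth = generate_audience(spec)
            ia = [s.participant_id for s in audience if s.group == "audio"]
            ib = [s.participant_id for s in audience if s.group == "visual"]
            tc = isc_timecourse(
                windowed_pairwise_isc(audience, between_group_pairs(ia, ib))
            )
            # raters report the narrative's activity envelope — the
            # quantity that actually drives windowed synchrony
            table = generate_rating_cohort(
                20, 900, 30, narrative_activity(truth.narrative_signal),
                noise_sd=0.5, seed=4000 + rep, discretize=False,
            )
            out = correlate_isc_ratings(tc, table)
            hits += (out.r > 0) and (out.p < 0.05)
        assert hits >= 16


class TestPeaks:
    def test_constant_timecourse_has_no_peaks(self):
        assert detect_peaks(flat_timecourse(np.full(100, 0.3))) == []

    def test_gaussian_tail_count_within_poisson_bounds(self):
        counts = []
        for rep in range(10):
            v = np.random.default_rng(rep).normal(size=3000)
            peaks = detect_peaks(flat_timecourse(v))
            counts.append(sum(e - s + 1 for s, e in peaks))
        lam = 3000 * stats.norm.sf(3)  # ~4.05 exceedances expected
        mean = np.mean(counts)
        se = np.sqrt(lam / len(counts))
        assert lam - 4 * se <= mean <= lam + 4 * se

    def test_affine_invariance(self):
        v = np.random.default_rng(2).normal(size=500)
        base = detect_peaks(flat_timecourse(v))
        scaled = detect_peaks(flat_timecourse(5.0 * v + 3.0))
        assert base == scaled

    def test_injected_burst_detected(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            burst = 3.0 * np.sin(2 * np.pi * np.arange(15) / 10.0)
            subjects = []
            from audsync.signal import SignalSeries
            for i in range(8):
                x = rng.normal(0, 1, 600)
                x[200:215] += burst
                subjects.append(SignalSeries(f"p{i}", "audio", "heart_rate", x))
            tc = isc_timecourse(windowed_pairwise_isc(subjects))
            peaks = detect_peaks(tc)
            hits += any(s <= 215 and e >= 200 - 15 for s, e in peaks)
        assert hits >= 18
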