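"""Interval-probed immersion ratings: cleaning, reliability, and their
relation to the synchrony time course.

Raters respond to a probe every 30 s on a 1-7 scale.  Cleaning drops slow
responses (reaction time above 5 s) and then whole raters whose missing
fraction exceeds 20 %.  Reliability is the mean pairwise inter-rater
correlation of the rating time series.  The link to synchrony averages the
ISC time course within each probe's trailing bin and correlates it with
the cohort-mean rating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .isc import ISCTimecourse

RT_MAX_S = 5.0
MISSING_MAX = 0.20
PEAK_SD_K = 3.0


@dataclass
class CleaningReport:
    n_raters_in: int
    n_raters_out: int
    excluded_raters: list[str]
    n_slow_responses: int
    missing_fraction: dict[str, float] = field(default_factory=dict)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    required = {"rater_id", "probe_t_s", "rating", "rt_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"rating table is missing columns: {sorted(missing)}")
    return table.copy()


def clean_ratings(
    table: pd.DataFrame,
    rt_max: float = RT_MAX_S,
    missing_max: float = MISSING_MAX,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the response- and rater-level exclusion rules.

    Responses with reaction time above ``rt_max`` become missing; raters
    whose overall missing fraction (after that step) exceeds
    ``missing_max`` are dropped entirely.
    """
    df = _validate(table)
    slow = (df["rt_s"] > rt_max) & df["rating"].notna()
    slow = slow.fillna(False)
    n_slow = int(slow.sum())
    df.loc[slow, "rating"] = np.nan

    frac = df.groupby("rater_id")["rating"].apply(lambda s: s.isna().mean())
    excluded = frac.index[frac > missing_max].tolist()
    kept = df[~df["rater_id"].isin(excluded)].reset_index(drop=True)
    if kept.empty:
        raise ValueError("every rater excluded; no usable ratings remain")
    report = CleaningReport(
        n_raters_in=int(df["rater_id"].nunique()),
        n_raters_out=int(kept["rater_id"].nunique()),
        excluded_raters=excluded,
        n_slow_responses=n_slow,
        missing_fraction=frac.to_dict(),
    )
    return kept, report


def _rating_matrix(table: pd.DataFrame) -> pd.DataFrame:
    return table.pivot_table(
        index="probe_t_s", columns="rater_id", values="rating", aggfunc="mean"
    )


def rating_reliability(table: pd.DataFrame, method: str = "pairwise") -> float:
    """Inter-rater agreement of the rating time series.

    ``pairwise`` (default): mean over rater pairs of the Pearson
    correlation on their shared probes (pairs with fewer than 3 shared
    probes, or with a constant series, are skipped).  ``pooled``: one
    Pearson correlation between each rater's series and the mean of the
    remaining raters, averaged (a long-format variant).
    """
    wide = _rating_matrix(_validate(table))
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    if method == "pairwise":
        rs = []
        for i in range(len(raters)):
            for j in range(i + 1, len(raters)):
                both = wide[[raters[i], raters[j]]].dropna()
                if len(both) < 3:
                    continue
                a, b = both.iloc[:, 0], both.iloc[:, 1]
                if a.std() == 0 or b.std() == 0:
                    continue
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        if not rs:
            raise ValueError("no rater pair had 3 or more shared probes")
        return float(np.mean(rs))
    if method == "pooled":
        rs = []
        for rid in raters:
            others = wide.drop(columns=rid).mean(axis=1)
            both = pd.concat([wide[rid], others], axis=1).dropna()
            if len(both) < 3 or both.iloc[:, 0].std() == 0 or both.iloc[:, 1].std() == 0:
                continue
            rs.append(float(np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1]))
        if not rs:
            raise ValueError("no rater had enough usable probes")
        return float(np.mean(rs))
    raise ValueError(f"unknown method {method!r}")


def bin_timecourse_at_probes(
    isc: ISCTimecourse,
    probe_times_s: np.ndarray,
    probe_interval_s: int = 30,
    alignment: str = "trailing",
) -> pd.Series:
    """Average the ISC time course within each probe's summary bin.

    ``trailing`` (default): the probe at time p summarizes [p - interval, p),
    i.e. the just-experienced content.  ``centered``: [p - interval/2,
    p + interval/2).
    """
    t = np.asarray(isc.window_starts_s, dtype=float)
    v = np.asarray(isc.values, dtype=float)
    out = {}
    for p in np.asarray(probe_times_s, dtype=float):
        if alignment == "trailing":
            lo, hi = p - probe_interval_s, p
        elif alignment == "centered":
            lo, hi = p - probe_interval_s / 2.0, p + probe_interval_s / 2.0
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
        sel = (t >= lo) & (t < hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[p] = float(np.nanmean(v[sel])) if sel.any() else np.nan
    return pd.Series(out, name="isc")


@dataclass
class RatingISCResult:
    r: float
    p: float
    n_probes: int
    defined: bool = True


def correlate_isc_ratings(
    isc: ISCTimecourse,
    table: pd.DataFrame,
    probe_interval_s: int = 30,
    alignment: str = "trailing",
) -> RatingISCResult:
    """Pearson correlation between binned ISC and the cohort-mean rating."""
    wide = _rating_matrix(_validate(table))
    mean_rating = wide.mean(axis=1)
    binned = bin_timecourse_at_probes(
        isc, mean_rating.index.to_numpy(), probe_interval_s, alignment
    )
    df = pd.concat([mean_rating.rename("rating"), binned], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 usable probes")
    if df["rating"].std() == 0 or df["isc"].std() == 0:
        return RatingISCResult(r=np.nan, p=np.nan, n_probes=len(df), defined=False)
    r, p = stats.pearsonr(df["rating"], df["isc"])
    return RatingISCResult(r=float(r), p=float(p), n_probes=len(df))


def detect_peaks(isc: ISCTimecourse, k: float = PEAK_SD_K) -> list[tuple[int, int]]:
    """Maximal runs of seconds where the time course exceeds mean + k*sd.

    Returns inclusive (start_s, end_s) intervals in window-start seconds.
    Mean and sd are taken over the whole time course, so the rule is
    invariant to affine rescaling of the trace.
    """
    v = np.asarray(isc.values, dtype=float)
    t = np.asarray(isc.window_starts_s, dtype=int)
    if len(v) < 30:
        raise ValueError("time course too short for peak detection")
    ok = ~np.isnan(v)
    mu, sd = np.mean(v[ok]), np.std(v[ok], ddof=1)
    if sd == 0:
        return []
    above = ok & (v > mu + k * sd)
    peaks: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            peaks.append((int(t[start]), int(t[i - 1])))
            start = None
    if start is not None:
        peaks.append((int(t[start]), int(t[len(above) - 1])))
    return peaks
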