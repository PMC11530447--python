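"""Sliding-window inter-subject correlation (ISC).

Synchrony between two participants is the Pearson correlation of their
1 Hz signals inside a 15 s window slid one second at a time.  A pair's
windowed correlations collapse to one scalar per pair (mean over windows
by default), a participant's ISC is the median of their row of pair
scalars, and the group time course is the per-window median across pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._sliding import pair_mean_over_windows, sliding_pearson
from .signal import SignalSeries

WINDOW_S = 15
STEP_S = 1

PairAgg = Literal["mean", "median", "fisherz"]


@dataclass
class PairWindowsArray:
    """Windowed correlations for a set of participant pairs.

    ``r`` has shape (n_pairs, n_windows); NaN marks windows where either
    member was constant (Pearson undefined there).  ``window_starts_s``
    index each window by its first second.
    """

    participant_ids: list[str]
    pairs: list[tuple[int, int]]
    r: np.ndarray
    window_starts_s: np.ndarray
    window_s: int = WINDOW_S

    @property
    def n_windows(self) -> int:
        return self.r.shape[1]


@dataclass
class ISCMatrix:
    """Symmetric participants x participants matrix of per-pair scalar ISC."""

    participant_ids: list[str]
    values: np.ndarray  # NaN on the diagonal and for non-included pairs
    participant_isc: pd.Series = field(repr=False, default=None)


@dataclass
class ISCTimecourse:
    """Per-window median synchrony across the included pairs."""

    window_starts_s: np.ndarray
    values: np.ndarray
    design: str = "between"
    window_s: int = WINDOW_S

    def __len__(self) -> int:
        return len(self.values)


def within_group_pairs(members: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs inside one group: C(n, 2) pairs."""
    return list(combinations(members, 2))


def between_group_pairs(
    group_a: Sequence[str], group_b: Sequence[str]
) -> list[tuple[str, str]]:
    """All cross-group pairs (n_a x n_b); groups must be disjoint."""
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    return [(a, b) for a in group_a for b in group_b]


def _common_matrix(series: Sequence[SignalSeries]) -> tuple[list[str], np.ndarray]:
    """Align series on their common time span and stack into (n, T)."""
    if not series:
        raise ValueError("no series given")
    rates = {s.sample_rate_hz for s in series}
    if rates != {1.0}:
        raise ValueError("all series must be sampled at 1 Hz")
    t_start = max(s.t0_s for s in series)
    t_end = min(s.t0_s + len(s) for s in series)
    if t_end - t_start < WINDOW_S:
        raise ValueError(
            f"common time span ({t_end - t_start:.0f} s) is shorter than one "
            f"{WINDOW_S} s window"
        )
    ids = [s.participant_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    X = np.stack(
        [
            s.values[int(t_start - s.t0_s) : int(t_end - s.t0_s)]
            for s in series
        ]
    )
    return ids, X


def windowed_pairwise_isc(
    series: Sequence[SignalSeries],
    pair_set: Sequence[tuple[str, str]] | None = None,
    window_s: int = WINDOW_S,
) -> PairWindowsArray:
    """Pearson r in every sliding window for every requested pair.

    ``pair_set`` names pairs by participant id; by default all unordered
    pairs are used.  Windows slide in 1 s steps; a T-second common span
    yields T - window + 1 windows.
    """
    ids, X = _common_matrix(series)
    index = {pid: k for k, pid in enumerate(ids)}
    if pair_set is None:
        pairs_idx = list(combinations(range(len(ids)), 2))
    else:
        if len(pair_set) == 0:
            raise ValueError("pair_set is empty")
        pairs_idx = [(index[a], index[b]) for a, b in pair_set]
    i_idx = np.array([p[0] for p in pairs_idx])
    j_idx = np.array([p[1] for p in pairs_idx])
    r = sliding_pearson(X[i_idx], X[j_idx], window_s)
    starts = np.arange(r.shape[1]) + int(max(s.t0_s for s in series))
    return PairWindowsArray(
        participant_ids=ids,
        pairs=pairs_idx,
        r=r,
        window_starts_s=starts,
        window_s=window_s,
    )


def _pair_scalars(pairs: PairWindowsArray, agg: PairAgg = "mean") -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs -> NaN
        if agg == "mean":
            return pair_mean_over_windows(pairs.r)
        if agg == "median":
            return np.nanmedian(pairs.r, axis=-1)
        if agg == "fisherz":
            z = np.arctanh(np.clip(pairs.r, -1 + 1e-12, 1 - 1e-12))
            return np.tanh(np.nanmean(z, axis=-1))
    raise ValueError(f"unknown agg {agg!r}")


def participant_isc(
    pairs: PairWindowsArray, agg: PairAgg = "mean"
) -> ISCMatrix:
    """Collapse windowed pair correlations to the ISC matrix and row medians.

    Each pair's windows collapse to a scalar (``agg``, mean by default);
    each participant's ISC is the median of their row of pair scalars.
    Participants with no defined pairs get NaN.
    """
    n = len(pairs.participant_ids)
    scalars = _pair_scalars(pairs, agg)
    M = np.full((n, n), np.nan)
    for (i, j), v in zip(pairs.pairs, scalars):
        M[i, j] = M[j, i] = v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        row_median = np.nanmedian(M, axis=1)
    per_participant = pd.Series(row_median, index=pairs.participant_ids, name="isc")
    return ISCMatrix(
        participant_ids=pairs.participant_ids,
        values=M,
        participant_isc=per_participant,
    )


def isc_timecourse(pairs: PairWindowsArray, design: str = "between") -> ISCTimecourse:
    """Median correlation across pairs, per sliding window."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows -> NaN
        med = np.nanmedian(pairs.r, axis=0)
    return ISCTimecourse(
        window_starts_s=pairs.window_starts_s,
        values=med,
        design=design,
        window_s=pairs.window_s,
    )
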