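"""Preprocessing of raw physiological recordings into clean 1 Hz series.

Heart rate is derived from R-peak event times: the instantaneous rate
60/RR (bpm) is treated as a step function over each inter-peak interval
and averaged within each one-second bin [t, t+1), 0-based from stimulus
onset.  Artifacts — implausible rates or abrupt jumps — are flagged
automatically and repaired by bridging: every flagged run is replaced by
the mean of its nearest clean neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import SignalSeries

#: Plausibility band for adult heart rate during seated media viewing, bpm.
HR_BAND_BPM = (40.0, 180.0)
#: Largest credible second-to-second change in 1 Hz heart rate, bpm.
HR_MAX_JUMP_BPM = 20.0


@dataclass
class RPeakTrain:
    """Strictly increasing ECG R-peak times, in seconds from stimulus onset."""

    peak_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.ndim != 1:
            raise ValueError("peak_times_s must be a 1-D vector")
        if len(self.peak_times_s) >= 2 and not np.all(np.diff(self.peak_times_s) > 0):
            raise ValueError("peak times must be strictly increasing")


def rr_to_heart_rate(
    peaks: RPeakTrain,
    duration_s: int,
    participant_id: str = "unknown",
    group: str = "audiovisual",
) -> SignalSeries:
    """Convert R-peak times to a 1 Hz heart-rate series in bpm.

    The instantaneous rate 60/RR is constant over each inter-peak interval;
    each bin [t, t+1) receives the time-average of that step function.  Bins
    before the first peak or after the last carry the nearest defined rate.
    """
    t = peaks.peak_times_s
    if len(t) < 2:
        raise ValueError("at least two R-peaks are required to derive heart rate")
    if duration_s < t[-1]:
        raise ValueError("duration_s must cover the last R-peak")
    duration_s = int(duration_s)
    rates = 60.0 / np.diff(t)  # bpm over [t_k, t_{k+1})

    # Extend the step function constantly outside [t_0, t_last): integral of
    # the extended function over each bin is the bin mean.
    edges = np.concatenate(([-np.inf], t[1:-1], [np.inf]))
    values = np.empty(duration_s, dtype=float)
    for b in range(duration_s):
        lo, hi = float(b), float(b + 1.0)
        # overlap of [lo, hi) with each rate segment [edges[k], edges[k+1])
        left = np.maximum(edges[:-1], lo)
        right = np.minimum(edges[1:], hi)
        overlap = np.clip(right - left, 0.0, None)
        values[b] = float(np.dot(overlap, rates))  # overlaps sum to 1
    return SignalSeries(
        participant_id=participant_id,
        group=group,
        signal_kind="heart_rate",
        values=values,
        sample_rate_hz=1.0,
    )


def detect_artifacts(
    series: SignalSeries,
    band_bpm: tuple[float, float] = HR_BAND_BPM,
    max_jump_bpm: float = HR_MAX_JUMP_BPM,
) -> np.ndarray:
    """Flag implausible heart-rate samples.

    A sample is flagged when it lies outside ``band_bpm`` or differs from the
    previous sample by more than ``max_jump_bpm``.  Replaces the by-hand
    artifact marking of lab practice with a reproducible rule.
    """
    x = series.values
    lo, hi = band_bpm
    mask = (x < lo) | (x > hi)
    if len(x) > 1:
        jump = np.abs(np.diff(x)) > max_jump_bpm
        mask[1:] |= jump
    return mask


def correct_artifacts(series: SignalSeries, mask: np.ndarray) -> SignalSeries:
    """Replace flagged samples by the mean of the nearest clean neighbours.

    A run of consecutive flagged samples receives a single bridging value,
    the mean of the clean samples just before and just after the run; runs
    touching either boundary copy the single nearest clean value.
    """
    x = series.values.copy()
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(x):
        raise ValueError("mask length must equal series length")
    if mask.all():
        raise ValueError(
            f"participant {series.participant_id}: every sample flagged; recording unusable"
        )
    if not mask.any():
        return series.with_values(x)
    clean_idx = np.flatnonzero(~mask)
    flagged = np.flatnonzero(mask)
    # nearest clean neighbour on each side (searchsorted on clean positions)
    pos = np.searchsorted(clean_idx, flagged)
    has_prev = pos > 0
    has_next = pos < len(clean_idx)
    prev_val = np.where(has_prev, x[clean_idx[np.maximum(pos - 1, 0)]], np.nan)
    next_val = np.where(has_next, x[clean_idx[np.minimum(pos, len(clean_idx) - 1)]], np.nan)
    repl = np.where(
        has_prev & has_next,
        0.5 * (prev_val + next_val),
        np.where(has_prev, prev_val, next_val),
    )
    x[flagged] = repl
    return series.with_values(x)


def clean_heart_rate(
    series: SignalSeries,
    band_bpm: tuple[float, float] = HR_BAND_BPM,
    max_jump_bpm: float = HR_MAX_JUMP_BPM,
) -> SignalSeries:
    """Detect and bridge artifacts in one step."""
    return correct_artifacts(series, detect_artifacts(series, band_bpm, max_jump_bpm))


def standardize(series: SignalSeries) -> SignalSeries:
    """Z-score the full recording (mean 0, sample sd 1, ddof=1)."""
    x = series.values
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd == 0.0:
        raise ValueError(
            f"participant {series.participant_id}: zero variance, cannot standardise"
        )
    return series.with_values((x - x.mean()) / sd)


def movement_magnitude(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    sample_rate_hz: float = 1.0,
    participant_id: str = "unknown",
    group: str = "audiovisual",
    mode: str = "rectified",
) -> SignalSeries:
    """Collapse triaxial acceleration (g-units) to a 1 Hz movement series.

    ``mode`` selects how the axes combine per sample: ``rectified``
    (|x|+|y|+|z|, the default), ``signed`` (x+y+z) or ``euclidean``
    (the vector norm).  The per-sample magnitude is then averaged within
    each one-second bin.
    """
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError("axis vectors must have equal length")
    if mode == "rectified":
        mag = np.abs(ax) + np.abs(ay) + np.abs(az)
    elif mode == "signed":
        mag = ax + ay + az
    elif mode == "euclidean":
        mag = np.sqrt(ax**2 + ay**2 + az**2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    step = int(round(sample_rate_hz))
    if step <= 0:
        raise ValueError("sample_rate_hz must be positive")
    n_bins = len(mag) // step
    binned = mag[: n_bins * step].reshape(n_bins, step).mean(axis=1)
    return SignalSeries(
        participant_id=participant_id,
        group=group,
        signal_kind="movement",
        values=binned,
        sample_rate_hz=1.0,
    )
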