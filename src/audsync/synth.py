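"""Synthetic audiences, stimuli and rating cohorts with known ground truth.

The audience generator emulates the two-modality study design: each
subject's 1 Hz heart-rate series is

    x_i(t) = baseline_i + lambda_shared * s(t) + lambda_mod * m_g(t) + eps_i(t)

where s(t) is a narrative signal common to everyone, m_g(t) a signal
specific to the subject's modality group, and eps_i an AR(1) individual
noise process.  s and the m_g are low-pass filtered (~0.1 Hz cutoff)
standardized Gaussian noise, mutually orthogonalized, so the stimulus
component carries the slow (5-10 s scale) modulation that heart-rate
synchrony rides on while the null keeps realistic autocorrelation.
Transient artifacts are injected as isolated +40 bpm single-sample spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .signal import SignalSeries

ARTIFACT_SPIKE_BPM = 40.0


@dataclass
class AudienceSpec:
    """Parameters of one synthetic two-group audience.

    Defaults mirror the emulated study design: two modality groups of 30,
    a ~55 minute (3300 s) recording at 1 Hz.
    """

    n_subjects_per_group: int = 30
    duration_s: int = 3300
    shared_loading: float = 0.6
    modality_loading: float = 0.6
    ar_coef: float = 0.5
    noise_sd: float = 1.0
    baseline_mean: float = 70.0
    baseline_sd: float = 5.0
    artifact_rate: float = 0.0
    seed: int = 0
    lowpass_cutoff_hz: float = 0.1

    def validate(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if self.duration_s < 15:
            raise ValueError("duration_s must cover at least one 15 s ISC window")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError(
                f"ar_coef must lie in [0, 1) for stationarity, got {self.ar_coef}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        for name in ("shared_loading", "modality_loading"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """What the generator actually injected, for parameter-recovery tests."""

    narrative_signal: np.ndarray
    group_signals: dict[str, np.ndarray]
    baselines: dict[str, float]
    shared_loading: float
    modality_loading: float
    artifact_positions: dict[str, np.ndarray]


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _lowpass_noise(rng: np.random.Generator, n: int, cutoff_hz: float) -> np.ndarray:
    """Standardized Gaussian noise low-pass filtered at ``cutoff_hz`` (1 Hz fs)."""
    white = rng.standard_normal(n)
    if cutoff_hz >= 0.5:
        return _standardize(white)
    b, a = sp_signal.butter(4, cutoff_hz / 0.5)
    return _standardize(sp_signal.filtfilt(b, a, white))


def _orthogonalize(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt on centered vectors, restandardized to mean 0 / sd 1."""
    out: list[np.ndarray] = []
    for v in vectors:
        u = v - v.mean()
        for w in out:
            u = u - (u @ w) / (w @ w) * w
        out.append(_standardize(u))
    return out


def generate_audience(spec: AudienceSpec) -> tuple[list[SignalSeries], GroundTruth]:
    """Simulate the two-group audience; deterministic given the spec's seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = spec.duration_s

    s, m_audio, m_visual = _orthogonalize(
        [_lowpass_noise(rng, T, spec.lowpass_cutoff_hz) for _ in range(3)]
    )
    group_signals = {"audio": m_audio, "visual": m_visual}

    series: list[SignalSeries] = []
    baselines: dict[str, float] = {}
    artifact_positions: dict[str, np.ndarray] = {}
    for group in ("audio", "visual"):
        for k in range(spec.n_subjects_per_group):
            pid = f"{group}_{k:02d}"
            baseline = rng.normal(spec.baseline_mean, spec.baseline_sd)
            innov = rng.standard_normal(T) * spec.noise_sd
            eps = sp_signal.lfilter([1.0], [1.0, -spec.ar_coef], innov)
            x = (
                baseline
                + spec.shared_loading * s
                + spec.modality_loading * group_signals[group]
                + eps
            )
            pos = _artifact_positions(rng, T, spec.artifact_rate)
            x[pos] += ARTIFACT_SPIKE_BPM
            baselines[pid] = float(baseline)
            artifact_positions[pid] = pos
            series.append(
                SignalSeries(
                    participant_id=pid,
                    group=group,
                    signal_kind="heart_rate",
                    values=x,
                    sample_rate_hz=1.0,
                )
            )
    truth = GroundTruth(
        narrative_signal=s,
        group_signals=group_signals,
        baselines=baselines,
        shared_loading=spec.shared_loading,
        modality_loading=spec.modality_loading,
        artifact_positions=artifact_positions,
    )
    return series, truth


def _artifact_positions(
    rng: np.random.Generator, T: int, rate: float
) -> np.ndarray:
    """Isolated interior spike positions (no two adjacent, none at the edges)."""
    if rate <= 0 or T < 3:
        return np.zeros(0, dtype=int)
    candidates = np.flatnonzero(rng.random(T - 2) < rate) + 1  # interior only
    keep: list[int] = []
    for c in candidates:
        if not keep or c - keep[-1] > 1:
            keep.append(int(c))
    return np.asarray(keep, dtype=int)


def narrative_activity(narrative_signal: np.ndarray, window_s: int = 15) -> np.ndarray:
    """Moment-to-moment activity envelope of the narrative signal.

    Windowed inter-subject correlation rises where the shared signal is
    locally variable (eventful), not where its level is high: within a
    window, Pearson r between two subjects grows with the shared signal's
    within-window variance.  The rolling standard deviation is therefore
    the generator's ground-truth "immersion" trace when coupling rating
    cohorts to audience synchrony.
    """
    s = pd.Series(np.asarray(narrative_signal, dtype=float))
    return s.rolling(window_s, min_periods=1).std().fillna(0.0).to_numpy()


# --------------------------------------------------------------------------
# audiovisual stimulus


@dataclass
class StimulusEvents:
    """Ground-truth event script: seconds at which scripted events occur."""

    loud_s: list[int] = field(default_factory=list)
    luminance_step_s: list[int] = field(default_factory=list)
    colour_change_s: list[int] = field(default_factory=list)
    flicker_s: list[int] = field(default_factory=list)


def generate_stimulus(
    duration_s: int,
    frame_rate: int = 5,
    audio_rate: int = 8000,
    seed: int = 0,
    frame_size: tuple[int, int] = (96, 96),
    events: StimulusEvents | None = None,
    moving_blob: bool = True,
    gray_level: float = 0.5,
    base_audio_amplitude: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, StimulusEvents]:
    """Synthesize a toy audiovisual stimulus with a ground-truth event script.

    Video: a high-contrast moving blob on a gray background, plus scripted
    whole-frame luminance steps, blob colour changes and 1 s onset flicker.
    Audio: an amplitude-modulated tone with scripted loud events.  With the
    blob and all events disabled the video is uniform gray; with
    ``base_audio_amplitude=0`` and no loud events the audio is silence.

    Returns (frames [n_frames, H, W, 3] float in [0, 1],
    waveform [duration*audio_rate] float in [-1, 1], events).
    """
    if frame_rate < 1:
        raise ValueError("frame_rate must be >= 1")
    if audio_rate < 1000:
        raise ValueError("audio_rate must be >= 1000")
    if events is None:
        events = StimulusEvents()
    rng = np.random.default_rng(seed)
    H, W = frame_size
    n_frames = duration_s * frame_rate
    frames = np.full((n_frames, H, W, 3), gray_level, dtype=float)

    yy, xx = np.mgrid[0:H, 0:W]
    colour_changes = set(events.colour_change_s)
    for f in range(n_frames):
        t = f / frame_rate
        sec = int(t)
        frame = frames[f]
        if sec in events.luminance_step_s:
            frame += 0.35
        if moving_blob:
            # drifting low-contrast grating keeps every channel time-varying
            grating = 0.06 * np.sin(2 * np.pi * (xx / W * 4.0 + t / 5.0)) * (
                0.5 + 0.5 * np.sin(2 * np.pi * t / 13.0)
            )
            frame += grating[..., None]
            cx = W / 2 + 0.35 * W * np.sin(2 * np.pi * t / 17.0)
            cy = H / 2 + 0.35 * H * np.cos(2 * np.pi * t / 23.0)
            blob_sigma = min(H, W) / 12.0 * (1.0 + 0.3 * np.sin(2 * np.pi * t / 31.0))
            blob = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * blob_sigma**2))
            colour = (
                np.array([1.0, 0.1, 0.1])
                if any(c <= sec < c + 2 for c in colour_changes)
                else np.array(
                    [
                        1.0,
                        0.7 + 0.3 * np.sin(2 * np.pi * t / 19.0),
                        0.7 + 0.3 * np.cos(2 * np.pi * t / 29.0),
                    ]
                )
            )
            amp = 0.45 + 0.15 * np.sin(2 * np.pi * t / 11.0)
            frame += amp * blob[..., None] * colour
        if any(c <= t < c + 1.0 for c in events.flicker_s) and f % 2 == 0:
            frame[: H // 4, : W // 4] += 0.4
        np.clip(frame, 0.0, 1.0, out=frame)

    n_samp = duration_s * audio_rate
    ts = np.arange(n_samp) / audio_rate
    if base_audio_amplitude > 0:
        am = 0.6 + 0.4 * np.sin(2 * np.pi * ts / 7.0 + rng.uniform(0, 2 * np.pi))
        wave = base_audio_amplitude * am * np.sin(2 * np.pi * 440.0 * ts)
    else:
        wave = np.zeros(n_samp)
    for sec in events.loud_s:
        seg = slice(sec * audio_rate, (sec + 1) * audio_rate)
        wave[seg] = 0.95 * np.sin(2 * np.pi * 440.0 * ts[seg])
    return frames, wave, events


# --------------------------------------------------------------------------
# rating cohort


def generate_rating_cohort(
    n_raters: int,
    duration_s: int,
    probe_interval_s: int,
    immersion_signal: np.ndarray,
    noise_sd: float = 0.0,
    missing_rate: float | np.ndarray = 0.0,
    slow_rt_rate: float | np.ndarray = 0.0,
    seed: int = 0,
    discretize: bool = True,
) -> pd.DataFrame:
    """Simulate interval-probed immersion ratings on a 1-7 scale.

    A probe sounds every ``probe_interval_s`` seconds; each rater reports
    the immersion signal averaged over the preceding interval, linearly
    mapped to the 1-7 scale, plus rater noise, rounded to the integer
    scale.  ``missing_rate`` / ``slow_rt_rate`` may be scalars or per-rater
    vectors; the affected response counts are exact
    (round(rate * n_probes) per rater), with positions randomized, so
    downstream exclusion rules behave deterministically.
    """
    if duration_s % probe_interval_s != 0:
        raise ValueError("probe_interval_s must divide duration_s")
    immersion_signal = np.asarray(immersion_signal, dtype=float)
    if len(immersion_signal) < duration_s:
        raise ValueError("immersion_signal must cover duration_s")
    rng = np.random.default_rng(seed)
    n_probes = duration_s // probe_interval_s
    probe_t = (np.arange(1, n_probes + 1)) * probe_interval_s

    seg = immersion_signal[:duration_s].reshape(n_probes, probe_interval_s).mean(axis=1)
    lo, hi = seg.min(), seg.max()
    scaled = np.full(n_probes, 4.0) if hi == lo else 1.0 + 6.0 * (seg - lo) / (hi - lo)

    missing_rate = np.broadcast_to(np.asarray(missing_rate, dtype=float), (n_raters,))
    slow_rt_rate = np.broadcast_to(np.asarray(slow_rt_rate, dtype=float), (n_raters,))

    rows = []
    for k in range(n_raters):
        rid = f"rater_{k:02d}"
        rating = scaled + rng.normal(0.0, noise_sd, size=n_probes)
        if discretize:
            rating = np.clip(np.rint(rating), 1, 7)
        rt = rng.uniform(0.5, 3.0, size=n_probes)
        n_slow = int(round(slow_rt_rate[k] * n_probes))
        if n_slow:
            slow_at = rng.choice(n_probes, size=n_slow, replace=False)
            rt[slow_at] = rng.uniform(5.01, 8.0, size=n_slow)
        n_missing = int(round(missing_rate[k] * n_probes))
        rating_out = rating.astype(float)
        if n_missing:
            miss_at = rng.choice(n_probes, size=n_missing, replace=False)
            rating_out[miss_at] = np.nan
            rt[miss_at] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "rater_id": rid,
                    "probe_t_s": probe_t,
                    "rating": rating_out,
                    "rt_s": rt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
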