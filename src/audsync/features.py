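"""Low-level audiovisual salience features.

Visual salience follows the classic biologically-inspired conspicuity
architecture: per-channel center-surround contrast across a Gaussian
pyramid.  Five channels are computed — intensity, colour (red-green and
blue-yellow opponency), orientation (four oriented edge filters), flicker
(frame-to-frame luminance change) and motion (Reichardt-style shifted
differences between consecutive luminance pyramids).  Each channel map is
normalized by the peak-promotion rule: the map is rescaled to [0, 1] and
multiplied by (M - m̄)^2, where M is the global maximum and m̄ the mean of
the other local maxima, which promotes maps with one dominant peak over
maps with many comparable peaks.

Auditory salience is the per-second RMS energy of the waveform (volume).

The per-second summary of each visual channel is the RMS over pixels of
the channel map, averaged over the frames of that second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

CHANNELS = ("colour", "intensity", "motion", "flicker", "orientation")

#: Center-surround pyramid pairs: (center level, surround level).
CS_PAIRS = tuple((c, c + d) for c in (2, 3, 4) for d in (3, 4))
#: Pyramid level at which rectified differences are summed.
COMMON_LEVEL = 2


def luminance(frame: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an RGB frame in [0, 1]."""
    return 0.299 * frame[..., 0] + 0.587 * frame[..., 1] + 0.114 * frame[..., 2]


def _opponency(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r, g, b = frame[..., 0], frame[..., 1], frame[..., 2]
    return r - g, b - (r + g) / 2.0


def gaussian_pyramid(img: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Level 0 is the input; each level blurs and halves the previous."""
    levels = [img.astype(float)]
    for _ in range(n_levels - 1):
        prev = levels[-1]
        if min(prev.shape) < 2:
            break
        sm = ndimage.gaussian_filter(prev, sigma=1.0, mode="nearest")
        levels.append(sm[::2, ::2])
    return levels


def _center_surround(pyr: list[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    """Sum of rectified center-surround differences at a common scale."""
    out = np.zeros(shape)
    for c, s in CS_PAIRS:
        if s >= len(pyr) or min(pyr[s].shape) < 2:
            continue
        surround = _resize(pyr[s], pyr[c].shape)
        diff = np.abs(pyr[c] - surround)
        out += _resize(diff, shape)
    return out


def _resize(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if img.shape == shape:
        return img
    zoom = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return ndimage.zoom(img, zoom, order=1, mode="nearest", grid_mode=True)


def peak_promotion(m: np.ndarray, neighborhood: int = 9) -> np.ndarray:
    """Normalize by (M - m̄)^2: promote maps with a single dominant peak."""
    peak = m.max()
    if peak <= 1e-12:  # numerically zero contrast (resampling residue)
        return np.zeros_like(m)
    m = m / peak
    local_max = (m == ndimage.maximum_filter(m, size=neighborhood, mode="nearest")) & (
        m > 0.05
    )
    vals = m[local_max]
    m_bar = float(vals[vals < 1.0].mean()) if np.any(vals < 1.0) else 0.0
    return m * (1.0 - m_bar) ** 2


_ORIENTATIONS = (0.0, 45.0, 90.0, 135.0)


def _oriented_responses(img: np.ndarray) -> list[np.ndarray]:
    """Rectified oriented-edge responses via directional Gaussian derivatives."""
    gy = ndimage.gaussian_filter(img, sigma=1.0, order=(1, 0), mode="nearest")
    gx = ndimage.gaussian_filter(img, sigma=1.0, order=(0, 1), mode="nearest")
    out = []
    for theta in _ORIENTATIONS:
        rad = np.deg2rad(theta)
        # edge energy perpendicular to the orientation
        out.append(np.abs(np.cos(rad) * gx + np.sin(rad) * gy))
    return out


_SHIFTS = ((0, 1), (1, 0), (0, -1), (-1, 0))


def conspicuity_maps(
    frame_t: np.ndarray,
    frame_prev: np.ndarray | None = None,
    n_levels: int = 9,
) -> dict[str, np.ndarray]:
    """Five conspicuity maps for one frame (RGB float in [0, 1]).

    ``frame_prev`` feeds the temporal channels; for the first frame the
    flicker and motion maps are defined as zero.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    if frame_t.ndim != 3 or frame_t.shape[-1] != 3:
        raise ValueError("frames must be HxWx3 RGB")
    if frame_prev is not None and frame_prev.shape != frame_t.shape:
        raise ValueError("frames must share shape")
    lum = luminance(frame_t)
    pyr_lum = gaussian_pyramid(lum, n_levels)
    common = pyr_lum[min(COMMON_LEVEL, len(pyr_lum) - 1)].shape

    maps: dict[str, np.ndarray] = {}
    maps["intensity"] = _center_surround(pyr_lum, common)

    rg, by = _opponency(frame_t)
    maps["colour"] = _center_surround(gaussian_pyramid(rg, n_levels), common) + (
        _center_surround(gaussian_pyramid(by, n_levels), common)
    )

    orient = np.zeros(common)
    for resp in _oriented_responses(lum):
        orient += _center_surround(gaussian_pyramid(resp, n_levels), common)
    maps["orientation"] = orient

    if frame_prev is None:
        maps["flicker"] = np.zeros(common)
        maps["motion"] = np.zeros(common)
    else:
        lum_prev = luminance(np.asarray(frame_prev, dtype=float))
        maps["flicker"] = _center_surround(
            gaussian_pyramid(np.abs(lum - lum_prev), n_levels), common
        )
        pyr_prev = gaussian_pyramid(lum_prev, n_levels)
        motion = np.zeros(common)
        for dy, dx in _SHIFTS:
            resp_pyr = []
            for lt, lp in zip(pyr_lum, pyr_prev):
                sh_p = np.roll(lp, (dy, dx), axis=(0, 1))
                sh_t = np.roll(lt, (dy, dx), axis=(0, 1))
                resp_pyr.append(np.abs(lt * sh_p - lp * sh_t))
            motion += _center_surround(resp_pyr, common)
        maps["motion"] = motion

    return {name: peak_promotion(m) for name, m in maps.items()}


def channel_rms_per_second(
    frames: np.ndarray, frame_rate: int, n_levels: int = 9
) -> pd.DataFrame:
    """Per-second conspicuity-channel RMS traces for a frame sequence.

    For every frame the RMS over pixels of each channel map is taken; the
    per-second value is the mean of the frame RMS values within [t, t+1).
    """
    frames = np.asarray(frames, dtype=float)
    if frame_rate < 1:
        raise ValueError("frame_rate must be >= 1")
    n_frames = len(frames)
    frame_rms = {ch: np.zeros(n_frames) for ch in CHANNELS}
    prev = None
    for f in range(n_frames):
        maps = conspicuity_maps(frames[f], prev, n_levels=n_levels)
        for ch in CHANNELS:
            frame_rms[ch][f] = np.sqrt(np.mean(maps[ch] ** 2))
        prev = frames[f]
    n_sec = n_frames // frame_rate
    data = {"t_s": np.arange(n_sec, dtype=int)}
    for ch in CHANNELS:
        per_frame = frame_rms[ch][: n_sec * frame_rate]
        data[ch] = per_frame.reshape(n_sec, frame_rate).mean(axis=1)
    return pd.DataFrame(data)


def audio_rms_per_second(waveform: np.ndarray, sample_rate: int) -> pd.DataFrame:
    """Per-second RMS volume; stereo input is averaged to mono first."""
    w = np.asarray(waveform, dtype=float)
    if w.ndim == 2:
        w = w.mean(axis=1)
    if w.ndim != 1:
        raise ValueError("waveform must be mono (T,) or stereo (T, 2)")
    n_sec = len(w) // sample_rate
    seg = w[: n_sec * sample_rate].reshape(n_sec, sample_rate)
    return pd.DataFrame(
        {"t_s": np.arange(n_sec, dtype=int), "rms_volume": np.sqrt((seg**2).mean(axis=1))}
    )


def feature_table(
    frames: np.ndarray,
    frame_rate: int,
    waveform: np.ndarray,
    audio_rate: int,
    n_levels: int = 9,
) -> pd.DataFrame:
    """Join the five visual channels with RMS volume on whole seconds."""
    vid = channel_rms_per_second(frames, frame_rate, n_levels=n_levels)
    aud = audio_rms_per_second(waveform, audio_rate)
    return vid.merge(aud, on="t_s", how="inner")


def read_frames(directory: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load a directory of PNG/JPEG frames, sorted by filename, to [0, 1] RGB."""
    import imageio.v3 as iio

    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise ValueError(f"no frames found in {directory}")
    frames = []
    for p in paths:
        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.max() > 1.0:
            img = img / 255.0
        frames.append(img[..., :3])
    return np.stack(frames), [p.name for p in paths]


def write_frames(frames: np.ndarray, directory: str | Path) -> list[str]:
    """Write float [0, 1] RGB frames as a numbered PNG sequence."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(np.asarray(frames, dtype=float)):
        name = f"frame_{i:05d}.png"
        iio.imwrite(directory / name, (np.clip(frame, 0, 1) * 255).astype(np.uint8))
        names.append(name)
    return names


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file to float in [-1, 1]."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    scale = 32768.0 if np.issubdtype(data.dtype, np.integer) else 1.0
    return np.asarray(data, dtype=float) / scale, int(rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write float [-1, 1] audio as 16-bit PCM WAV."""
    from scipy.io import wavfile

    pcm = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (pcm * 32767).astype(np.int16))
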