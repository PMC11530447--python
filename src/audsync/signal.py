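"""Core containers for uniformly sampled physiological signals and their text I/O.

The canonical on-disk form is a long delimited table with columns
``participant_id, group, signal_kind, t_s, value`` where ``t_s`` counts
integer seconds from stimulus onset (0-based) for 1 Hz series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("audio", "visual", "audiovisual")
SIGNAL_KINDS = ("heart_rate", "skin_conductance", "movement")


@dataclass
class SignalSeries:
    """One participant's uniformly sampled signal.

    Parameters
    ----------
    participant_id : str
        Unique participant label.
    group : str
        Stimulus modality condition: ``audio``, ``visual`` or ``audiovisual``.
    signal_kind : str
        ``heart_rate`` (bpm), ``skin_conductance`` (microsiemens or z-units)
        or ``movement`` (g-units, 1 g = 9.81 m/s^2).
    values : ndarray
        Sample values.
    sample_rate_hz : float
        Sampling rate; downstream synchrony analysis expects 1 Hz.
    t0_s : float
        Time of the first sample, in seconds from stimulus onset.
    """

    participant_id: str
    group: str
    signal_kind: str
    values: np.ndarray
    sample_rate_hz: float = 1.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(
                f"unknown signal_kind {self.signal_kind!r}; expected one of {SIGNAL_KINDS}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.values)) / self.sample_rate_hz

    def with_values(self, values: np.ndarray) -> "SignalSeries":
        return replace(self, values=np.asarray(values, dtype=float))


def signals_to_frame(series: Iterable[SignalSeries]) -> pd.DataFrame:
    """Stack series into the canonical long table (1 Hz series only)."""
    rows = []
    for s in series:
        if s.sample_rate_hz != 1.0:
            raise ValueError(
                f"canonical table holds 1 Hz series; {s.participant_id} is "
                f"{s.sample_rate_hz} Hz — bin it first"
            )
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "group": s.group,
                    "signal_kind": s.signal_kind,
                    "t_s": np.arange(len(s.values), dtype=int) + int(s.t0_s),
                    "value": s.values,
                }
            )
        )
    if not rows:
        raise ValueError("no series given")
    return pd.concat(rows, ignore_index=True)


def write_signals(series: Iterable[SignalSeries], path: str | Path, sep: str = "\t") -> None:
    signals_to_frame(series).to_csv(path, sep=sep, index=False)


def frame_to_signals(table: pd.DataFrame) -> list[SignalSeries]:
    out: list[SignalSeries] = []
    required = {"participant_id", "group", "signal_kind", "t_s", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"signal table is missing columns: {sorted(missing)}")
    for (pid, group, kind), sub in table.groupby(
        ["participant_id", "group", "signal_kind"], sort=True
    ):
        sub = sub.sort_values("t_s")
        t = sub["t_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            raise ValueError(f"participant {pid}: t_s is not contiguous 1 Hz")
        out.append(
            SignalSeries(
                participant_id=str(pid),
                group=str(group),
                signal_kind=str(kind),
                values=sub["value"].to_numpy(dtype=float),
                sample_rate_hz=1.0,
                t0_s=float(t[0]) if len(t) else 0.0,
            )
        )
    return out


def read_signals(path: str | Path, sep: str = "\t") -> list[SignalSeries]:
    return frame_to_signals(pd.read_csv(path, sep=sep))


def read_rpeaks(path: str | Path) -> np.ndarray:
    """Read an R-peak event list: one peak time (seconds) per line."""
    peaks = np.loadtxt(path, ndmin=1, dtype=float)
    return np.sort(peaks)
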