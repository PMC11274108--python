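"""Domain containers: recordings, windows, spectrograms and window sets.

A ``SensorRecording`` is one subject's continuous six-channel gyroscope
stream (wrist x/y/z then ankle x/y/z, deg/s) plus round annotations and
exclusion intervals. Segmentation produces ``GyroWindow`` objects, and
batches of windows travel as a ``WindowSet`` — stacked arrays aligned with
a pandas metadata table — which persists to HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CHANNEL_NAMES = ("wrist_x", "wrist_y", "wrist_z", "ankle_x", "ankle_y", "ankle_z")
MED_STATES = ("OFF", "ON")
UPDRS_MAX = 108  # maximum attainable motor-exam total


@dataclass
class RoundAnnotation:
    round_index: int
    start_s: float
    end_s: float
    updrs_score: int
    med_state: str
    activities: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if not 0 <= self.updrs_score <= UPDRS_MAX:
            raise ValueError(f"updrs_score must be in [0, {UPDRS_MAX}]")
        if self.med_state not in MED_STATES:
            raise ValueError(f"med_state must be one of {MED_STATES}")
        if self.end_s <= self.start_s:
            raise ValueError("round interval must have positive length")
        for label, a, b in self.activities:
            if a < self.start_s - 1e-9 or b > self.end_s + 1e-9:
                raise ValueError(
                    f"activity {label!r} [{a}, {b}) outside round "
                    f"[{self.start_s}, {self.end_s})")


@dataclass
class SensorRecording:
    subject_id: str
    signals: np.ndarray          # (n_samples, 6), deg/s
    fs: float
    rounds: list[RoundAnnotation]
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[1] != len(CHANNEL_NAMES):
            raise ValueError("signals must be (n_samples, 6)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        dur = self.duration_s
        ivs = sorted(self.exclusion_intervals)
        for (a, b) in ivs:
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"exclusion [{a}, {b}) outside [0, {dur})")
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError("exclusion intervals overlap")
        starts = sorted((r.start_s, r.end_s) for r in self.rounds)
        for (a1, b1), (a2, b2) in zip(starts, starts[1:]):
            if a2 < b1 - 1e-9:
                raise ValueError("round intervals overlap")

    @property
    def duration_s(self) -> float:
        return self.signals.shape[0] / self.fs


@dataclass
class GyroWindow:
    x_r: np.ndarray              # (window_samples, 6)
    subject_id: str
    round_index: int
    activity_label: str
    start_s: float
    updrs_score: int = -1
    med_state: str = "OFF"


@dataclass
class Spectrogram:
    x_s: np.ndarray              # (freq_bins, frames, 6), dB
    freq_axis: np.ndarray        # Hz
    time_axis: np.ndarray        # s


class WindowSet:
    """Stacked raw windows plus aligned per-window metadata.

    ``x_r`` has shape (N, window_samples, 6); ``meta`` is a DataFrame with
    columns subject, round, activity, med_state, updrs, start_s.
    """

    META_COLUMNS = ("subject", "round", "activity", "med_state", "updrs", "start_s")

    def __init__(self, x_r: np.ndarray, meta: pd.DataFrame):
        x_r = np.asarray(x_r, dtype=float)
        if x_r.ndim != 3:
            raise ValueError("x_r must be (N, samples, channels)")
        if len(meta) != x_r.shape[0]:
            raise ValueError("metadata length mismatch")
        missing = set(self.META_COLUMNS) - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        self.x_r = x_r
        self.meta = meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.x_r.shape[0]

    @classmethod
    def from_windows(cls, windows: list[GyroWindow]) -> "WindowSet":
        if not windows:
            raise ValueError("empty window list")
        x = np.stack([w.x_r for w in windows])
        meta = pd.DataFrame({
            "subject": [w.subject_id for w in windows],
            "round": [w.round_index for w in windows],
            "activity": [w.activity_label for w in windows],
            "med_state": [w.med_state for w in windows],
            "updrs": [w.updrs_score for w in windows],
            "start_s": [w.start_s for w in windows],
        })
        return cls(x, meta)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        mask = np.asarray(mask)
        return WindowSet(self.x_r[mask], self.meta.loc[mask].reset_index(drop=True))

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject"].to_numpy()

    def save_hdf5(self, path, x_s: np.ndarray | None = None,
                  attrs: dict | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("x_r", data=self.x_r)
            if x_s is not None:
                f.create_dataset("x_s", data=x_s)
            g = f.create_group("meta")
            for col in self.META_COLUMNS:
                vals = self.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
            for k, v in (attrs or {}).items():
                f.attrs[k] = v

    @classmethod
    def load_hdf5(cls, path) -> tuple["WindowSet", np.ndarray | None, dict]:
        with h5py.File(path, "r") as f:
            x_r = f["x_r"][...]
            x_s = f["x_s"][...] if "x_s" in f else None
            cols = {}
            for col in cls.META_COLUMNS:
                v = f["meta"][col][...]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[col] = v
            attrs = dict(f.attrs)
        return cls(x_r, pd.DataFrame(cols)), x_s, attrs
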