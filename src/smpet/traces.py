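"""Per-molecule multi-channel intensity time traces.

A :class:`TraceSet` holds one intensity array per molecule and channel on a
common frame grid, plus acquisition metadata.  The on-disk form is a flat CSV
with columns ``molecule_id, frame, time_s, intensity_green[, intensity_red]``
(one-colour data simply omit the missing channel column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("green", "red")


@dataclass
class TraceSet:
    frame_interval_s: float
    channels: tuple[str, ...]
    intensities: dict  # molecule_id -> {channel: np.ndarray of shape (n_frames,)}
    true_states: dict = field(default_factory=dict)  # optional ground truth, same layout

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        lengths = {arr.size for per_ch in self.intensities.values() for arr in per_ch.values()}
        if len(lengths) > 1:
            raise ValueError("all traces must share one frame grid")

    @property
    def molecule_ids(self) -> list:
        return list(self.intensities)

    @property
    def n_frames(self) -> int:
        for per_ch in self.intensities.values():
            for arr in per_ch.values():
                return int(arr.size)
        return 0

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def trace(self, molecule_id, channel: str) -> np.ndarray:
        return self.intensities[molecule_id][channel]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        t = self.time_s
        frames = np.arange(self.n_frames)
        for mol, per_ch in self.intensities.items():
            block = {"molecule_id": mol, "frame": frames, "time_s": t}
            for ch in self.channels:
                block[f"intensity_{ch}"] = per_ch[ch]
            rows.append(pd.DataFrame(block))
        if not rows:
            cols = ["molecule_id", "frame", "time_s"] + [f"intensity_{c}" for c in self.channels]
            return pd.DataFrame(columns=cols)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval_s: float | None = None) -> "TraceSet":
        channels = tuple(c.removeprefix("intensity_") for c in df.columns
                         if c.startswith("intensity_"))
        if not channels:
            raise ValueError("no intensity_<channel> columns found")
        if frame_interval_s is None:
            tt = df[df.molecule_id == df.molecule_id.iloc[0]].sort_values("frame")
            dts = np.diff(tt["time_s"].to_numpy())
            if dts.size == 0:
                raise ValueError("cannot infer frame interval from a single-frame trace")
            frame_interval_s = float(np.median(dts))
        intensities = {}
        for mol, grp in df.groupby("molecule_id", sort=False):
            grp = grp.sort_values("frame")
            intensities[mol] = {ch: grp[f"intensity_{ch}"].to_numpy(dtype=float)
                                for ch in channels}
        return cls(frame_interval_s=frame_interval_s, channels=channels,
                   intensities=intensities)

    @classmethod
    def from_csv(cls, path, frame_interval_s: float | None = None) -> "TraceSet":
        return cls.from_dataframe(pd.read_csv(path), frame_interval_s=frame_interval_s)
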