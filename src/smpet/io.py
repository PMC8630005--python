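"""File formats for pipeline artifacts.

Image stacks are multi-frame 16-bit grayscale TIFFs (one file per channel,
frame index = time order); traces, steps, idealizations, events and dwells
are flat CSVs; ground-truth event logs, channel transforms and kinetic
summaries are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AffineMap
from .imaging import ChannelTransform
from .simulate import ClampTrajectory
from .stepdetect import FLUORESCENT, QUENCHED, IdealizedTrace, Step


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    return stack


def write_event_log(path, trajectories: list[ClampTrajectory]) -> None:
    log = {str(traj.molecule_id): [{"frame": ev.frame, "time_s": ev.time_s,
                                    "channel": ev.channel, "kind": ev.kind}
                                   for ev in traj.events]
           for traj in trajectories}
    Path(path).write_text(json.dumps(log, indent=1))


def read_event_log(path) -> dict:
    return json.loads(Path(path).read_text())


def steps_to_frame(idealized: dict) -> pd.DataFrame:
    """idealized: molecule_id -> {channel: IdealizedTrace} -> steps CSV table."""
    rows = []
    for mol, per_ch in idealized.items():
        for ch, ideal in per_ch.items():
            for s in ideal.steps:
                rows.append({"molecule_id": mol, "channel": ch, "frame": s.frame,
                             "direction": s.direction, "amplitude": s.amplitude})
    return pd.DataFrame(rows, columns=["molecule_id", "channel", "frame",
                                       "direction", "amplitude"])


def steps_from_frame(df: pd.DataFrame) -> dict:
    """Steps CSV table -> molecule_id -> {channel: [Step, ...]}."""
    out: dict = {}
    for (mol, ch), grp in df.groupby(["molecule_id", "channel"], sort=False):
        grp = grp.sort_values("frame")
        out.setdefault(mol, {})[ch] = [
            Step(frame=int(r.frame), direction=str(r.direction),
                 amplitude=float(r.amplitude)) for r in grp.itertuples()]
    return out


def idealization_to_frame(idealized: dict) -> pd.DataFrame:
    rows = []
    for mol, per_ch in idealized.items():
        for ch, ideal in per_ch.items():
            rows.append(pd.DataFrame({
                "molecule_id": mol, "channel": ch,
                "frame": np.arange(ideal.n_frames),
                "level_label": ideal.labels}))
    if not rows:
        return pd.DataFrame(columns=["molecule_id", "channel", "frame", "level_label"])
    return pd.concat(rows, ignore_index=True)


def idealization_from_frame(df: pd.DataFrame, steps: dict | None = None) -> dict:
    out: dict = {}
    for (mol, ch), grp in df.groupby(["molecule_id", "channel"], sort=False):
        labels = grp.sort_values("frame")["level_label"].to_numpy(dtype=object)
        step_list = (steps or {}).get(mol, {}).get(ch, [])
        single = QUENCHED not in labels or FLUORESCENT not in labels
        out.setdefault(mol, {})[ch] = IdealizedTrace(labels=labels, steps=step_list,
                                                     single_level=single)
    return out


def write_transform(path, transform: ChannelTransform) -> None:
    Path(path).write_text(json.dumps({
        "matrix": transform.affine.matrix.tolist(),
        "offset": transform.affine.offset.tolist(),
        "residual_rms_px": transform.residual_rms_px,
        "n_beads": transform.n_beads,
    }, indent=1))


def read_transform(path) -> ChannelTransform:
    d = json.loads(Path(path).read_text())
    return ChannelTransform(AffineMap(np.array(d["matrix"]), np.array(d["offset"])),
                            residual_rms_px=float(d["residual_rms_px"]),
                            n_beads=int(d.get("n_beads", 0)))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
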