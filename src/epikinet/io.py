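"""Delimited-text I/O for the shared table formats.

The TAC table is the package's interchange format: one row per frame per
VOI per side with columns ``frame_start_s, frame_duration_s,
value_kBq_per_mL, voi_id, side, subject_id``.  Carotid/background curves
use the same layout with side in {left_carotid, right_carotid,
carotid_background}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import FrameSchedule
from .idif import CarotidMeasurement
from .kinetics import TissueTAC

TAC_COLUMNS = ["frame_start_s", "frame_duration_s", "value_kBq_per_mL",
               "voi_id", "side", "subject_id"]

__all__ = [
    "TAC_COLUMNS",
    "read_tac_table",
    "write_tac_table",
    "tacs_from_table",
    "schedule_from_table",
    "write_schedule",
    "read_schedule",
    "carotid_from_table",
    "write_json",
    "read_json",
]


def write_tac_table(df: pd.DataFrame, path) -> None:
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC table missing columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_tac_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC table missing columns {sorted(missing)}")
    return df


def schedule_from_table(df: pd.DataFrame) -> FrameSchedule:
    sub = df[["frame_start_s", "frame_duration_s"]].drop_duplicates().sort_values("frame_start_s")
    return FrameSchedule(starts=sub["frame_start_s"].to_numpy(float),
                         durations=sub["frame_duration_s"].to_numpy(float))


def tacs_from_table(df: pd.DataFrame) -> list[TissueTAC]:
    """Split a long TAC table into TissueTAC objects (one per voi x side x subject)."""
    out = []
    for (subject, voi, side), g in df.groupby(["subject_id", "voi_id", "side"], sort=True):
        g = g.sort_values("frame_start_s")
        sched = FrameSchedule(starts=g["frame_start_s"].to_numpy(float),
                              durations=g["frame_duration_s"].to_numpy(float))
        out.append(TissueTAC(schedule=sched, values=g["value_kBq_per_mL"].to_numpy(float),
                             voi_id=str(voi), side=str(side)))
    return out


def write_schedule(schedule: FrameSchedule, path) -> None:
    schedule.to_table().to_csv(path, index=False)


def read_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path)
    return FrameSchedule(starts=df["frame_start_s"].to_numpy(float),
                         durations=df["frame_duration_s"].to_numpy(float))


def carotid_from_table(df: pd.DataFrame) -> CarotidMeasurement:
    """Carotid measurement from a table with columns time_min, cmeas, cbkgd."""
    df = df.sort_values("time_min")
    return CarotidMeasurement(times_min=df["time_min"].to_numpy(float),
                              cmeas=df["cmeas_kBq_per_mL"].to_numpy(float),
                              cbkgd=df["cbkgd_kBq_per_mL"].to_numpy(float))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
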