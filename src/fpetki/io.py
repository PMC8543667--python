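"""Tabular readers and writers.

All files are TSV/CSV with commented ``#`` metadata lines declaring units.
On disk time is stored in seconds and activity in kBq/mL; in memory the
package works in minutes.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .blood import BloodSamples
from .frames import FrameSchedule
from .synthetic.mid import MidTrial

_SEC = 60.0


def _read_table(path: Path | str, sep: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return pd.read_csv(path, sep=sep, comment="#")


def write_tac_table(path: Path | str, frames: FrameSchedule, tacs: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": frames.start * _SEC,
            "frame_end_s": frames.end * _SEC,
            **{name: np.asarray(v, dtype=float) for name, v in tacs.items()},
        }
    )
    with open(path, "w") as fh:
        fh.write("# time: seconds; activity: kBq/mL per region column\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tac_table(path: Path | str) -> tuple[FrameSchedule, dict[str, np.ndarray]]:
    df = _read_table(path)
    frames = FrameSchedule(
        df["frame_start_s"].to_numpy() / _SEC, df["frame_end_s"].to_numpy() / _SEC
    )
    tacs = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in ("frame_start_s", "frame_end_s")
    }
    return frames, tacs


def write_blood_table(
    path: Path | str, time_min: np.ndarray, whole_blood: np.ndarray, plasma: np.ndarray
) -> None:
    df = pd.DataFrame(
        {
            "time_s": np.asarray(time_min, dtype=float) * _SEC,
            "wholeblood_kBq_per_mL": whole_blood,
            "plasma_kBq_per_mL": plasma,
        }
    )
    with open(path, "w") as fh:
        fh.write("# arterial samples; time: seconds; activity: kBq/mL\n")
        df.to_csv(fh, sep="\t", index=False)


def read_blood_table(path: Path | str) -> BloodSamples:
    df = _read_table(path)
    return BloodSamples(
        time=df["time_s"].to_numpy() / _SEC,
        whole_blood=df["wholeblood_kBq_per_mL"].to_numpy(dtype=float),
        plasma=df["plasma_kBq_per_mL"].to_numpy(dtype=float),
    )


def write_motion_table(path: Path | str, motion: np.ndarray) -> None:
    cols = ["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"]
    df = pd.DataFrame(np.asarray(motion, dtype=float), columns=cols)
    with open(path, "w") as fh:
        fh.write("# rigid-body motion parameters per frame\n")
        df.to_csv(fh, sep="\t", index=False)


def read_motion_table(path: Path | str) -> np.ndarray:
    return _read_table(path).to_numpy(dtype=float)


def write_trial_log(path: Path | str, trials: Sequence[MidTrial]) -> None:
    df = pd.DataFrame([dataclasses.asdict(tr) for tr in trials])
    df.to_csv(path, index=False)


def read_trial_log(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"trial_index", "block", "amount", "time_limit", "reaction_time", "hit", "balance_delta"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    return df


def write_curve_table(path: Path | str, time_min: np.ndarray, value: np.ndarray, name: str) -> None:
    df = pd.DataFrame({"time_s": np.asarray(time_min, dtype=float) * _SEC, name: value})
    with open(path, "w") as fh:
        fh.write(f"# {name} versus time; time: seconds\n")
        df.to_csv(fh, sep="\t", index=False)


def read_curve_table(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    df = _read_table(path)
    cols = [c for c in df.columns if c != "time_s"]
    return df["time_s"].to_numpy() / _SEC, df[cols[0]].to_numpy(dtype=float)


def write_json(path: Path | str, payload: dict) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


def read_json(path: Path | str) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return json.loads(path.read_text())
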