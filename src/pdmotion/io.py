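"""Reading and writing the on-disk recording format.

One subject = one CSV of the six gyroscope traces plus one JSON annotation
file. CSV header: ``time_s,wrist_x,wrist_y,wrist_z,ankle_x,ankle_y,ankle_z``
(deg/s at 64 Hz). JSON schema::

    {"subject_id": str, "fs": 64,
     "rounds": [{"index": int, "start_s": float, "end_s": float,
                 "updrs": int, "med_state": "OFF"|"ON",
                 "activities": [[label, start_s, end_s], ...]}, ...],
     "exclusions": [[start_s, end_s], ...]}
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CHANNEL_NAMES, RoundAnnotation, SensorRecording

CSV_COLUMNS = ("time_s",) + CHANNEL_NAMES


def write_recording(recording: SensorRecording, csv_path, json_path) -> None:
    n = recording.signals.shape[0]
    df = pd.DataFrame(recording.signals, columns=list(CHANNEL_NAMES))
    df.insert(0, "time_s", np.arange(n) / recording.fs)
    df.to_csv(csv_path, index=False, float_format="%.6f")
    ann = {
        "subject_id": recording.subject_id,
        "fs": recording.fs,
        "rounds": [
            {
                "index": r.round_index,
                "start_s": r.start_s,
                "end_s": r.end_s,
                "updrs": r.updrs_score,
                "med_state": r.med_state,
                "activities": [[lab, a, b] for lab, a, b in r.activities],
            }
            for r in recording.rounds
        ],
        "exclusions": [[a, b] for a, b in recording.exclusion_intervals],
    }
    Path(json_path).write_text(json.dumps(ann, indent=1))


def read_recording(csv_path, json_path) -> SensorRecording:
    """Load and validate a recording; malformed rows are reported by line."""
    df = pd.read_csv(csv_path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing columns {missing}")
    bad = df[list(CSV_COLUMNS)].isna().any(axis=1)
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
        raise ValueError(f"{csv_path}: malformed rows at lines {lines[:20]}")
    ann = json.loads(Path(json_path).read_text())
    fs = float(ann["fs"])
    if fs != 64.0:
        raise ValueError(f"{json_path}: unsupported sampling rate {fs} (need 64)")
    rounds = [
        RoundAnnotation(
            round_index=int(r["index"]),
            start_s=float(r["start_s"]),
            end_s=float(r["end_s"]),
            updrs_score=int(r["updrs"]),
            med_state=str(r["med_state"]),
            activities=[(str(l), float(a), float(b))
                        for l, a, b in r.get("activities", [])],
        )
        for r in ann.get("rounds", [])
    ]
    return SensorRecording(
        subject_id=str(ann["subject_id"]),
        signals=df[list(CHANNEL_NAMES)].to_numpy(dtype=float),
        fs=fs,
        rounds=rounds,
        exclusion_intervals=[(float(a), float(b))
                             for a, b in ann.get("exclusions", [])],
    )


def write_cohort(recordings, out_dir) -> list[tuple[Path, Path]]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        csv_path = out_dir / f"{rec.subject_id}.csv"
        json_path = out_dir / f"{rec.subject_id}.json"
        write_recording(rec, csv_path, json_path)
        paths.append((csv_path, json_path))
    return paths


def read_cohort(data_dir) -> list[SensorRecording]:
    data_dir = Path(data_dir)
    csvs = sorted(data_dir.glob("*.csv"))
    if not csvs:
        raise FileNotFoundError(f"no recording CSVs in {data_dir}")
    return [read_recording(p, p.with_suffix(".json")) for p in csvs]
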