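"""Readers and writers for the frame table dialects.

Two on-disk forms are supported, both lossless:

* CSV — one row per frame: ``timestamp`` plus 76 count columns named
  ``ch{c}_bin{b}`` (channel-major, c in 1..4, b in 1..19).
* JSON-lines — one object per line: ``{"timestamp": t, "counts":
  [[19 ints] × 4]}``.

Schema violations are rejected with the offending row numbers; an empty
file yields an empty frame list with a warning (a session may simply
not have started).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .instrument import Frame, N_BINS, N_CHANNELS

FRAME_COLUMNS = ["timestamp"] + [
    f"ch{c}_bin{b}" for c in range(1, N_CHANNELS + 1) for b in range(1, N_BINS + 1)
]


def frames_to_table(frames: Sequence[Frame]) -> pd.DataFrame:
    rows = [np.concatenate(([f.timestamp], f.flatten())) for f in frames]
    df = pd.DataFrame(rows, columns=FRAME_COLUMNS)
    for col in FRAME_COLUMNS[1:]:
        df[col] = df[col].astype(np.int64)
    return df


def table_to_frames(df: pd.DataFrame, source: str = "<table>") -> list[Frame]:
    missing = [c for c in FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing[:5]}{'...' if len(missing) > 5 else ''}")
    bad_rows = df.index[df[FRAME_COLUMNS].isna().any(axis=1)].tolist()
    if bad_rows:
        raise ValueError(f"{source}: malformed rows (missing values) at {bad_rows}")
    frames = []
    for _, row in df.iterrows():
        counts = row[FRAME_COLUMNS[1:]].to_numpy(dtype=np.int64).reshape(N_CHANNELS, N_BINS)
        frames.append(Frame(timestamp=float(row["timestamp"]), counts=counts))
    return frames


def write_frames_csv(path, frames: Sequence[Frame], header_comment: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frames_to_table(frames).to_csv(fh, index=False)
    return path


def read_frames_csv(path) -> list[Frame]:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty frame file, returning an empty session")
        return []
    if df.empty:
        warnings.warn(f"{path}: empty frame file, returning an empty session")
        return []
    return table_to_frames(df, source=str(path))


def write_frames_jsonl(path, frames: Sequence[Frame]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for f in frames:
            fh.write(
                json.dumps({"timestamp": f.timestamp, "counts": f.counts.tolist()}) + "\n"
            )
    return path


def read_frames_jsonl(path) -> list[Frame]:
    path = Path(path)
    frames: list[Frame] = []
    errors: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                counts = np.asarray(obj["counts"], dtype=np.int64)
                if counts.shape != (N_CHANNELS, N_BINS):
                    raise ValueError(f"counts shape {counts.shape}")
                frames.append(Frame(timestamp=float(obj["timestamp"]), counts=counts))
            except (KeyError, ValueError, json.JSONDecodeError):
                errors.append(lineno)
    if errors:
        raise ValueError(f"{path}: malformed rows at lines {errors}")
    if not frames:
        warnings.warn(f"{path}: empty frame file, returning an empty session")
    return frames
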