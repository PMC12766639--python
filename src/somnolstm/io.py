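"""CSV readers and writers for raw streams and hypnograms.

Dialects
--------
accelerometer : ``timestamp,x,y,z`` with a header row. Timestamps are either
    ISO-8601 strings or epoch-seconds floats.
heart rate    : ``timestamp,bpm``.
hypnogram     : two metadata lines ``lights_off=...`` and ``lights_on=...``
    followed by a ``epoch_index,stage`` CSV block.

Readers log (and count) dropped non-finite rows; writers emit epoch-seconds
floats at full precision so that write -> read round-trips are numerically
exact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .simulate import STAGES, HeartRateSeries, Hypnogram, SensorRecording

logger = logging.getLogger(__name__)

_KNOWN_FS = np.array([25, 50, 100])


def _parse_timestamps(col: pd.Series) -> np.ndarray:
    """Accept epoch-seconds floats or ISO-8601 strings; return float seconds."""
    if np.issubdtype(col.dtype, np.number):
        return col.to_numpy(dtype=float)
    try:
        return col.astype(float).to_numpy()
    except (TypeError, ValueError):
        pass
    try:
        dt = pd.to_datetime(col, utc=True, format="ISO8601")
    except (TypeError, ValueError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc
    return dt.astype("int64").to_numpy() / 1e9


def _check_monotone(ts: np.ndarray, what: str) -> None:
    violations = int(np.sum(np.diff(ts) <= 0))
    if violations > 1:
        raise FormatError(
            f"{what}: timestamps non-monotone at {violations} positions"
        )


def read_accel_csv(path: str | Path) -> SensorRecording:
    """Read a raw accelerometer CSV, inferring fs from inter-sample gaps."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 4:
        raise FormatError("accelerometer CSV needs columns timestamp,x,y,z")
    ts = _parse_timestamps(df.iloc[:, 0])
    xyz = df.iloc[:, 1:4].to_numpy(dtype=float)
    finite = np.isfinite(ts) & np.all(np.isfinite(xyz), axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("read_accel_csv(%s): dropped %d non-finite rows", path, dropped)
        ts, xyz = ts[finite], xyz[finite]
    if len(ts) < 2:
        raise FormatError("accelerometer CSV has fewer than 2 usable rows")
    _check_monotone(ts, "accelerometer CSV")
    dt = np.diff(ts)
    fs_raw = 1.0 / np.median(dt[dt > 0])
    fs = int(_KNOWN_FS[np.argmin(np.abs(_KNOWN_FS - fs_raw))])
    if abs(fs_raw - fs) / fs > 0.10:
        raise FormatError(
            f"inferred sampling rate {fs_raw:.2f} Hz not within 10% of 25/50/100"
        )
    return SensorRecording(t0=float(ts[0]), fs=fs, samples=xyz)


def write_accel_csv(path: str | Path, rec: SensorRecording) -> None:
    pd.DataFrame(
        {
            "timestamp": rec.timestamps,
            "x": rec.samples[:, 0],
            "y": rec.samples[:, 1],
            "z": rec.samples[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.17g")  # exact float round-trip


def read_hr_csv(path: str | Path) -> HeartRateSeries:
    """Read a ``timestamp,bpm`` CSV. Implausible bpm values (outside the open
    interval (20, 250)) are retained but flagged invalid."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError("heart-rate CSV needs columns timestamp,bpm")
    ts = _parse_timestamps(df.iloc[:, 0])
    bpm = df.iloc[:, 1].to_numpy(dtype=float)
    finite = np.isfinite(ts)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("read_hr_csv(%s): dropped %d rows without timestamps", path, dropped)
        ts, bpm = ts[finite], bpm[finite]
    if len(ts) == 0:
        raise FormatError("heart-rate CSV has no usable rows")
    _check_monotone(ts, "heart-rate CSV")
    validity = np.isfinite(bpm) & (bpm > 20) & (bpm < 250)
    return HeartRateSeries(timestamps=ts, bpm=bpm, validity=validity)


def write_hr_csv(path: str | Path, hr: HeartRateSeries) -> None:
    pd.DataFrame({"timestamp": hr.timestamps, "bpm": hr.bpm}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read a hypnogram CSV with its 2-line lights-window metadata header."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4 or not lines[0].startswith("lights_off=") or not lines[
        1
    ].startswith("lights_on="):
        raise FormatError(
            "hypnogram CSV must start with lights_off=/lights_on= metadata lines"
        )
    lights_off = float(lines[0].split("=", 1)[1])
    lights_on = float(lines[1].split("=", 1)[1])
    if lines[2].strip() != "epoch_index,stage":
        raise FormatError("expected header 'epoch_index,stage'")
    labels = []
    for ln in lines[3:]:
        if not ln.strip():
            continue
        _, stage = ln.split(",", 1)
        stage = stage.strip()
        if stage not in STAGES:
            raise FormatError(f"unknown stage token {stage!r}")
        labels.append(stage)
    if not labels:
        raise FormatError("hypnogram CSV has no epochs")
    epoch_len = (lights_on - lights_off) / len(labels)
    if epoch_len <= 0:
        raise FormatError("lights window must be positive")
    try:
        return Hypnogram(
            epoch_labels=np.array(labels, dtype=object),
            epoch_len_s=epoch_len,
            lights_off=lights_off,
            lights_on=lights_on,
            participant_id=path.stem,
        )
    except ValidationError as exc:  # pragma: no cover - defensive
        raise FormatError(str(exc)) from exc


def write_hypnogram_csv(path: str | Path, hyp: Hypnogram) -> None:
    with open(path, "w") as fh:
        fh.write(f"lights_off={hyp.lights_off!r}\n")
        fh.write(f"lights_on={hyp.lights_on!r}\n")
        fh.write("epoch_index,stage\n")
        for i, s in enumerate(hyp.epoch_labels):
            fh.write(f"{i},{s}\n")
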