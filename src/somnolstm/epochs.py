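"""Epoch-grid synchronisation of accelerometer, HR and hypnogram streams.

Epochs are 0-based, half-open intervals
``[lights_off + i*epoch_len_s, lights_off + (i+1)*epoch_len_s)``: a sample
landing exactly on a boundary belongs to the *later* epoch. A trailing
partial epoch is discarded. An epoch is valid when it holds exactly
``fs * epoch_len_s`` accelerometer samples and at least 80% valid HR seconds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, IngestionError, ValidationError
from .simulate import HeartRateSeries, Hypnogram, SensorRecording

logger = logging.getLogger(__name__)

#: Minimum fraction of valid interpolated HR seconds for an epoch to count.
HR_VALID_FRACTION = 0.80
#: HR gaps longer than this (seconds) are not interpolated across.
HR_MAX_GAP_S = 60.0


@dataclass(frozen=True)
class EpochGrid:
    """Shared 30-s epoch grid between lights-off and lights-on."""

    lights_off: float
    lights_on: float
    epoch_len_s: float = 30.0

    def __post_init__(self):
        if self.epoch_len_s <= 0:
            raise ValidationError("epoch_len_s must be positive")
        if self.lights_on <= self.lights_off:
            raise ValidationError("lights_on must exceed lights_off")

    @property
    def n_epochs(self) -> int:
        return int(math.floor((self.lights_on - self.lights_off) / self.epoch_len_s))

    def epoch_start(self, i: int) -> float:
        return self.lights_off + i * self.epoch_len_s

    @property
    def duration_s(self) -> int:
        return int(round(self.n_epochs * self.epoch_len_s))


@dataclass
class AlignedNight:
    """Epoch-synchronised accelerometer/HR/label streams for one night.

    ``accel_epochs`` is (n_epochs, fs*epoch_len_s, 3) with NaN padding where
    an epoch is incomplete; ``hr_epochs`` is (n_epochs, epoch_len_s) 1-Hz bpm
    with ``hr_valid`` flags; ``epoch_valid`` marks epochs usable downstream.
    """

    grid: EpochGrid
    fs: int
    accel_epochs: np.ndarray
    hr_epochs: np.ndarray
    hr_valid: np.ndarray
    labels: np.ndarray
    epoch_valid: np.ndarray
    participant_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.grid.n_epochs

    @property
    def n_valid(self) -> int:
        return int(self.epoch_valid.sum())


def resample_hr_1hz(hr: HeartRateSeries, grid: EpochGrid) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate HR onto the grid's integer seconds.

    Returns ``(bpm, valid)`` of length ``grid.duration_s``. Seconds outside
    the sampled range or inside gaps longer than :data:`HR_MAX_GAP_S` are
    marked invalid (bpm set to NaN).
    """
    ts = hr.timestamps[hr.validity]
    vals = hr.bpm[hr.validity]
    inside = (ts >= grid.lights_off) & (ts < grid.lights_on)
    if int(inside.sum()) < 2:
        raise IngestionError("fewer than 2 valid HR samples inside lights window")
    t = grid.lights_off + np.arange(grid.duration_s, dtype=float)
    out = np.interp(t, ts, vals)
    valid = (t >= ts[0]) & (t <= ts[-1])
    # invalidate seconds bridged across long gaps
    idx = np.searchsorted(ts, t, side="right")
    interior = (idx > 0) & (idx < len(ts))
    gap = np.zeros_like(t)
    gap[interior] = ts[idx[interior]] - ts[idx[interior] - 1]
    valid &= ~(interior & (gap > HR_MAX_GAP_S))
    out[~valid] = np.nan
    return out, valid


def align_streams(
    accel: SensorRecording, hr: HeartRateSeries, hypnogram: Hypnogram
) -> AlignedNight:
    """Slice all three streams onto the hypnogram's epoch grid."""
    grid = EpochGrid(hypnogram.lights_off, hypnogram.lights_on, hypnogram.epoch_len_s)
    n_ep = grid.n_epochs
    spe = int(round(accel.fs * grid.epoch_len_s))
    sec = int(round(grid.epoch_len_s))

    ts = accel.timestamps
    if ts[0] >= grid.lights_on or ts[-1] < grid.lights_off:
        raise AlignmentError("accelerometer stream does not overlap lights window")

    boundaries = grid.lights_off + grid.epoch_len_s * np.arange(n_ep + 1)
    cuts = np.searchsorted(ts, boundaries, side="left")  # half-open ownership

    accel_epochs = np.full((n_ep, spe, 3), np.nan)
    epoch_complete = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        lo, hi = cuts[i], cuts[i + 1]
        k = hi - lo
        if k > spe:  # oversampled epoch cannot be trusted either
            k = 0
        elif k > 0:
            accel_epochs[i, :k] = accel.samples[lo:hi]
        epoch_complete[i] = k == spe

    bpm_1hz, hr_ok = resample_hr_1hz(hr, grid)
    hr_epochs = bpm_1hz[: n_ep * sec].reshape(n_ep, sec)
    hr_valid = hr_ok[: n_ep * sec].reshape(n_ep, sec)
    hr_frac = hr_valid.mean(axis=1)

    epoch_valid = epoch_complete & (hr_frac >= HR_VALID_FRACTION)
    if not np.any(cuts[1:] > cuts[:-1]):
        raise AlignmentError("zero epochs overlap the accelerometer stream")
    n_invalid = int((~epoch_valid).sum())
    if n_invalid:
        logger.info(
            "align_streams(%s): %d of %d epochs invalid",
            hypnogram.participant_id,
            n_invalid,
            n_ep,
        )
    return AlignedNight(
        grid=grid,
        fs=accel.fs,
        accel_epochs=accel_epochs,
        hr_epochs=hr_epochs,
        hr_valid=hr_valid,
        labels=np.asarray(hypnogram.epoch_labels[:n_ep], dtype=object),
        epoch_valid=epoch_valid,
        participant_id=hypnogram.participant_id,
    )
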