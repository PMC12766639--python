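"""Night-level sleep summary measures derived from epoch label sequences.

All durations are reported in minutes: TST = sleep epochs x epoch_len/60;
SE = 100*TST/TIB; SOL = wake epochs before the first sleep epoch x
epoch_len/60; WASO = wake epochs after the first sleep epoch x epoch_len/60;
stage minutes are the analogous sums for light/deep/REM labels. For every
binary sequence TST + SOL + WASO = TIB, and for every staged sequence
light + deep + rem = TST. A night with no sleep epoch has SOL = TIB (the
limit of the definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .simulate import STAGES

BINARY_CLASSES = ("wake", "sleep")
STAGE4_CLASSES = ("wake", "light", "deep", "rem")

_BINARY_MAP = {"W": "wake", "N1": "sleep", "N2": "sleep", "N3": "sleep",
               "REM": "sleep", "wake": "wake", "sleep": "sleep",
               "light": "sleep", "deep": "sleep", "rem": "sleep"}
_STAGE4_MAP = {"W": "wake", "N1": "light", "N2": "light", "N3": "deep",
               "REM": "rem", "wake": "wake", "light": "light", "deep": "deep",
               "rem": "rem"}


def collapse_stages(labels, scheme: str = "binary") -> np.ndarray:
    """Collapse 5-stage codes: binary (wake/sleep) or stage4
    (wake / light=N1-N2 / deep=N3 / rem). Idempotent on collapsed input."""
    if scheme == "binary":
        mapping = _BINARY_MAP
    elif scheme == "stage4":
        mapping = _STAGE4_MAP
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    labels = np.asarray(labels, dtype=object)
    try:
        return np.array([mapping[l] for l in labels], dtype=object)
    except KeyError as exc:
        raise ValidationError(f"unknown stage code {exc.args[0]!r}") from exc


@dataclass
class SleepSummary:
    """TST/SE/SOL/WASO (+ stage minutes for staged input) for one night."""

    TIB: float  # minutes
    TST: float
    SE: float  # percent
    SOL: float
    WASO: float
    light: float | None = None
    deep: float | None = None
    rem: float | None = None
    epoch_len_s: float = 30.0
    participant_id: str = ""

    def as_dict(self) -> dict[str, float]:
        out = {"TST": self.TST, "SE": self.SE, "SOL": self.SOL, "WASO": self.WASO}
        if self.light is not None:
            out.update({"light": self.light, "deep": self.deep, "rem": self.rem})
        return out


def derive_summary(
    labels, epoch_len_s: float = 30.0, participant_id: str = ""
) -> SleepSummary:
    """Sleep summary of a collapsed (binary or stage4) label sequence."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValidationError("label sequence must be non-empty")
    known = set(BINARY_CLASSES) | set(STAGE4_CLASSES)
    bad = set(labels) - known
    if bad:
        if set(labels) <= set(STAGES):
            raise ValidationError(
                "derive_summary expects collapsed labels; apply collapse_stages first"
            )
        raise ValidationError(f"unknown labels: {sorted(bad)}")

    per_epoch_min = epoch_len_s / 60.0
    n = len(labels)
    TIB = n * per_epoch_min
    asleep = labels != "wake"
    TST = float(asleep.sum()) * per_epoch_min
    if not asleep.any():
        summary = SleepSummary(TIB=TIB, TST=0.0, SE=0.0, SOL=TIB, WASO=0.0,
                               epoch_len_s=epoch_len_s,
                               participant_id=participant_id)
    else:
        first = int(np.argmax(asleep))
        SOL = first * per_epoch_min
        WASO = float(np.sum(labels[first:] == "wake")) * per_epoch_min
        summary = SleepSummary(
            TIB=TIB, TST=TST, SE=100.0 * TST / TIB, SOL=SOL, WASO=WASO,
            epoch_len_s=epoch_len_s, participant_id=participant_id,
        )
    if set(labels) & {"light", "deep", "rem"}:  # staged input
        summary.light = float(np.sum(labels == "light")) * per_epoch_min
        summary.deep = float(np.sum(labels == "deep")) * per_epoch_min
        summary.rem = float(np.sum(labels == "rem")) * per_epoch_min
    return summary
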