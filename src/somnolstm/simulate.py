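"""Synthetic overnight cohort simulator.

Generates ground-truth hypnograms (first-order Markov chains over the AASM
stages W/N1/N2/N3/REM in 30-s epochs) together with stage-conditioned raw
tri-axial wrist acceleration and 1-Hz heart rate, so that the full
classification and agreement pipeline can be exercised without any recorded
data.

The signal model, per 30-s epoch of stage ``s``:

* acceleration = persistent unit gravity vector (re-oriented at posture
  changes, which occur only in wake epochs) + i.i.d. Gaussian sensor noise +
  Poisson-timed movement bursts whose rate and amplitude depend on ``s``
  (W >> N1 > REM > N2 > N3). A fraction of wake epochs are "still wake"
  (quiet rest) with strongly suppressed burst rate, which makes single-epoch
  wake detection genuinely hard and rewards models that use night context.
* heart rate = stage mean + a stationary AR(1) fluctuation whose marginal SD
  depends on ``s`` (REM variability above NREM), sampled at 1 Hz.

Every simulated night carries a sidecar event log (bursts, posture changes,
target HR means per epoch) so tests can verify the generator's bookkeeping
without re-deriving events from the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: Default stage-transition matrix (rows/cols ordered as STAGES). Structural
#: zeros enforce plausible architecture: W and N1 cannot jump straight to
#: N3/REM, N3 is entered only from N2, REM only from N2/N3. Its stationary
#: distribution is ~= (0.05 W, 0.10 N1, 0.40 N2, 0.25 N3, 0.20 REM), i.e.
#: about 5% wake, 50% light, 25% deep, 20% REM across a night.
DEFAULT_TRANSITION = np.array(
    [
        [0.850, 0.126, 0.024, 0.000, 0.000],
        [0.010, 0.765, 0.225, 0.000, 0.000],
        [0.005, 0.032, 0.886, 0.050, 0.027],
        [0.002, 0.000, 0.048, 0.920, 0.030],
        [0.020, 0.022, 0.050, 0.000, 0.908],
    ]
)


@dataclass(frozen=True)
class DeviceProfile:
    """Sampling rate and sensor noise of an emulated wrist device."""

    name: str
    fs: int  # Hz
    noise_sd: float  # g

    def __post_init__(self):
        if self.fs not in (25, 50, 100):
            raise ValidationError(f"fs must be one of 25/50/100 Hz, got {self.fs}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


#: Emulated device profiles (sampling rates follow the hardware they mimic).
DEVICE_PROFILES: dict[str, DeviceProfile] = {
    "actigraph": DeviceProfile("actigraph", 100, 0.010),
    "apple": DeviceProfile("apple", 50, 0.012),
    "fitbit": DeviceProfile("fitbit", 50, 0.015),
    "garmin": DeviceProfile("garmin", 25, 0.020),
}


@dataclass(frozen=True)
class StageMovement:
    """Movement-burst parameters for one stage.

    burst_rate
        Expected number of movement bursts per 30-s epoch (Poisson).
    burst_amplitude
        Peak burst acceleration in g.
    still_prob
        Probability that an epoch of this stage is a "still" epoch whose
        burst rate is multiplied by ``still_factor`` (quiet wakefulness).
    """

    burst_rate: float
    burst_amplitude: float
    still_prob: float = 0.0
    still_factor: float = 0.1

    def __post_init__(self):
        if self.burst_rate < 0 or self.burst_amplitude < 0:
            raise ValidationError("burst rate/amplitude must be non-negative")
        if not 0 <= self.still_prob <= 1:
            raise ValidationError("still_prob must lie in [0, 1]")


#: Per-stage movement defaults. Ordering of burst rates: W >> N1 > REM > N2 > N3.
DEFAULT_MOVEMENT: dict[str, StageMovement] = {
    "W": StageMovement(3.0, 0.30, still_prob=0.30, still_factor=0.15),
    "N1": StageMovement(0.8, 0.08),
    "N2": StageMovement(0.15, 0.04),
    "N3": StageMovement(0.05, 0.03),
    "REM": StageMovement(0.40, 0.06),
}


@dataclass(frozen=True)
class StageHeartRate:
    mean: float  # bpm
    sd: float  # marginal SD of the AR(1) fluctuation, bpm

    def __post_init__(self):
        if self.sd < 0:
            raise ValidationError("HR SD must be non-negative")


@dataclass(frozen=True)
class HeartRateParams:
    """Stage-conditional HR model: bpm(t) = mean(stage) + AR(1) noise."""

    stages: dict[str, StageHeartRate]
    ar_coef: float = 0.9

    def __post_init__(self):
        if not 0 <= self.ar_coef < 1:
            raise ValidationError("AR(1) coefficient must lie in [0, 1)")


#: Paediatric overnight HR defaults (bpm); REM variability exceeds NREM.
DEFAULT_HR = HeartRateParams(
    stages={
        "W": StageHeartRate(85.0, 8.0),
        "N1": StageHeartRate(80.0, 5.0),
        "N2": StageHeartRate(75.0, 4.0),
        "N3": StageHeartRate(70.0, 3.0),
        "REM": StageHeartRate(82.0, 7.0),
    },
    ar_coef=0.9,
)

#: Probability that a wake epoch triggers a posture re-orientation.
DEFAULT_REORIENT_PROB = 0.3


@dataclass
class Hypnogram:
    """Per-epoch PSG stage labels over a lights-off -> lights-on window."""

    epoch_labels: np.ndarray  # array of stage codes
    epoch_len_s: float = 30.0
    lights_off: float = 0.0  # epoch-seconds timestamp
    lights_on: float = 0.0
    participant_id: str = "sim"

    def __post_init__(self):
        self.epoch_labels = np.asarray(self.epoch_labels, dtype=object)
        if self.epoch_len_s <= 0:
            raise ValidationError("epoch_len_s must be positive")
        bad = set(self.epoch_labels) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage codes: {sorted(bad)}")
        expected = self.lights_off + len(self.epoch_labels) * self.epoch_len_s
        if self.lights_on == 0.0 and self.lights_off == 0.0:
            self.lights_on = expected
        if abs(self.lights_on - expected) > 1e-6:
            raise ValidationError(
                "lights window does not equal n_epochs * epoch_len_s"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_labels)


@dataclass
class SensorRecording:
    """Raw tri-axial acceleration in g, uniformly sampled at ``fs`` Hz."""

    t0: float
    fs: int
    samples: np.ndarray  # (n, 3)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError("samples must have shape (n, 3)")

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class HeartRateSeries:
    """Timestamped beats-per-minute series with per-sample validity."""

    timestamps: np.ndarray
    bpm: np.ndarray
    validity: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if not (len(self.timestamps) == len(self.bpm) == len(self.validity)):
            raise ValidationError("timestamps/bpm/validity length mismatch")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")


@dataclass
class NightEvents:
    """Sidecar bookkeeping emitted by the generator, one row per epoch."""

    epoch_index: np.ndarray
    stage: np.ndarray
    n_bursts: np.ndarray
    still: np.ndarray
    reoriented: np.ndarray
    hr_mean_target: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch_index": self.epoch_index,
                "stage": self.stage,
                "n_bursts": self.n_bursts,
                "still": self.still,
                "reoriented": self.reoriented,
                "hr_mean_target": self.hr_mean_target,
            }
        )


@dataclass
class CohortNight:
    hypnogram: Hypnogram
    accel: SensorRecording
    hr: HeartRateSeries
    device_profile_name: str
    events: NightEvents


@dataclass
class CohortDataset:
    """One simulated night per subject, plus the master seed that made it."""

    nights: list[CohortNight]
    seed: int

    def __post_init__(self):
        ids = [n.hypnogram.participant_id for n in self.nights]
        if len(set(ids)) != len(ids):
            raise ValidationError("participant_ids must be unique")


def _validate_transition(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (5, 5):
        raise ValidationError("transition matrix must be 5x5")
    if np.any(matrix < 0):
        raise ValidationError("transition probabilities must be non-negative")
    if np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("each transition-matrix row must sum to 1")
    return matrix


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (unit eigenvector)."""
    matrix = _validate_transition(matrix)
    w, v = np.linalg.eig(matrix.T)
    p = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return p / p.sum()


def simulate_hypnogram(
    n_epochs: int,
    transition_matrix: np.ndarray | None = None,
    initial_stage: str = "W",
    seed: int = 0,
    epoch_len_s: float = 30.0,
    lights_off: float = 0.0,
    participant_id: str = "sim",
) -> Hypnogram:
    """Realize a first-order Markov hypnogram of ``n_epochs`` 30-s epochs."""
    if n_epochs < 1:
        raise ValidationError("n_epochs must be >= 1")
    if initial_stage not in _STAGE_INDEX:
        raise ValidationError(f"unknown stage code: {initial_stage!r}")
    matrix = _validate_transition(
        DEFAULT_TRANSITION if transition_matrix is None else transition_matrix
    )
    rng = np.random.default_rng(seed)
    cum = np.cumsum(matrix, axis=1)
    states = np.empty(n_epochs, dtype=np.int64)
    s = _STAGE_INDEX[initial_stage]
    u = rng.random(n_epochs)
    states[0] = s
    for i in range(1, n_epochs):
        s = int(np.searchsorted(cum[s], u[i], side="right"))
        s = min(s, 4)  # guard against u == 1.0 edge
        states[i] = s
    labels = np.array([STAGES[s] for s in states], dtype=object)
    return Hypnogram(
        epoch_labels=labels,
        epoch_len_s=epoch_len_s,
        lights_off=lights_off,
        lights_on=lights_off + n_epochs * epoch_len_s,
        participant_id=participant_id,
    )


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - measure-zero
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def simulate_night(
    hypnogram: Hypnogram,
    device_profile: DeviceProfile | str = "actigraph",
    movement_params: dict[str, StageMovement] | None = None,
    hr_params: HeartRateParams | None = None,
    seed: int = 0,
    reorient_prob: float = DEFAULT_REORIENT_PROB,
) -> tuple[SensorRecording, HeartRateSeries, NightEvents]:
    """Generate raw acceleration and 1-Hz HR conditioned on a hypnogram.

    Returns the accelerometer recording, the heart-rate series and the
    sidecar event log. Sample counts are exactly ``fs * duration`` and
    ``1 * duration``.
    """
    if hypnogram.n_epochs < 1:
        raise ValidationError("hypnogram must be non-empty")
    if isinstance(device_profile, str):
        try:
            device_profile = DEVICE_PROFILES[device_profile]
        except KeyError:
            raise ValidationError(f"unknown device profile {device_profile!r}")
    movement = dict(DEFAULT_MOVEMENT if movement_params is None else movement_params)
    hr_p = DEFAULT_HR if hr_params is None else hr_params
    for s in STAGES:
        if s not in movement:
            raise ValidationError(f"movement_params missing stage {s}")
        if s not in hr_p.stages:
            raise ValidationError(f"hr_params missing stage {s}")

    fs = device_profile.fs
    eps = hypnogram.epoch_len_s
    spe = int(round(fs * eps))  # samples per epoch
    n_ep = hypnogram.n_epochs
    rng = np.random.default_rng(seed)

    accel = np.zeros((n_ep * spe, 3))
    hr_sec = int(round(eps))
    bpm = np.zeros(n_ep * hr_sec)

    gravity = _random_unit_vector(rng)
    phi = hr_p.ar_coef
    x = 0.0  # AR(1) state, continuous across epochs

    n_bursts_log = np.zeros(n_ep, dtype=np.int64)
    still_log = np.zeros(n_ep, dtype=bool)
    reoriented_log = np.zeros(n_ep, dtype=bool)
    hr_mean_log = np.zeros(n_ep)

    t_local = np.arange(spe) / fs
    for i, stage in enumerate(hypnogram.epoch_labels):
        mv = movement[stage]
        # posture changes only while awake
        if stage == "W" and rng.random() < reorient_prob:
            gravity = _random_unit_vector(rng)
            reoriented_log[i] = True
        block = gravity + (
            rng.normal(0.0, device_profile.noise_sd, size=(spe, 3))
            if device_profile.noise_sd > 0
            else 0.0
        )
        if np.isscalar(block) or block.ndim == 1:
            block = np.tile(gravity, (spe, 1))

        still = mv.still_prob > 0 and rng.random() < mv.still_prob
        rate = mv.burst_rate * (mv.still_factor if still else 1.0)
        k = rng.poisson(rate) if rate > 0 else 0
        for _ in range(k):
            dur = rng.uniform(0.25, 1.5)
            n = max(2, int(round(dur * fs)))
            start = rng.integers(0, max(1, spe - n))
            freq = rng.uniform(2.0, 6.0)
            direction = _random_unit_vector(rng)
            tt = t_local[:n]
            envelope = mv.burst_amplitude * np.hanning(n) * np.sin(
                2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi)
            )
            block[start : start + n] += envelope[:, None] * direction
        accel[i * spe : (i + 1) * spe] = block
        n_bursts_log[i] = k
        still_log[i] = still

        shr = hr_p.stages[stage]
        innov_sd = shr.sd * np.sqrt(max(0.0, 1.0 - phi * phi))
        seg = np.empty(hr_sec)
        for j in range(hr_sec):
            x = phi * x + (rng.normal(0.0, innov_sd) if innov_sd > 0 else 0.0)
            seg[j] = shr.mean + x
        bpm[i * hr_sec : (i + 1) * hr_sec] = seg
        hr_mean_log[i] = shr.mean

    rec = SensorRecording(t0=hypnogram.lights_off, fs=fs, samples=accel)
    hr_ts = hypnogram.lights_off + np.arange(n_ep * hr_sec, dtype=float)
    hr = HeartRateSeries(
        timestamps=hr_ts, bpm=bpm, validity=np.ones(len(bpm), dtype=bool)
    )
    events = NightEvents(
        epoch_index=np.arange(n_ep),
        stage=np.asarray(hypnogram.epoch_labels, dtype=object),
        n_bursts=n_bursts_log,
        still=still_log,
        reoriented=reoriented_log,
        hr_mean_target=hr_mean_log,
    )
    return rec, hr, events


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-based per-subject seed derivation (order-independent)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def simulate_cohort(
    n_subjects: int,
    night_len_epochs: int | tuple[int, int] = (900, 1020),
    device_profiles: tuple[str, ...] = ("actigraph",),
    seed: int = 0,
    transition_matrix: np.ndarray | None = None,
    movement_params: dict[str, StageMovement] | None = None,
    hr_params: HeartRateParams | None = None,
) -> CohortDataset:
    """Simulate one night per subject.

    ``night_len_epochs`` is either a fixed epoch count or an inclusive
    (low, high) range sampled per subject. Device profiles are assigned
    round-robin. Per-subject randomness derives deterministically from the
    master seed via :func:`subject_seed`, independent of iteration order.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    if not device_profiles:
        raise ValidationError("device_profiles must be non-empty")
    profiles = [
        DEVICE_PROFILES[p] if isinstance(p, str) else p for p in device_profiles
    ]
    nights = []
    for i in range(n_subjects):
        s_i = subject_seed(seed, i)
        rng = np.random.default_rng(s_i)
        if isinstance(night_len_epochs, int):
            n_ep = night_len_epochs
        else:
            lo, hi = night_len_epochs
            n_ep = int(rng.integers(lo, hi + 1))
        # arbitrary fixed-offset clock: one night per day, ~22:30 lights off
        lights_off = 1_704_000_000.0 + 86400.0 * i + float(rng.integers(-1800, 1801))
        profile = profiles[i % len(profiles)]
        hyp = simulate_hypnogram(
            n_ep,
            transition_matrix=transition_matrix,
            initial_stage="W",
            seed=s_i + 1,
            lights_off=lights_off,
            participant_id=f"S{i:03d}",
        )
        rec, hr, events = simulate_night(
            hyp,
            device_profile=profile,
            movement_params=movement_params,
            hr_params=hr_params,
            seed=s_i + 2,
        )
        nights.append(CohortNight(hyp, rec, hr, profile.name, events))
    return CohortDataset(nights=nights, seed=seed)
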