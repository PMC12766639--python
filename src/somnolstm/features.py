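"""Per-epoch feature extraction.

Two representations are produced from an :class:`~somnolstm.epochs.AlignedNight`:

* a 145-column named feature table (time-domain statistics, averaged STFT
  power components FFT0-FFT14, axis correlations, an activity count and nine
  HR summaries) consumed by the logistic-regression and random-forest
  baselines, and
* per-epoch spectral blocks of 5 channels (x, y, z, magnitude, HR) x 30
  components (FFT0-FFT29) consumed by the local-global LSTM.

Spectral components come from Hann-windowed 1-s segments with 50% overlap;
per-segment magnitude-squared spectra are averaged arithmetically across the
epoch, so component k sits at ~k Hz regardless of the device sampling rate.
The 1-Hz HR stream is degenerate under a 1-s window, so its spectral channel
uses a single 30-s window over the epoch's 30 samples (16 one-sided bins,
zero-padded up to the requested component count). Devices whose sampling
rate supplies fewer one-sided bins than requested are likewise zero-padded,
keeping block shapes device-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import AlignedNight
from .exceptions import ConfigurationError, ValidationError

#: Width of the baseline feature table.
N_FEATURES = 145
#: Spectral components per motion channel in the feature table (FFT0-FFT14).
N_COMPONENTS_TABLE = 15
#: Spectral components per channel in LSTM blocks (FFT0-FFT29).
N_COMPONENTS_LSTM = 30
#: One-sided bins of a 30-sample (30-s, 1-Hz) HR window.
N_HR_BINS = 16

MOTION_CHANNELS = ("x", "y", "z", "mag")
LSTM_CHANNELS = ("x", "y", "z", "mag", "hr")

TIME_FEATURE_NAMES = (
    "mean", "sd", "min", "max", "range", "median", "q25", "q75", "iqr",
    "skew", "kurt", "mad", "rms", "zcr", "ac1s", "domfreq", "dompower",
    "specent",
)

HR_FEATURE_NAMES = (
    "hr_mean", "hr_sd", "hr_min", "hr_max", "hr_range", "hr_slope",
    "hr_delta", "hr_rmssd", "hr_valid_frac",
)

#: HR summaries require at least this fraction of valid seconds in the epoch.
HR_FEATURE_MIN_VALID = 0.5


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def magnitude(samples: np.ndarray) -> np.ndarray:
    """Euclidean norm sqrt(x^2+y^2+z^2) of an (n, 3) block, per sample."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("empty sample block")
    return np.sqrt(np.sum(np.square(samples), axis=-1))


def stft_power_features(
    series: np.ndarray, fs: float, K: int, window_s: float = 1.0
) -> np.ndarray:
    """Averaged short-time power spectrum of one channel, first ``K`` bins.

    Hann-windowed segments of ``window_s`` seconds with 50% overlap (hop =
    ``win - win//2`` samples); per-segment magnitude-squared one-sided DFT;
    arithmetic mean across segments. FFT0 is the DC bin.

    Each segment is demeaned before windowing and its mean is carried in
    FFT0 as ``(mean * sum(hann))^2``: the Hann window's own cosine component
    would otherwise leak the (gravity-dominated) DC into bin 1 and swamp the
    low-frequency movement bins. A constant series therefore has FFT0 > 0
    and every higher component exactly 0.
    """
    x = np.asarray(series, dtype=float)
    win = int(round(fs * window_s))
    if win < 1 or win > len(x):
        raise ValidationError("window longer than series")
    n_bins = win // 2 + 1
    if K > n_bins:
        raise ValidationError(
            f"K={K} exceeds the {n_bins} one-sided bins of a "
            f"{window_s:g}-s window at {fs:g} Hz"
        )
    return _stft_power_block(x[None, :], win, K)[0]


def _hann_periodic(win: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(win) / win)


def _stft_power_block(X: np.ndarray, win: int, K: int) -> np.ndarray:
    """Vectorised averaged STFT power over epochs: X (n, L) -> (n, K)."""
    hop = win - win // 2
    w = _hann_periodic(win)
    segs = np.lib.stride_tricks.sliding_window_view(X, win, axis=1)[:, ::hop, :]
    means = segs.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft((segs - means) * w, axis=-1)
    power = spec.real**2 + spec.imag**2
    power[..., 0] = (means[..., 0] * w.sum()) ** 2  # DC carried explicitly
    return power.mean(axis=1)[:, :K]


def n_segments(fs: int, epoch_len_s: float = 30.0, window_s: float = 1.0) -> int:
    """Number of 50%-overlapped windows per epoch (59 for a 30-s epoch at
    even fs; one fewer pair fits when fs is odd)."""
    win = int(round(fs * window_s))
    hop = win - win // 2
    return 1 + (int(round(fs * epoch_len_s)) - win) // hop


def time_features(series: np.ndarray, fs: float) -> dict[str, float]:
    """The 18 per-channel time/summary statistics of one epoch.

    Skewness and excess kurtosis of a constant series are defined as 0; the
    zero-crossing rate counts sign changes of the mean-centred signal per
    second; ``ac1s`` is the Pearson correlation at a 1-s lag; dominant
    frequency/power and spectral entropy come from the full-epoch
    periodogram ``|rfft(x)|^2 / n`` over non-DC bins (entropy normalised to
    [0, 1]).
    """
    out = _time_features_block(np.asarray(series, dtype=float)[None, :], fs)
    return {name: float(out[name][0]) for name in TIME_FEATURE_NAMES}


def _time_features_block(X: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n == 0:
        raise ValidationError("empty series")
    duration = n / fs
    mean = X.mean(axis=1)
    dev = X - mean[:, None]
    m2 = np.mean(dev**2, axis=1)
    sd = np.sqrt(m2)
    mn, mx = X.min(axis=1), X.max(axis=1)
    median = np.median(X, axis=1)
    q25 = np.quantile(X, 0.25, axis=1)
    q75 = np.quantile(X, 0.75, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m3 = np.mean(dev**3, axis=1)
        m4 = np.mean(dev**4, axis=1)
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1) ** 2 - 3.0, 0.0)
    mad = np.median(np.abs(X - median[:, None]), axis=1)
    rms = np.sqrt(np.mean(X**2, axis=1))
    zcr = np.sum(dev[:, 1:] * dev[:, :-1] < 0, axis=1) / duration

    lag = int(round(fs))
    if 0 < lag < n:
        a, b = X[:, :-lag], X[:, lag:]
        am, bm = a.mean(axis=1), b.mean(axis=1)
        cov = np.mean((a - am[:, None]) * (b - bm[:, None]), axis=1)
        va = np.mean((a - am[:, None]) ** 2, axis=1)
        vb = np.mean((b - bm[:, None]) ** 2, axis=1)
        denom = np.sqrt(va * vb)
        ac1s = np.where(denom > 0, cov / np.where(denom > 0, denom, 1), 0.0)
    else:
        ac1s = np.zeros(len(X))

    spec = np.fft.rfft(X, axis=1)
    power = (spec.real**2 + spec.imag**2) / n
    pnz = power[:, 1:]
    if pnz.shape[1] == 0:
        domfreq = dompower = specent = np.zeros(len(X))
    else:
        tot = pnz.sum(axis=1)
        # relative floor: fp noise of an exact-DC series must not register
        live = tot > 1e-12 * power.sum(axis=1) + 1e-300
        k = np.argmax(pnz, axis=1)
        dompower = np.where(live, pnz[np.arange(len(X)), k], 0.0)
        domfreq = np.where(live, (k + 1) * fs / n, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = pnz / np.where(tot > 0, tot, 1)[:, None]
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            ent = -plogp.sum(axis=1)
        norm = np.log(pnz.shape[1]) if pnz.shape[1] > 1 else 1.0
        specent = np.where(live, ent / norm, 0.0)

    return {
        "mean": mean, "sd": sd, "min": mn, "max": mx, "range": mx - mn,
        "median": median, "q25": q25, "q75": q75, "iqr": q75 - q25,
        "skew": skew, "kurt": kurt, "mad": mad, "rms": rms, "zcr": zcr,
        "ac1s": ac1s, "domfreq": domfreq, "dompower": dompower,
        "specent": specent,
    }


def hr_features(
    hr_1hz: np.ndarray, valid: np.ndarray | None = None
) -> dict[str, float]:
    """Nine HR summaries of a 30-s (30-sample) 1-Hz block.

    Invalid seconds are excluded; if fewer than half the seconds are valid
    every summary is returned as NaN for downstream imputation.
    """
    x = np.asarray(hr_1hz, dtype=float)
    if len(x) != 30:
        raise ValidationError("HR block must hold 30 one-second samples")
    v = np.isfinite(x) if valid is None else (np.asarray(valid, bool) & np.isfinite(x))
    out = _hr_features_block(x[None, :], v[None, :])
    return {name: float(out[name][0]) for name in HR_FEATURE_NAMES}


def _hr_features_block(H: np.ndarray, V: np.ndarray) -> dict[str, np.ndarray]:
    n_ep, sec = H.shape
    t = np.arange(sec, dtype=float)
    frac = V.mean(axis=1)
    enough = frac >= HR_FEATURE_MIN_VALID

    Hm = np.where(V, H, np.nan)
    with np.errstate(invalid="ignore"):
        cnt = V.sum(axis=1)
        mean = np.where(V, H, 0.0).sum(axis=1) / np.maximum(cnt, 1)
        mean = np.where(enough, mean, np.nan)
        dev = Hm - mean[:, None]
        sd = np.sqrt(np.nansum(np.square(dev), axis=1) / np.maximum(cnt, 1))
        mn = np.nanmin(np.where(enough[:, None], Hm, np.inf), axis=1)
        mx = np.nanmax(np.where(enough[:, None], Hm, -np.inf), axis=1)

        tm = np.where(V, t, np.nan)
        tmean = np.nansum(tm, axis=1) / np.maximum(cnt, 1)
        tdev = np.where(V, t - tmean[:, None], 0.0)
        num = np.nansum(tdev * np.nan_to_num(dev), axis=1)
        den = np.nansum(tdev**2, axis=1)
        slope = np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)

    first = np.full(n_ep, np.nan)
    last = np.full(n_ep, np.nan)
    rows, cols = np.nonzero(V)
    if len(rows):
        first_idx = np.full(n_ep, -1)
        last_idx = np.full(n_ep, -1)
        # first occurrence wins going forward, last going backward
        for r, c in zip(rows, cols):
            if first_idx[r] < 0:
                first_idx[r] = c
            last_idx[r] = c
        has = first_idx >= 0
        first[has] = H[has, first_idx[has]]
        last[has] = H[has, last_idx[has]]

    pair = V[:, 1:] & V[:, :-1]
    d = np.where(pair, np.diff(H, axis=1), 0.0)
    npair = pair.sum(axis=1)
    rmssd = np.where(
        npair > 0, np.sqrt(np.sum(d**2, axis=1) / np.maximum(npair, 1)), np.nan
    )

    nanv = np.full(n_ep, np.nan)
    def gate(a):
        return np.where(enough, a, nanv)

    return {
        "hr_mean": gate(mean), "hr_sd": gate(sd), "hr_min": gate(mn),
        "hr_max": gate(mx), "hr_range": gate(mx - mn), "hr_slope": gate(slope),
        "hr_delta": gate(last - first), "hr_rmssd": gate(rmssd),
        "hr_valid_frac": gate(frac),
    }


# ---------------------------------------------------------------------------
# feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    channel: str
    definition: str


@dataclass
class FeatureRegistry:
    """Ordered, versioned list of the 145 feature definitions."""

    entries: list[FeatureSpec]
    version: str = "1"

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigurationError("feature names must be unique")
        if len(self.entries) != N_FEATURES:
            raise ConfigurationError(
                f"registry must hold exactly {N_FEATURES} entries, "
                f"got {len(self.entries)}"
            )

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def hr_names(self) -> list[str]:
        return [e.name for e in self.entries if e.channel == "hr"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.channel, e.definition) for e in self.entries],
            columns=["name", "channel", "definition"],
        )


def default_registry() -> FeatureRegistry:
    """The default 145-feature composition.

    18 time statistics x 4 motion channels (72) + FFT0-FFT14 x 4 motion
    channels (60) + 3 axis-pair correlations + 1 activity count + 9 HR
    summaries = 145.
    """
    entries: list[FeatureSpec] = []
    for ch in MOTION_CHANNELS:
        for f in TIME_FEATURE_NAMES:
            entries.append(FeatureSpec(f"{ch}_{f}", ch, f"time-domain {f}"))
    for ch in MOTION_CHANNELS:
        for k in range(N_COMPONENTS_TABLE):
            entries.append(
                FeatureSpec(f"{ch}_fft{k}", ch, "averaged STFT power, ~%d Hz" % k)
            )
    for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
        entries.append(FeatureSpec(f"corr_{a}{b}", f"{a}{b}", "axis correlation"))
    entries.append(
        FeatureSpec("activity_count", "mag", "sum of |magnitude - 1 g| over samples")
    )
    for name in HR_FEATURE_NAMES:
        entries.append(FeatureSpec(name, "hr", name.replace("hr_", "HR ")))
    return FeatureRegistry(entries=entries)


# ---------------------------------------------------------------------------
# night-level builders
# ---------------------------------------------------------------------------

def _motion_channels(accel_block: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "x": accel_block[:, :, 0],
        "y": accel_block[:, :, 1],
        "z": accel_block[:, :, 2],
        "mag": magnitude(accel_block),
    }


def _padded_stft(X: np.ndarray, fs: int, K: int, window_s: float = 1.0) -> np.ndarray:
    """Averaged STFT power, zero-padded on the right up to K components."""
    win = int(round(fs * window_s))
    avail = min(K, win // 2 + 1)
    out = np.zeros((X.shape[0], K))
    out[:, :avail] = _stft_power_block(X, win, avail)
    return out


def _corr_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    da = a - a.mean(axis=1, keepdims=True)
    db = b - b.mean(axis=1, keepdims=True)
    num = np.sum(da * db, axis=1)
    den = np.sqrt(np.sum(da**2, axis=1) * np.sum(db**2, axis=1))
    return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)


def build_feature_table(
    night: AlignedNight,
    registry: FeatureRegistry | None = None,
    include_hr: bool = True,
) -> pd.DataFrame:
    """The 145-column per-epoch feature table of one night (valid epochs only).

    With ``include_hr=False`` the nine HR columns are zeroed (column count is
    preserved) to realise the no-HR model variants. Missing values (e.g. HR
    summaries of low-coverage epochs) are left as NaN for leakage-free,
    training-fold median imputation downstream.
    """
    reg = default_registry() if registry is None else registry
    if len(reg.entries) != N_FEATURES:  # pragma: no cover - registry enforces
        raise ConfigurationError("registry must hold 145 entries")
    v = night.epoch_valid
    accel = night.accel_epochs[v]
    hr = night.hr_epochs[v]
    hr_ok = night.hr_valid[v] & np.isfinite(hr)

    cols: dict[str, np.ndarray] = {}
    chans = _motion_channels(accel)
    for ch in MOTION_CHANNELS:
        tf = _time_features_block(chans[ch], night.fs)
        for f in TIME_FEATURE_NAMES:
            cols[f"{ch}_{f}"] = tf[f]
    for ch in MOTION_CHANNELS:
        fft = _padded_stft(chans[ch], night.fs, N_COMPONENTS_TABLE)
        for k in range(N_COMPONENTS_TABLE):
            cols[f"{ch}_fft{k}"] = fft[:, k]
    cols["corr_xy"] = _corr_pair(chans["x"], chans["y"])
    cols["corr_xz"] = _corr_pair(chans["x"], chans["z"])
    cols["corr_yz"] = _corr_pair(chans["y"], chans["z"])
    cols["activity_count"] = np.sum(np.abs(chans["mag"] - 1.0), axis=1)

    hf = _hr_features_block(np.nan_to_num(hr), hr_ok)
    for name in HR_FEATURE_NAMES:
        cols[name] = np.zeros(int(v.sum())) if not include_hr else hf[name]

    df = pd.DataFrame({name: cols[name] for name in reg.names})
    df.insert(0, "participant_id", night.participant_id)
    df.insert(1, "epoch_index", np.nonzero(v)[0])
    df.insert(2, "label", night.labels[v])
    return df


@dataclass
class LstmInput:
    """Per-night spectral sequence: blocks of (5 channels x K components)."""

    participant_id: str
    X: np.ndarray  # (n_valid_epochs, 5, K)
    labels: np.ndarray  # (n_valid_epochs,) raw stage codes
    epoch_index: np.ndarray
    K: int = N_COMPONENTS_LSTM

    def __post_init__(self):
        if self.X.ndim != 3 or self.X.shape[1] != len(LSTM_CHANNELS):
            raise ValidationError("LstmInput blocks must be (n, 5, K)")
        if self.X.shape[2] != self.K:
            raise ValidationError("block width differs from K")
        if len(self.labels) != len(self.X):
            raise ValidationError("labels/blocks length mismatch")


@dataclass
class FeatureDataset:
    """Stacked per-epoch feature tables of many nights."""

    df: pd.DataFrame

    def __post_init__(self):
        for col in ("participant_id", "epoch_index", "label"):
            if col not in self.df.columns:
                raise ValidationError(f"feature table lacks column {col!r}")

    @property
    def feature_cols(self) -> list[str]:
        return [c for c in self.df.columns
                if c not in ("participant_id", "epoch_index", "label")]

    @property
    def participants(self) -> list[str]:
        return sorted(self.df["participant_id"].unique().tolist())

    def subset(self, ids) -> "FeatureDataset":
        ids = set(ids)
        return FeatureDataset(
            self.df[self.df["participant_id"].isin(ids)].reset_index(drop=True)
        )


@dataclass
class SequenceDataset:
    """Per-night LSTM spectral sequences of many nights."""

    nights: list

    @property
    def participants(self) -> list[str]:
        return sorted(n.participant_id for n in self.nights)

    def subset(self, ids) -> "SequenceDataset":
        ids = set(ids)
        return SequenceDataset([n for n in self.nights if n.participant_id in ids])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([n.labels for n in self.nights])


def build_lstm_input(
    night: AlignedNight, K: int = N_COMPONENTS_LSTM, include_hr: bool = True
) -> LstmInput:
    """Spectral sequence input for the local-global LSTM.

    Motion channels use 1-s windows (bins above the device's one-sided bin
    count are zero). The HR channel uses one 30-s window over the epoch's
    1-Hz samples (16 bins, zero-padded); invalid seconds are filled with the
    epoch's valid-second mean first. ``include_hr=False`` zeroes the HR
    channel.
    """
    v = night.epoch_valid
    accel = night.accel_epochs[v]
    chans = _motion_channels(accel)
    n = int(v.sum())
    X = np.zeros((n, len(LSTM_CHANNELS), K))
    for c, ch in enumerate(MOTION_CHANNELS):
        X[:, c, :] = _padded_stft(chans[ch], night.fs, K)
    if include_hr and n:
        hr = night.hr_epochs[v].copy()
        ok = night.hr_valid[v] & np.isfinite(hr)
        frac = ok.mean(axis=1)
        fill = np.where(ok.any(axis=1), np.nansum(np.where(ok, hr, 0), axis=1)
                        / np.maximum(ok.sum(axis=1), 1), 0.0)
        hr = np.where(ok, hr, fill[:, None])
        hr[frac < HR_FEATURE_MIN_VALID] = 0.0  # too gappy: no spectral content
        sec = hr.shape[1]
        avail = min(K, sec // 2 + 1)
        X[:, 4, :avail] = _stft_power_block(hr, sec, avail)
    return LstmInput(
        participant_id=night.participant_id,
        X=X,
        labels=night.labels[v],
        epoch_index=np.nonzero(v)[0],
        K=K,
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def extract_night(cohort_night, registry: FeatureRegistry | None = None,
                  include_hr: bool = True) -> tuple[pd.DataFrame, LstmInput]:
    """Align one simulated night and build both epoch representations."""
    from .epochs import align_streams

    aligned = align_streams(
        cohort_night.accel, cohort_night.hr, cohort_night.hypnogram
    )
    table = build_feature_table(aligned, registry=registry, include_hr=include_hr)
    seq = build_lstm_input(aligned, include_hr=True)  # HR channel zeroed at model time
    return table, seq


def extract_cohort(cohort, registry: FeatureRegistry | None = None
                   ) -> tuple[FeatureDataset, SequenceDataset]:
    """Feature table + spectral sequences for every night of a cohort.

    HR information is always extracted here; the no-HR model variants zero
    the HR columns/channel at training and prediction time, which keeps one
    extraction pass sufficient for both variants.
    """
    tables, seqs = [], []
    for night in cohort.nights:
        t, s = extract_night(night, registry=registry, include_hr=True)
        tables.append(t)
        seqs.append(s)
    return (
        FeatureDataset(pd.concat(tables, ignore_index=True)),
        SequenceDataset(seqs),
    )
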