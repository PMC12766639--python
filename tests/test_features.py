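"""Feature extraction against independent brute-force oracles."""

import math

import numpy as np
import pytest

from somnolstm.exceptions import ValidationError
from somnolstm.features import (
    HR_FEATURE_NAMES,
    N_COMPONENTS_LSTM,
    N_COMPONENTS_TABLE,
    N_FEATURES,
    TIME_FEATURE_NAMES,
    build_feature_table,
    build_lstm_input,
    default_registry,
    hr_features,
    magnitude,
    n_segments,
    stft_power_features,
    time_features,
)


# ---------------------------------------------------------------------------
# brute-force oracles (single-pass, loop-based, independent of the package)
# ---------------------------------------------------------------------------

def oracle_stft(series, fs, K, window_s=1.0):
    win = int(round(fs * window_s))
    hop = win - win // 2
    w = np.array([0.5 - 0.5 * math.cos(2 * math.pi * i / win) for i in range(win)])
    spectra = []
    start = 0
    while start + win <= len(series):
        seg = np.asarray(series[start : start + win], dtype=float)
        m = seg.mean()
        spec = np.fft.rfft((seg - m) * w)
        p = np.abs(spec) ** 2
        p[0] = (m * w.sum()) ** 2
        spectra.append(p)
        start += hop
    return np.mean(spectra, axis=0)[:K]


def oracle_time_features(x, fs):
    x = np.asarray(x, dtype=float)
    n = len(x)
    mu = sum(x) / n
    dev = x - mu
    m2 = sum(dev**2) / n
    sd = math.sqrt(m2)
    out = {
        "mean": mu, "sd": sd, "min": min(x), "max": max(x),
        "range": max(x) - min(x), "median": float(np.median(x)),
        "q25": float(np.quantile(x, 0.25)), "q75": float(np.quantile(x, 0.75)),
    }
    out["iqr"] = out["q75"] - out["q25"]
    out["skew"] = (sum(dev**3) / n) / m2**1.5 if m2 > 0 else 0.0
    out["kurt"] = (sum(dev**4) / n) / m2**2 - 3.0 if m2 > 0 else 0.0
    med = out["median"]
    out["mad"] = float(np.median([abs(v - med) for v in x]))
    out["rms"] = math.sqrt(sum(x**2) / n)
    out["zcr"] = sum(
        1 for i in range(1, n) if dev[i - 1] * dev[i] < 0
    ) / (n / fs)
    lag = int(round(fs))
    if 0 < lag < n:
        a, b = x[:-lag], x[lag:]
        am, bm = np.mean(a), np.mean(b)
        cov = np.mean((a - am) * (b - bm))
        den = math.sqrt(np.mean((a - am) ** 2) * np.mean((b - bm) ** 2))
        out["ac1s"] = cov / den if den > 0 else 0.0
    else:
        out["ac1s"] = 0.0
    power = np.abs(np.fft.rfft(x)) ** 2 / n
    pnz = power[1:]
    if pnz.sum() > 1e-12 * power.sum() + 1e-300:
        k = int(np.argmax(pnz))
        out["domfreq"] = (k + 1) * fs / n
        out["dompower"] = float(pnz[k])
        p = pnz / pnz.sum()
        ent = -sum(v * math.log(v) for v in p if v > 0)
        out["specent"] = ent / math.log(len(pnz)) if len(pnz) > 1 else ent
    else:
        out["domfreq"] = out["dompower"] = out["specent"] = 0.0
    return out


def oracle_hr_features(block, valid):
    xs = [(t, v) for t, (v, ok) in enumerate(zip(block, valid)) if ok]
    frac = len(xs) / len(block)
    if frac < 0.5:
        return {k: float("nan") for k in HR_FEATURE_NAMES}
    ts = np.array([t for t, _ in xs], dtype=float)
    vs = np.array([v for _, v in xs], dtype=float)
    mu = vs.mean()
    slope = float(np.polyfit(ts, vs, 1)[0]) if len(set(ts)) > 1 else 0.0
    diffs = [
        block[i] - block[i - 1]
        for i in range(1, len(block))
        if valid[i] and valid[i - 1]
    ]
    rmssd = math.sqrt(np.mean(np.square(diffs))) if diffs else float("nan")
    return {
        "hr_mean": mu, "hr_sd": float(vs.std()), "hr_min": vs.min(),
        "hr_max": vs.max(), "hr_range": vs.max() - vs.min(),
        "hr_slope": slope, "hr_delta": vs[-1] - vs[0], "hr_rmssd": rmssd,
        "hr_valid_frac": frac,
    }


# ---------------------------------------------------------------------------

class TestMagnitude:
    def test_unit_vectors(self):
        assert magnitude(np.array([[1.0, 0.0, 0.0]]))[0] == 1.0
        assert magnitude(np.array([[3.0, 4.0, 0.0]]))[0] == 5.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(100, 3))
        expected = [math.sqrt(x * x + y * y + z * z) for x, y, z in block]
        assert np.allclose(magnitude(block), expected, rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            magnitude(np.empty((0, 3)))


class TestStft:
    def test_constant_series_is_dc_only(self):
        out = stft_power_features(np.full(1500, 3.7), fs=50, K=15)
        assert out[0] > 0
        assert np.all(np.abs(out[1:]) < 1e-9)

    def test_sinusoid_peaks_at_its_bin(self):
        fs = 25
        t = np.arange(fs * 30) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        out = stft_power_features(x, fs=fs, K=13)
        assert int(np.argmax(out[1:])) + 1 == 5  # 1-s windows: bin k ~ k Hz

    def test_segment_count_convention(self):
        assert n_segments(50) == 59
        assert n_segments(100) == 59
        assert n_segments(25) == 56  # odd fs fits one fewer pair

    def test_matches_naive_window_loop(self):
        rng = np.random.default_rng(5)
        for fs in (25, 50, 100):
            x = rng.normal(size=fs * 30)
            K = fs // 2 + 1
            got = stft_power_features(x, fs=fs, K=K)
            exp = oracle_stft(x, fs, K)
            assert np.allclose(got, exp, rtol=1e-9, atol=1e-12)

    def test_k_beyond_bins_rejected(self):
        with pytest.raises(ValidationError):
            stft_power_features(np.zeros(750), fs=25, K=30)

    def test_hr_window_geometry(self):
        # a 30-s window over 30 one-second samples supplies 16 bins
        out = stft_power_features(np.random.default_rng(1).normal(70, 5, 30),
                                  fs=1, K=16, window_s=30.0)
        assert out.shape == (16,)


class TestTimeFeatures:
    def test_constant_series_degenerate_values(self):
        out = time_features(np.full(750, 2.5), fs=25)
        assert out["sd"] == 0 and out["range"] == 0
        assert out["skew"] == 0 and out["kurt"] == 0
        assert out["zcr"] == 0 and out["specent"] == 0

    def test_alternating_signal_zcr(self):
        fs = 10
        x = np.tile([0.0, 1.0], 50)
        out = time_features(x, fs=fs)
        assert out["zcr"] == pytest.approx((len(x) - 1) / (len(x) / fs))

    def test_matches_textbook_formulas(self):
        rng = np.random.default_rng(9)
        for fs in (25, 50):
            x = rng.normal(size=fs * 30)
            got = time_features(x, fs)
            exp = oracle_time_features(x, fs)
            for name in TIME_FEATURE_NAMES:
                assert got[name] == pytest.approx(exp[name], rel=1e-9, abs=1e-12), name


class TestHrFeatures:
    def test_constant_block(self):
        out = hr_features(np.full(30, 60.0))
        assert out["hr_mean"] == 60 and out["hr_sd"] == 0
        assert out["hr_slope"] == 0 and out["hr_rmssd"] == 0

    def test_linear_ramp_slope(self):
        out = hr_features(60.0 + np.arange(30.0))
        assert out["hr_slope"] == pytest.approx(1.0)
        assert out["hr_delta"] == pytest.approx(29.0)

    def test_low_coverage_marks_missing(self):
        valid = np.zeros(30, bool)
        valid[:10] = True
        out = hr_features(np.full(30, 70.0), valid)
        assert all(math.isnan(v) for v in out.values())

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            block = rng.uniform(55, 110, 30)
            valid = rng.random(30) > 0.25
            got = hr_features(block, valid)
            exp = oracle_hr_features(block, valid)
            for name in HR_FEATURE_NAMES:
                g, e = got[name], exp[name]
                if math.isnan(e):
                    assert math.isnan(g), name
                else:
                    assert g == pytest.approx(e, rel=1e-9, abs=1e-12), name


class TestFeatureTable:
    def test_exactly_145_named_features(self, one_night):
        table = build_feature_table(one_night["aligned"])
        feature_cols = [c for c in table.columns
                        if c not in ("participant_id", "epoch_index", "label")]
        assert len(feature_cols) == N_FEATURES
        assert feature_cols == default_registry().names

    def test_registry_composition(self):
        reg = default_registry()
        assert len(reg.entries) == N_FEATURES
        fft_cols = [e for e in reg.entries if "_fft" in e.name]
        assert len(fft_cols) == 4 * N_COMPONENTS_TABLE

    def test_hr_flag_changes_only_hr_columns(self, one_night):
        with_hr = build_feature_table(one_night["aligned"], include_hr=True)
        without = build_feature_table(one_night["aligned"], include_hr=False)
        hr_cols = list(HR_FEATURE_NAMES)
        other = [c for c in with_hr.columns if c not in hr_cols]
        assert with_hr[other].equals(without[other])
        assert (without[hr_cols] == 0).all().all()

    def test_determinism(self, one_night):
        a = build_feature_table(one_night["aligned"])
        b = build_feature_table(one_night["aligned"])
        assert a.equals(b)

    def test_scale_equivariance(self, one_night):
        """x*c scales mean/SD/RMS by c, powers by c^2, leaves corr/zcr fixed."""
        import copy
        night = one_night["aligned"]
        scaled = copy.copy(night)
        scaled.accel_epochs = night.accel_epochs * 2.0
        a = build_feature_table(night)
        b = build_feature_table(scaled)
        for ch in ("x", "y", "z", "mag"):
            assert np.allclose(b[f"{ch}_sd"], 2.0 * a[f"{ch}_sd"], rtol=1e-9)
            assert np.allclose(b[f"{ch}_rms"], 2.0 * a[f"{ch}_rms"], rtol=1e-9)
            assert np.allclose(b[f"{ch}_fft3"], 4.0 * a[f"{ch}_fft3"], rtol=1e-9)
            assert np.allclose(b[f"{ch}_zcr"], a[f"{ch}_zcr"])
        for pair in ("xy", "xz", "yz"):
            assert np.allclose(b[f"corr_{pair}"], a[f"corr_{pair}"], rtol=1e-9)

    def test_table_values_match_scalar_ops(self, one_night):
        """Vectorised table equals per-epoch scalar recomputation."""
        night = one_night["aligned"]
        table = build_feature_table(night)
        rng = np.random.default_rng(0)
        for row in rng.choice(len(table), 5, replace=False):
            ep = int(table.iloc[row]["epoch_index"])
            block = night.accel_epochs[ep]
            mag = magnitude(block)
            tf = time_features(mag, night.fs)
            for name in TIME_FEATURE_NAMES:
                assert table.iloc[row][f"mag_{name}"] == pytest.approx(
                    tf[name], rel=1e-9, abs=1e-12
                )
            fft = stft_power_features(block[:, 0], night.fs,
                                      min(N_COMPONENTS_TABLE, night.fs // 2 + 1))
            for k, v in enumerate(fft):
                assert table.iloc[row][f"x_fft{k}"] == pytest.approx(
                    v, rel=1e-9, abs=1e-12
                )
            assert table.iloc[row]["activity_count"] == pytest.approx(
                np.sum(np.abs(mag - 1.0)), rel=1e-9
            )


class TestLstmInput:
    def test_block_geometry(self, one_night):
        seq = build_lstm_input(one_night["aligned"])
        assert seq.X.shape == (one_night["aligned"].n_valid, 5, N_COMPONENTS_LSTM)
        assert np.isfinite(seq.X).all() and (seq.X >= 0).all()

    def test_hr_channel_zeroed_without_hr(self, one_night):
        seq = build_lstm_input(one_night["aligned"], include_hr=False)
        assert np.all(seq.X[:, 4, :] == 0)

    def test_motion_channels_match_stft_op(self, one_night):
        night = one_night["aligned"]
        seq = build_lstm_input(night)
        avail = min(N_COMPONENTS_LSTM, night.fs // 2 + 1)
        ep = int(seq.epoch_index[7])
        got = seq.X[7, 3, :]  # magnitude channel
        exp = stft_power_features(magnitude(night.accel_epochs[ep]),
                                  night.fs, avail)
        assert np.allclose(got[:avail], exp, rtol=1e-9)
        assert np.all(got[avail:] == 0)

    def test_hr_channel_padding(self, one_night):
        seq = build_lstm_input(one_night["aligned"])
        assert np.all(seq.X[:, 4, 16:] == 0)  # 30-s 1-Hz window: 16 bins
        assert np.any(seq.X[:, 4, :16] > 0)
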