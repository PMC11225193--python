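"""Acoustic feature extraction and feature-table validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from callspace.errors import ConfigurationError, DegenerateSignalError, ValidationError
from callspace.features import (
    FEATURE_NAMES,
    ID_COLUMNS,
    SpectrogramParams,
    extract_features,
    extract_from_selection_table,
    load_feature_table,
    write_feature_table,
)

from .conftest import tone

RATE = 22050


def test_pure_tone_concentrates_spectrum():
    f = extract_features(tone(3000, 0.2), RATE)
    assert f["spectral_mean"] == pytest.approx(3.0, abs=0.15)
    assert f["spectral_median"] == pytest.approx(3.0, abs=0.15)
    assert f["dominant_mean"] == pytest.approx(3.0, abs=0.15)
    assert f["spectral_sd"] < 0.2
    assert f["duration"] == pytest.approx(0.2, abs=1e-3)


def test_band_limited_white_noise_is_flat():
    """A flat spectrum has flatness and entropy at their maximum of 1."""
    rng = np.random.default_rng(0)
    f = extract_features(rng.standard_normal(2 * RATE), RATE)
    assert f["spectral_flatness"] == pytest.approx(1.0, abs=0.05)
    assert f["spectral_entropy"] == pytest.approx(1.0, abs=0.05)


def test_duration_is_selection_span():
    f = extract_features(tone(2500, 0.25), RATE)
    assert f["duration"] == pytest.approx(0.25, abs=1e-3)


def test_silent_input_rejected():
    with pytest.raises(DegenerateSignalError):
        extract_features(np.zeros(1000), RATE)


def test_band_outside_nyquist_rejected():
    with pytest.raises(ConfigurationError):
        extract_features(tone(3000, 0.1), RATE, SpectrogramParams(band_khz=(0.5, 20.0)))


def test_amplitude_scaling_invariance():
    x = tone(2700, 0.3) + 0.1 * np.random.default_rng(1).standard_normal(int(0.3 * RATE))
    a = extract_features(x, RATE)
    b = extract_features(7.31 * x, RATE)
    for name in FEATURE_NAMES:
        assert b[name] == pytest.approx(a[name], rel=1e-6, abs=1e-9), name


def test_time_shift_invariance_within_longer_file():
    call = tone(3100, 0.2)
    for offset in (0, 1000, 5000):
        buffer = np.concatenate([np.zeros(offset), call, np.zeros(500)])
        f = extract_features(buffer[offset : offset + len(call)], RATE)
        if offset == 0:
            ref = f
        assert f == ref


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_feature_invariants_on_random_signals(seed):
    """Quantile ordering, range identities and bounded entropies hold for any signal."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(800, 6000))
    t = np.arange(n) / RATE
    x = rng.standard_normal(n) + np.sin(2 * np.pi * rng.uniform(600, 8000) * t)
    f = extract_features(x, RATE)
    assert f["spectral_q25"] <= f["spectral_median"] <= f["spectral_q75"]
    assert f["spectral_iqr"] == pytest.approx(f["spectral_q75"] - f["spectral_q25"], abs=1e-9)
    assert f["dominant_min"] <= f["dominant_mean"] <= f["dominant_max"]
    assert f["dominant_range"] == pytest.approx(f["dominant_max"] - f["dominant_min"], abs=1e-9)
    for name in ("spectral_entropy", "spectral_flatness", "time_entropy"):
        assert 0.0 <= f[name] <= 1.0 + 1e-9
    assert f["duration"] > 0


# ---------------------------------------------------------------------------
# feature tables


def _feature_row(call_id="c1", **overrides):
    row = {
        "call_id": call_id, "bird_id": "b1", "flock_id": "f1",
        "age_class": "young", "block": 1,
        "duration": 0.1, "spectral_mean": 3.0, "spectral_sd": 0.4,
        "spectral_median": 3.0, "spectral_q25": 2.8, "spectral_q75": 3.2,
        "spectral_iqr": 0.4, "spectral_skewness": 0.1, "spectral_kurtosis": 3.0,
        "spectral_entropy": 0.5, "spectral_flatness": 0.4, "time_entropy": 0.6,
        "dominant_mean": 3.0, "dominant_min": 2.7, "dominant_max": 3.3,
        "dominant_range": 0.6, "modulation_index": 1.2,
    }
    row.update(overrides)
    return row


def test_valid_table_round_trips(tmp_path):
    df = pd.DataFrame([_feature_row(f"c{i}") for i in range(10)])
    path = tmp_path / "feat.csv"
    write_feature_table(df, path)
    loaded = load_feature_table(path)
    assert len(loaded) == 10
    assert list(loaded.columns) == list(ID_COLUMNS) + list(FEATURE_NAMES)


def test_quantile_violation_rejected_with_row_number(tmp_path):
    rows = [_feature_row("c0"), _feature_row("c1", spectral_q25=3.5), _feature_row("c2")]
    path = tmp_path / "bad.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    with pytest.raises(ValidationError, match=r"\[1\]"):
        load_feature_table(path)
    kept = load_feature_table(path, on_invalid="drop")
    assert list(kept["call_id"]) == ["c0", "c2"]


def test_column_order_is_irrelevant(tmp_path):
    df = pd.DataFrame([_feature_row(f"c{i}") for i in range(5)])
    canonical, permuted = tmp_path / "a.csv", tmp_path / "b.csv"
    write_feature_table(df, canonical)
    df[list(reversed(df.columns))].to_csv(permuted, index=False)
    pd.testing.assert_frame_equal(load_feature_table(canonical), load_feature_table(permuted))


def test_missing_columns_raise(tmp_path):
    path = tmp_path / "short.csv"
    pd.DataFrame([{"call_id": "c1", "duration": 0.1}]).to_csv(path, index=False)
    with pytest.raises(ValidationError, match="missing columns"):
        load_feature_table(path)


def test_selection_table_extraction(tmp_path):
    wav_path = tmp_path / "rec.wav"
    audio = np.concatenate([tone(2800, 0.3), np.zeros(RATE // 2), tone(3500, 0.25)])
    wavfile.write(wav_path, RATE, (audio * 32767).astype(np.int16))
    selections = pd.DataFrame(
        [
            {"call_id": "c1", "bird_id": "b1", "flock_id": "f1", "age_class": "young",
             "block": 1, "sound_file": str(wav_path), "start_s": 0.0, "end_s": 0.3},
            {"call_id": "c2", "bird_id": "b1", "flock_id": "f1", "age_class": "young",
             "block": 5, "sound_file": str(wav_path), "start_s": 0.8, "end_s": 1.05},
        ]
    )
    table = extract_from_selection_table(selections)
    assert len(table) == 2
    assert table.loc[0, "duration"] == pytest.approx(0.3, abs=2e-3)
    assert table.loc[1, "duration"] == pytest.approx(0.25, abs=2e-3)
    assert table.loc[0, "dominant_mean"] == pytest.approx(2.8, abs=0.15)
    assert table.loc[1, "dominant_mean"] == pytest.approx(3.5, abs=0.15)
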