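"""Per-call acoustic feature extraction and feature-table I/O.

Each contact call is summarised by 17 spectro-temporal features describing
how acoustic power is distributed in time and frequency: duration, seven
statistics of the band-limited mean power spectrum treated as a probability
distribution (mean, SD, median, Q25, Q75, IQR, skewness, kurtosis — the IQR
being derived), two flatness/entropy descriptors of that spectrum, an
entropy of the temporal energy envelope, and five descriptors of the
per-frame dominant-frequency track (mean, min, max, range, modulation
index).  Frequencies are reported in kHz, duration in seconds, entropies
normalised to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from .errors import (
    ConfigurationError,
    DegenerateSignalError,
    ValidationError,
)

__all__ = [
    "FEATURE_NAMES",
    "ID_COLUMNS",
    "SpectrogramParams",
    "extract_features",
    "extract_from_selection_table",
    "load_feature_table",
    "validate_feature_frame",
    "write_feature_table",
]

#: Canonical order of the 17 per-call features.
FEATURE_NAMES: tuple[str, ...] = (
    "duration",
    "spectral_mean",
    "spectral_sd",
    "spectral_median",
    "spectral_q25",
    "spectral_q75",
    "spectral_iqr",
    "spectral_skewness",
    "spectral_kurtosis",
    "spectral_entropy",
    "spectral_flatness",
    "time_entropy",
    "dominant_mean",
    "dominant_min",
    "dominant_max",
    "dominant_range",
    "modulation_index",
)

#: Provenance columns required alongside the features in a call table.
ID_COLUMNS: tuple[str, ...] = ("call_id", "bird_id", "flock_id", "age_class", "block")

AGE_CLASSES = ("young", "older")


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT settings for feature extraction.

    Defaults (Hann window, 512-point FFT, 50% overlap, 0.5–9 kHz band) suit
    budgerigar contact calls, whose energy sits mostly around 2–4 kHz.
    Band limits are in kHz.
    """

    n_fft: int = 512
    overlap: float = 0.5
    window: str = "hann"
    band_khz: tuple[float, float] = (0.5, 9.0)

    def validate(self, sample_rate: float) -> None:
        lo, hi = self.band_khz
        nyquist_khz = sample_rate / 2000.0
        if not (0 <= lo < hi):
            raise ConfigurationError(f"band limits must satisfy 0 <= lo < hi, got {self.band_khz}")
        if hi > nyquist_khz + 1e-12:
            raise ConfigurationError(
                f"band upper limit {hi} kHz exceeds Nyquist {nyquist_khz} kHz"
            )
        if not 0 <= self.overlap < 1:
            raise ConfigurationError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.n_fft < 8:
            raise ConfigurationError(f"n_fft too small: {self.n_fft}")


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Quantile of a discrete distribution given by (values, weights)."""
    cum = np.cumsum(weights)
    cum /= cum[-1]
    idx = int(np.searchsorted(cum, q, side="left"))
    return float(values[min(idx, len(values) - 1)])


def extract_features(
    waveform: np.ndarray,
    sample_rate: float,
    params: SpectrogramParams | None = None,
) -> dict[str, float]:
    """Compute the 17-feature vector for one call.

    Parameters
    ----------
    waveform : 1-D array of samples (any linear amplitude scale).
    sample_rate : Hz.
    params : spectrogram settings; defaults suit budgerigar contact calls.

    Returns a dict keyed by :data:`FEATURE_NAMES`.  Raises
    :class:`DegenerateSignalError` for silent input and
    :class:`ConfigurationError` for band limits outside the Nyquist range.
    """
    params = params or SpectrogramParams()
    params.validate(sample_rate)
    x = np.asarray(waveform, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateSignalError("empty waveform")
    if not np.any(x != 0.0):
        raise DegenerateSignalError("all-zero (silent) waveform")

    nperseg = min(params.n_fft, x.size)
    noverlap = int(nperseg * params.overlap)
    freqs, times, sxx = signal.spectrogram(
        x,
        fs=sample_rate,
        window=params.window,
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=params.n_fft,
        mode="psd",
    )
    freqs_khz = freqs / 1000.0
    lo, hi = params.band_khz
    band = (freqs_khz >= lo) & (freqs_khz <= hi)
    if band.sum() < 2:
        raise ConfigurationError("band contains fewer than 2 frequency bins")
    f = freqs_khz[band]
    s = sxx[band, :]
    total = s.sum()
    if total <= 0:
        raise DegenerateSignalError("no energy inside the analysis band")

    # mean power spectrum as a probability distribution over frequency
    spec = s.mean(axis=1)
    p = spec / spec.sum()
    mean = float(np.sum(p * f))
    var = float(np.sum(p * (f - mean) ** 2))
    sd = float(np.sqrt(var))
    median = _weighted_quantile(f, p, 0.5)
    q25 = _weighted_quantile(f, p, 0.25)
    q75 = _weighted_quantile(f, p, 0.75)
    if sd > 0:
        skew = float(np.sum(p * (f - mean) ** 3) / sd**3)
        kurt = float(np.sum(p * (f - mean) ** 4) / sd**4)
    else:  # single-bin spectrum
        skew, kurt = 0.0, 0.0
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(len(p))) if len(p) > 1 else 0.0
    flatness = float(np.exp(np.mean(np.log(np.maximum(spec, 1e-300)))) / spec.mean())

    # temporal energy envelope entropy
    frame_energy = s.sum(axis=0)
    pe = frame_energy / frame_energy.sum()
    nz = pe[pe > 0]
    time_entropy = (
        float(-(nz * np.log(nz)).sum() / np.log(len(pe))) if len(pe) > 1 else 0.0
    )

    # dominant-frequency track: per-frame spectral peak within the band
    dom = f[np.argmax(s, axis=0)]
    dom_min = float(dom.min())
    dom_max = float(dom.max())
    # clamp against float round-off so dom_min <= dom_mean <= dom_max exactly
    dom_mean = float(min(max(dom.mean(), dom_min), dom_max))
    dom_range = dom_max - dom_min
    if dom_range > 0 and len(dom) > 1:
        modulation = float(np.abs(np.diff(dom)).sum() / dom_range)
    else:
        modulation = 0.0

    return {
        "duration": x.size / float(sample_rate),
        "spectral_mean": mean,
        "spectral_sd": sd,
        "spectral_median": median,
        "spectral_q25": q25,
        "spectral_q75": q75,
        "spectral_iqr": q75 - q25,
        "spectral_skewness": skew,
        "spectral_kurtosis": kurt,
        "spectral_entropy": entropy,
        "spectral_flatness": flatness,
        "time_entropy": time_entropy,
        "dominant_mean": dom_mean,
        "dominant_min": dom_min,
        "dominant_max": dom_max,
        "dominant_range": dom_range,
        "modulation_index": modulation,
    }


def extract_from_selection_table(
    selections: pd.DataFrame,
    params: SpectrogramParams | None = None,
) -> pd.DataFrame:
    """Extract features for every row of a selection table.

    The table needs columns ``call_id, bird_id, flock_id, age_class, block,
    sound_file, start_s, end_s``; each row points at a span of a WAV file
    containing one isolated call.  Returns a feature table (ID columns plus
    the 17 features) suitable for :func:`load_feature_table` round-trips.
    """
    required = set(ID_COLUMNS) | {"sound_file", "start_s", "end_s"}
    missing = required - set(selections.columns)
    if missing:
        raise ValidationError(f"selection table missing columns: {sorted(missing)}")
    rows = []
    cache: dict[str, tuple[float, np.ndarray]] = {}
    for _, sel in selections.iterrows():
        if not sel.end_s > sel.start_s:
            raise ValidationError(
                f"call {sel.call_id}: end_s ({sel.end_s}) must exceed start_s ({sel.start_s})"
            )
        path = str(sel.sound_file)
        if path not in cache:
            rate, data = wavfile.read(path)
            if data.ndim > 1:  # mixdown multi-channel recordings
                data = data.mean(axis=1)
            cache[path] = (float(rate), np.asarray(data, dtype=float))
        rate, data = cache[path]
        i0, i1 = int(round(sel.start_s * rate)), int(round(sel.end_s * rate))
        feats = extract_features(data[i0:i1], rate, params)
        rows.append({c: sel[c] for c in ID_COLUMNS} | feats)
    return pd.DataFrame(rows, columns=list(ID_COLUMNS) + list(FEATURE_NAMES))


_ATOL = 1e-9


def _invariant_violations(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows violating any FeatureVector invariant."""
    bad = pd.Series(False, index=df.index)
    bad |= ~(df["duration"] > 0)
    bad |= df["spectral_q25"] > df["spectral_median"] + _ATOL
    bad |= df["spectral_median"] > df["spectral_q75"] + _ATOL
    bad |= (df["spectral_iqr"] - (df["spectral_q75"] - df["spectral_q25"])).abs() > 1e-6
    bad |= df["dominant_min"] > df["dominant_mean"] + _ATOL
    bad |= df["dominant_mean"] > df["dominant_max"] + _ATOL
    bad |= (df["dominant_range"] - (df["dominant_max"] - df["dominant_min"])).abs() > 1e-6
    for col in ("spectral_entropy", "spectral_flatness", "time_entropy"):
        bad |= (df[col] < -_ATOL) | (df[col] > 1 + _ATOL)
    bad |= ~np.isfinite(df[list(FEATURE_NAMES)]).all(axis=1)
    return bad


def validate_feature_frame(df: pd.DataFrame, on_invalid: str = "raise") -> pd.DataFrame:
    """Validate a call table against the schema and record invariants.

    ``on_invalid``: "raise" (default) aborts listing the offending row
    numbers; "drop" removes them with a warning and returns the rest.
    """
    missing = (set(ID_COLUMNS) | set(FEATURE_NAMES)) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    feats = df[list(FEATURE_NAMES)]
    non_numeric = [c for c in FEATURE_NAMES if not pd.api.types.is_numeric_dtype(feats[c])]
    if non_numeric:
        raise ValidationError(f"non-numeric feature columns: {non_numeric}")
    blocks = pd.to_numeric(df["block"], errors="coerce")
    if blocks.isna().any() or not blocks.between(1, 5).all():
        raise ValidationError("block must be an integer in 1..5 for every row")
    bad = _invariant_violations(df)
    if bad.any():
        rows = list(df.index[bad])
        if on_invalid == "raise":
            raise ValidationError(f"rows violate feature invariants: {rows}")
        warnings.warn(f"dropping {len(rows)} invalid feature rows: {rows}", stacklevel=2)
        df = df.loc[~bad]
    out = df[list(ID_COLUMNS) + list(FEATURE_NAMES)].copy()
    out["block"] = out["block"].astype(int)
    return out


def load_feature_table(path, on_invalid: str = "raise") -> pd.DataFrame:
    """Read and validate a per-call feature CSV (one row per call)."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas parse failure detail
        raise ValidationError(f"cannot parse feature table {path}: {exc}") from exc
    return validate_feature_frame(df, on_invalid=on_invalid)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a call table as CSV with ID columns first, features in canonical order."""
    cols = list(ID_COLUMNS) + list(FEATURE_NAMES)
    df[cols].to_csv(path, index=False)
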