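"""Predefined acoustic features (PAF) of a single call rendition.

Eighteen descriptors in three groups:

* **spectral (8)** — mean, standard deviation, skewness, kurtosis, normalized
  entropy, and the 25/50/75% quantiles (q1, q2, q3) of the in-band power
  spectrum treated as a probability distribution over frequency;
* **temporal (5)** — mean, standard deviation, skewness, kurtosis and
  normalized entropy of the rectified low-pass amplitude envelope treated as a
  probability distribution over time (relative to call onset);
* **fundamental (5)** — mean, min, max and coefficient of variation of the
  fundamental frequency over voiced frames, plus mean pitch saliency (the
  normalized autocorrelation peak height) over all frames.  The fifth feature
  can be switched to the fraction of voiced frames.

All features are invariant to waveform amplitude scaling: the spectral and
temporal groups are computed on normalized distributions and the f0 tracker
uses normalized autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synth import CallRecord

logger = logging.getLogger(__name__)

SPECTRAL_FEATURES = [
    "spect_mean", "spect_sd", "spect_skew", "spect_kurt", "spect_entropy",
    "q1", "q2", "q3",
]
TEMPORAL_FEATURES = ["time_mean", "time_sd", "time_skew", "time_kurt", "time_entropy"]
FUNDAMENTAL_FEATURES = ["fund_mean", "fund_min", "fund_max", "fund_cv", "saliency_mean"]
PAF_FEATURES = SPECTRAL_FEATURES + TEMPORAL_FEATURES + FUNDAMENTAL_FEATURES
PROVENANCE_COLUMNS = ["vocalizer_id", "call_type", "rendition_id"]


@dataclass
class Spectrogram:
    times: np.ndarray  # s, frame centers
    freqs: np.ndarray  # Hz
    log_power: np.ndarray  # dB re max, frames on axis 1 (freq x time)
    window_sd: float
    step: float


@dataclass
class AmplitudeEnvelope:
    times: np.ndarray
    amplitude: np.ndarray
    cutoff: float


@dataclass
class FundamentalTrack:
    times: np.ndarray
    f0: np.ndarray  # Hz; NaN for unvoiced frames
    saliency: np.ndarray  # 0..1
    voicing_threshold: float

    @property
    def voiced(self) -> np.ndarray:
        return self.saliency >= self.voicing_threshold


@dataclass
class PAFVector:
    vocalizer_id: str
    call_type: str
    rendition_id: str
    values: dict[str, float]  # the 18 features; NaN marks missing

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {
            "vocalizer_id": self.vocalizer_id,
            "call_type": self.call_type,
            "rendition_id": self.rendition_id,
        }
        row.update({k: self.values[k] for k in PAF_FEATURES})
        return row


def compute_spectrogram(
    call: CallRecord,
    window_sd: float = 0.002,
    step: float = 0.001,
    floor_db: float = 80.0,
) -> Spectrogram:
    """Gaussian-windowed short-time power spectrum in dB relative to its peak.

    The Gaussian window (sd ``window_sd`` s, truncated at ±3 sd) with step
    ``step`` s gives heavy overlap, so the transform remains invertible in
    principle.  Values are floored ``floor_db`` below the peak; a silent input
    sits entirely at the floor.
    """
    if window_sd <= 0 or step <= 0:
        raise ValueError("window_sd and step must be > 0")
    fs = call.sample_rate
    nperseg = int(round(6 * window_sd * fs)) | 1
    hop = max(int(round(step * fs)), 1)
    x = call.waveform
    if x.size < nperseg:
        logger.warning("call shorter than one window (%d < %d samples); padding", x.size, nperseg)
        x = np.pad(x, (0, nperseg - x.size))
    win = signal.windows.gaussian(nperseg, std=window_sd * fs, sym=True)
    sft = signal.ShortTimeFFT(win, hop=hop, fs=fs, scale_to="magnitude")
    spec = sft.stft(x)
    power = np.abs(spec) ** 2
    peak = power.max()
    if peak <= 0:
        log_power = np.full(power.shape, -floor_db)
    else:
        with np.errstate(divide="ignore"):
            log_power = 10.0 * np.log10(power / peak)
        log_power = np.maximum(log_power, -floor_db)
    times = sft.t(x.size)
    return Spectrogram(times, sft.f, log_power, window_sd, step)


def _distribution_stats(support: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """Mean, sd, skew, kurtosis and normalized entropy of a discrete pmf."""
    mean = float(np.sum(support * p))
    var = float(np.sum((support - mean) ** 2 * p))
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.sum(((support - mean) / sd) ** 3 * p))
        kurt = float(np.sum(((support - mean) / sd) ** 4 * p))
    else:
        skew, kurt = 0.0, 0.0
    pos = p[p > 0]
    entropy = float(-np.sum(pos * np.log(pos)) / np.log(len(p))) if len(p) > 1 else 0.0
    return {"mean": mean, "sd": sd, "skew": skew, "kurt": kurt, "entropy": entropy}


def _pmf_quantiles(support: np.ndarray, p: np.ndarray, qs: tuple[float, ...]) -> list[float]:
    """Quantiles of a binned pmf, spreading each bin's mass over its width.

    The piecewise-linear inverse CDF avoids the up-to-one-bin upward bias of a
    stepped CDF while staying within half a bin for a point mass.
    """
    half = np.gradient(support.astype(float)) / 2.0
    edges = np.concatenate([[support[0] - half[0]], support + half])
    cdf = np.concatenate([[0.0], np.cumsum(p)])
    cdf = cdf / cdf[-1]
    return [float(np.interp(q, cdf, edges)) for q in qs]


def spectral_stats(call: CallRecord, band: tuple[float, float] = (250.0, 12000.0)) -> dict[str, float]:
    """The 8 spectral features from the in-band power spectral density.

    The PSD (Welch estimate, Hann windows of up to 1024 samples) restricted to
    ``band`` is normalized to a probability distribution over frequency; the
    features are its moments, entropy and quartiles.
    """
    fs = call.sample_rate
    if not 0 < band[0] < band[1] < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, Nyquist)")
    nperseg = min(1024, call.waveform.size)
    freqs, psd = signal.welch(call.waveform, fs=fs, nperseg=nperseg)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    freqs, psd = freqs[mask], psd[mask]
    total = psd.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("zero in-band energy; spectral features undefined")
        return {k: np.nan for k in SPECTRAL_FEATURES}
    p = psd / total
    stats = _distribution_stats(freqs, p)
    q1, q2, q3 = _pmf_quantiles(freqs, p, (0.25, 0.5, 0.75))
    return {
        "spect_mean": stats["mean"], "spect_sd": stats["sd"],
        "spect_skew": stats["skew"], "spect_kurt": stats["kurt"],
        "spect_entropy": stats["entropy"], "q1": q1, "q2": q2, "q3": q3,
    }


def amplitude_envelope(call: CallRecord, cutoff: float = 50.0) -> AmplitudeEnvelope:
    """Rectified waveform low-pass filtered at ``cutoff`` Hz (zero-phase)."""
    rect = np.abs(call.waveform)
    sos = signal.butter(4, cutoff, fs=call.sample_rate, output="sos")
    env = signal.sosfiltfilt(sos, rect)
    env = np.maximum(env, 0.0)
    times = np.arange(env.size) / call.sample_rate
    return AmplitudeEnvelope(times, env, cutoff)


def temporal_stats(call: CallRecord, envelope_cutoff: float = 50.0) -> dict[str, float]:
    """The 5 temporal features from the normalized amplitude envelope.

    Times are in seconds relative to call onset.
    """
    env = amplitude_envelope(call, envelope_cutoff)
    total = env.amplitude.sum()
    if total <= 0:
        logger.warning("silent call; temporal features undefined")
        return {k: np.nan for k in TEMPORAL_FEATURES}
    p = env.amplitude / total
    stats = _distribution_stats(env.times, p)
    return {
        "time_mean": stats["mean"], "time_sd": stats["sd"],
        "time_skew": stats["skew"], "time_kurt": stats["kurt"],
        "time_entropy": stats["entropy"],
    }


def fundamental_track(
    call: CallRecord,
    f0_band: tuple[float, float] = (300.0, 6000.0),
    frame: float = 0.02,
    hop: float = 0.005,
    voicing_threshold: float = 0.5,
) -> FundamentalTrack:
    """Frame-wise f0 from the highest in-band normalized autocorrelation peak.

    Saliency is the peak's normalized (lag-bias-corrected) height; frames whose
    saliency falls below ``voicing_threshold`` are unvoiced (f0 = NaN).  An
    all-unvoiced track is a legal outcome.
    """
    fs = call.sample_rate
    x = call.waveform.astype(float)
    n_frame = min(int(round(frame * fs)), x.size)
    n_hop = max(int(round(hop * fs)), 1)
    lag_min = max(int(np.floor(fs / f0_band[1])), 1)
    lag_max = min(int(np.ceil(fs / f0_band[0])), n_frame - 1)
    starts = np.arange(0, max(x.size - n_frame, 0) + 1, n_hop)
    times, f0s, sals = [], [], []
    for s in starts:
        seg = x[s : s + n_frame]
        seg = seg - seg.mean()
        times.append((s + n_frame / 2) / fs)
        e0 = np.dot(seg, seg)
        if e0 <= 0 or lag_max <= lag_min:
            f0s.append(np.nan)
            sals.append(0.0)
            continue
        nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
        ac = np.fft.irfft(np.abs(np.fft.rfft(seg, nfft)) ** 2)[:n_frame]
        ac_norm = ac / ac[0]
        # Peak picking uses the biased estimate: its linear lag taper makes
        # the true period beat its own multiples (no octave-down errors).
        # Among local maxima within 2% of the in-band maximum, the smallest
        # lag wins (breaks plateaus of a perfectly periodic signal).
        window = ac_norm[lag_min : lag_max + 1]
        best = float(window.max())
        k = int(np.argmax(window)) + lag_min
        if best > 0:
            cand = np.flatnonzero(window >= 0.98 * best) + lag_min
            for c in cand:
                if 0 < c < n_frame - 1 and ac_norm[c - 1] <= ac_norm[c] >= ac_norm[c + 1]:
                    k = int(c)
                    break
        # parabolic refinement of the peak lag
        if 0 < k < n_frame - 1:
            y0, y1, y2 = ac_norm[k - 1], ac_norm[k], ac_norm[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        # saliency corrects the estimator's lag bias so a perfect periodicity
        # scores ~1 at any lag
        sal = float(np.clip(ac_norm[k] * n_frame / max(n_frame - k, 1), 0.0, 1.0))
        sals.append(sal)
        f0s.append(fs / (k + delta) if sal >= voicing_threshold else np.nan)
    return FundamentalTrack(
        np.asarray(times), np.asarray(f0s), np.asarray(sals), voicing_threshold
    )


def fundamental_stats(track: FundamentalTrack, fifth_feature: str = "saliency") -> dict[str, float]:
    """The 5 fundamental features from an f0 track.

    ``fifth_feature`` selects the voicing summary: ``"saliency"`` (mean pitch
    saliency over all frames, the default) or ``"voiced_fraction"``.  With no
    voiced frame the four f0 statistics are missing (NaN).
    """
    if fifth_feature not in ("saliency", "voiced_fraction"):
        raise ValueError(f"unknown fifth_feature {fifth_feature!r}")
    voiced_f0 = track.f0[np.isfinite(track.f0)]
    if track.saliency.size == 0:
        fifth = np.nan
    elif fifth_feature == "saliency":
        fifth = float(np.mean(track.saliency))
    else:
        fifth = float(np.mean(track.voiced))
    if voiced_f0.size == 0:
        return {
            "fund_mean": np.nan, "fund_min": np.nan, "fund_max": np.nan,
            "fund_cv": np.nan, "saliency_mean": fifth,
        }
    mean = float(np.mean(voiced_f0))
    return {
        "fund_mean": mean,
        "fund_min": float(np.min(voiced_f0)),
        "fund_max": float(np.max(voiced_f0)),
        "fund_cv": float(np.std(voiced_f0) / mean) if mean > 0 else np.nan,
        "saliency_mean": fifth,
    }


def extract_paf(
    call: CallRecord,
    band: tuple[float, float] = (250.0, 12000.0),
    envelope_cutoff: float = 50.0,
    f0_band: tuple[float, float] = (300.0, 6000.0),
    voicing_threshold: float = 0.5,
    fifth_feature: str = "saliency",
) -> PAFVector:
    """All 18 features for one call; missing f0 statistics propagate as NaN."""
    values: dict[str, float] = {}
    values.update(spectral_stats(call, band))
    values.update(temporal_stats(call, envelope_cutoff))
    track = fundamental_track(call, f0_band=f0_band, voicing_threshold=voicing_threshold)
    values.update(fundamental_stats(track, fifth_feature))
    return PAFVector(call.vocalizer_id, call.call_type, call.rendition_id, values)


def extract_paf_table(calls: list[CallRecord], **kwargs) -> pd.DataFrame:
    """One row per rendition: provenance columns plus the 18 feature columns."""
    return pd.DataFrame([extract_paf(c, **kwargs).as_row() for c in calls])


def write_features_csv(table: pd.DataFrame, path) -> None:
    """Features CSV dialect: missing values as empty fields."""
    table.to_csv(path, index=False, na_rep="")


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PROVENANCE_COLUMNS + PAF_FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"features CSV missing columns: {missing}")
    return df
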