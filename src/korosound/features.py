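"""The 46-dimensional KS feature vector.

Four blocks, computed from the denoised record restricted to the detected
KS span [B, E]:

* 19 energy features from a 3-level wavelet-packet (WP) decomposition at
  the 800 Hz working rate, whose eight leaves are exactly the 50 Hz bands
  0-50 ... 350-400 Hz: the seven global band-energy ratios S_total(j) over
  50-400 Hz, and per-beat low/high-frequency ratios en = E(50-100)/E(50-400),
  en_h = E(150-400)/E(50-400) and total energy Et, summarized through their
  mean-normalized variability series (std and extrema, in percent).
* 12 statistical features of the amplitude samples plus the dominant
  frequency of the 50-400 Hz periodogram.
* 2 entropies: amplitude-histogram entropy and spectral entropy (bits).
* 13 MFCCs: 40 ms / 50 % framed Mel filterbank (26 triangles, 0-400 Hz),
  log energies, DCT orders 1..13, averaged across frames.

Feature-set views: A = energy + statistical + entropy (33),
B = statistical + entropy + MFCC (27), C = all 46.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import periodogram
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .audio_io import AudioRecord, RunConfig, resample
from .denoise import denoise_record
from .envelope import segment_record

__all__ = [
    "BandEnergies", "BeatFeatureSeries", "FeatureVector",
    "FEATURE_NAMES", "FEATURE_SETS", "BAND_EDGES",
    "wp_band_energies", "global_band_ratios", "beat_band_ratios",
    "variability_series", "energy_feature_block", "statistical_features",
    "entropy_features", "mfcc_features", "mel_filterbank", "extract_features",
]

#: the eight 50 Hz WP leaf bands at the 800 Hz working rate
BAND_EDGES = [(50 * i, 50 * (i + 1)) for i in range(8)]

ENERGY_FEATURES = [
    "Stotal_50_100", "Stotal_100_150", "Stotal_150_200", "Stotal_200_250",
    "Stotal_250_300", "Stotal_300_350", "Stotal_350_400",
    "std_enr", "std_enr_h", "std_TM", "std_Ep",
    "enr_max", "enr_min", "enr_h_max", "enr_h_min",
    "TM_max", "TM_min", "Ep_max", "Ep_min",
]
STATISTICAL_FEATURES = [
    "mean", "median", "std", "mean_abs_dev", "q1", "q3", "iqr",
    "skewness", "kurtosis", "dom_freq", "dom_freq_mag", "dom_freq_ratio",
]
ENTROPY_FEATURES = ["H_signal", "H_freq"]
MFCC_FEATURES = [f"mfcc_{i}" for i in range(1, 14)]

FEATURE_NAMES = ENERGY_FEATURES + STATISTICAL_FEATURES + ENTROPY_FEATURES + MFCC_FEATURES

FEATURE_SETS = {
    "A": ENERGY_FEATURES + STATISTICAL_FEATURES + ENTROPY_FEATURES,
    "B": STATISTICAL_FEATURES + ENTROPY_FEATURES + MFCC_FEATURES,
    "C": FEATURE_NAMES,
}

#: relative floor applied to Mel filter energies before the log
_MEL_FLOOR = 1e-10


@dataclass
class BandEnergies:
    """WP leaf energies in ascending frequency order (eight 50 Hz bands)."""

    node_energies: np.ndarray

    def __post_init__(self) -> None:
        self.node_energies = np.asarray(self.node_energies, dtype=np.float64)
        if self.node_energies.shape != (8,):
            raise ValueError("expected 8 band energies")
        if np.any(self.node_energies < 0):
            raise ValueError("band energies must be non-negative")

    @property
    def total_50_400(self) -> float:
        """Total energy over the seven bands at and above 50 Hz."""
        return float(np.sum(self.node_energies[1:]))


@dataclass
class BeatFeatureSeries:
    """Per-beat ratio/energy series and inter-beat intervals Ti (s)."""

    en: np.ndarray
    en_h: np.ndarray
    Et: np.ndarray
    Ti: np.ndarray

    def __post_init__(self) -> None:
        for name in ("en", "en_h", "Et", "Ti"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.en.size == self.en_h.size == self.Et.size):
            raise ValueError("en, en_h and Et must have one value per beat")
        if np.any((self.en < 0) | (self.en > 1)) or np.any((self.en_h < 0) | (self.en_h > 1)):
            raise ValueError("energy ratios must lie in [0, 1]")
        if np.any(self.Et < 0):
            raise ValueError("beat energies must be non-negative")


@dataclass
class FeatureVector:
    """The 46 named features of one record, with set views A/B/C."""

    values: dict[str, float]
    source_id: str = ""
    label: str = "unlabeled"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must contain the 46 named features in order")
        arr = np.array(list(self.values.values()), dtype=np.float64)
        if not np.all(np.isfinite(arr)):
            bad = [n for n, v in self.values.items() if not np.isfinite(v)]
            raise ValueError(f"non-finite features: {bad}")

    def array(self, feature_set: str = "C") -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_SETS[feature_set]])

    def to_dict(self) -> dict:
        out = dict(self.values)
        out["source_id"] = self.source_id
        out["label"] = self.label
        return out


# ---------------------------------------------------------------- energy

def wp_band_energies(signal: np.ndarray, wavelet_name: str = "db24") -> BandEnergies:
    """3-level wavelet-packet leaf energies in frequency order.

    Periodized orthogonal transform, so the leaf energies conserve the
    signal energy (Parseval); the signal is trimmed to a multiple of 8
    samples to keep the transform exactly orthogonal.  Leaves are reordered
    from tree order to natural frequency order before band labeling.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 8:
        raise ValueError("signal too short for a 3-level decomposition")
    if wavelet_name not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet: {wavelet_name}")
    x = x[: (x.size // 8) * 8]
    wp = pywt.WaveletPacket(x, wavelet_name, mode="periodization", maxlevel=3)
    nodes = wp.get_level(3, order="freq")
    energies = np.array([np.sum(n.data ** 2) for n in nodes])
    return BandEnergies(node_energies=energies)


def global_band_ratios(bands: BandEnergies) -> np.ndarray:
    """The seven global energy ratios S_total(j) = E(j) / E_total(50-400).

    Renormalized so they sum to exactly 1; zero in-band energy is an error.
    """
    total = bands.total_50_400
    if total <= 0:
        raise ValueError("zero energy in 50-400 Hz")
    ratios = bands.node_energies[1:] / total
    return ratios / ratios.sum()


def beat_band_ratios(beat: np.ndarray,
                     wavelet_name: str = "db24") -> tuple[float, float, float]:
    """Per-beat (en, en_h, Et).

    en is the 50-100 Hz fraction, en_h the 150-400 Hz fraction of the beat's
    50-400 Hz energy Et; the 100-150 Hz band belongs to neither ratio, so
    en + E(100-150)/Et + en_h = 1.
    """
    bands = wp_band_energies(beat, wavelet_name)
    Et = bands.total_50_400
    if Et <= 0:
        raise ValueError("zero energy in 50-400 Hz for this beat")
    en = float(bands.node_energies[1] / Et)
    en_h = float(np.sum(bands.node_energies[3:]) / Et)
    return en, en_h, Et


def variability_series(values: np.ndarray) -> np.ndarray:
    """Mean-normalize a per-beat sequence (output mean is exactly 1)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty series")
    m = float(np.mean(v))
    if m == 0:
        raise ValueError("zero-mean series cannot be mean-normalized")
    return v / m


def energy_feature_block(series: BeatFeatureSeries,
                         bands: BandEnergies) -> dict[str, float]:
    """The 19 energy features, all in percent.

    Global ratios and the en/en_h summaries are fractions x100; the total
    energy Et and interval Ti are first mean-normalized (Ep, TM) and then
    x100, so a perfectly regular train gives TM_max = TM_min = 100.
    Population standard deviations throughout.
    """
    if series.en.size < 2 or series.Ti.size < 1:
        raise ValueError("insufficient beats: need at least 2 for variability features")
    ratios = global_band_ratios(bands) * 100.0
    en, en_h = series.en * 100.0, series.en_h * 100.0
    Ep = variability_series(series.Et) * 100.0
    TM = variability_series(series.Ti) * 100.0
    out = {name: float(v) for name, v in zip(ENERGY_FEATURES[:7], ratios)}
    out.update({
        "std_enr": float(np.std(en)), "std_enr_h": float(np.std(en_h)),
        "std_TM": float(np.std(TM)), "std_Ep": float(np.std(Ep)),
        "enr_max": float(np.max(en)), "enr_min": float(np.min(en)),
        "enr_h_max": float(np.max(en_h)), "enr_h_min": float(np.min(en_h)),
        "TM_max": float(np.max(TM)), "TM_min": float(np.min(TM)),
        "Ep_max": float(np.max(Ep)), "Ep_min": float(np.min(Ep)),
    })
    return out


# ------------------------------------------------------------ statistical

def statistical_features(signal: np.ndarray, rate: float) -> dict[str, float]:
    """12 amplitude/spectral statistics of the KS span.

    Time-domain moments and quartiles of the samples; the dominant
    frequency is the periodogram argmax restricted to 50-400 Hz, with its
    peak power and the peak's share of the in-band power.  Skewness is the
    standardized third moment and kurtosis is Pearson (normal -> 3); both
    are 0 by convention for a degenerate (constant) signal.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    std = float(np.std(x))
    if std == 0.0:
        warnings.warn("degenerate signal: skewness and kurtosis set to 0")
        skew = kurt = 0.0
    else:
        skew = float(_skew(x))
        kurt = float(_kurtosis(x, fisher=False))
    q1, q3 = np.percentile(x, [25, 75])
    freqs, power = periodogram(x, fs=rate)
    band = (freqs >= 50) & (freqs <= 400)
    in_band = power[band]
    if in_band.size and in_band.sum() > 0:
        k = int(np.argmax(in_band))
        dom_freq = float(freqs[band][k])
        dom_mag = float(in_band[k])
        dom_ratio = float(in_band[k] / in_band.sum())
    else:
        dom_freq = dom_mag = dom_ratio = 0.0
    return {
        "mean": float(np.mean(x)), "median": float(np.median(x)), "std": std,
        "mean_abs_dev": float(np.mean(np.abs(x - np.mean(x)))),
        "q1": float(q1), "q3": float(q3), "iqr": float(q3 - q1),
        "skewness": skew, "kurtosis": kurt,
        "dom_freq": dom_freq, "dom_freq_mag": dom_mag, "dom_freq_ratio": dom_ratio,
    }


# --------------------------------------------------------------- entropy

def entropy_features(signal: np.ndarray, rate: float,
                     bins: int = 128) -> tuple[float, float]:
    """Amplitude-histogram entropy and spectral entropy, both in bits.

    H_signal is the Shannon entropy of the bins-bin amplitude histogram
    (empty bins contribute 0); H_freq is the entropy of the periodogram
    normalized to a probability distribution.  A pure tone therefore has
    lower H_freq than broadband noise.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < bins:
        raise ValueError(f"need at least {bins} samples")
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    h_signal = float(-np.sum(p * np.log2(p)))
    _, power = periodogram(x, fs=rate)
    total = power.sum()
    if total > 0:
        q = power[power > 0] / total
        h_freq = float(-np.sum(q * np.log2(q)))
    else:
        h_freq = 0.0
    return h_signal, h_freq


# ----------------------------------------------------------------- MFCC

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, rate: float,
                   fmax: float = 400.0) -> np.ndarray:
    """Triangular Mel filters evaluated at the one-sided FFT bin frequencies.

    n_filters + 2 points equally spaced on the Mel scale between 0 and
    fmax; filter m rises linearly from point m-1 to a peak of 1 at point m
    and falls to point m+1.  Shape (n_filters, nfft // 2 + 1).
    """
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fmax), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.arange(nfft // 2 + 1) * rate / nfft
    fb = np.zeros((n_filters, freqs.size))
    for m in range(1, n_filters + 1):
        left, center, right = hz_pts[m - 1], hz_pts[m], hz_pts[m + 1]
        up = (freqs - left) / (center - left)
        down = (right - freqs) / (right - center)
        fb[m - 1] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc_frame(frame: np.ndarray, filterbank: np.ndarray, nfft: int,
               n_coeffs: int = 13) -> np.ndarray | None:
    """DCT of the log Mel filter energies of one frame (orders 1..n_coeffs).

    c(n1) = sum_m log E(m) cos((m - 0.5) / M * n1 * pi).  Filter energies
    are floored at a fraction of the frame maximum before the log, so the
    coefficients are invariant to waveform gain (the gain adds a constant
    to every log energy and the order >= 1 cosines sum to zero).  Returns
    None for a frame with no filterbank energy.
    """
    power = np.abs(np.fft.rfft(frame, n=nfft)) ** 2
    energies = filterbank @ power
    peak = float(np.max(energies))
    if peak <= 0.0:
        return None
    log_e = np.log(np.maximum(energies, _MEL_FLOOR * peak))
    M = filterbank.shape[0]
    m = np.arange(1, M + 1)
    n1 = np.arange(1, n_coeffs + 1)
    dct = np.cos((m[None, :] - 0.5) / M * n1[:, None] * np.pi)
    return dct @ log_e


def mfcc_features(signal: np.ndarray, rate: float, n_filters: int = 26,
                  n_coeffs: int = 13, frame_len: float = 0.040,
                  overlap: float = 0.5, nfft: int = 256) -> np.ndarray:
    """Frame-averaged MFCCs of the KS span (exactly n_coeffs values).

    40 ms / 50 % framing by default; the spectrum is zero-padded to nfft
    so the narrow low-frequency Mel triangles are resolved.
    """
    if n_filters < n_coeffs:
        raise ValueError("DCT order exceeds filter count")
    x = np.asarray(signal, dtype=np.float64)
    L = int(round(frame_len * rate))
    if x.size < L:
        raise ValueError("signal shorter than one analysis frame")
    H = int(round(L * (1.0 - overlap)))
    fb = mel_filterbank(n_filters, nfft, rate)
    coeffs = []
    for start in range(0, x.size - L + 1, H):
        c = mfcc_frame(x[start:start + L], fb, nfft, n_coeffs)
        if c is not None:
            coeffs.append(c)
    if not coeffs:
        raise ValueError("no frame with filterbank energy")
    return np.mean(coeffs, axis=0)


# ------------------------------------------------------------- assembly

def extract_features(record: AudioRecord,
                     config: RunConfig | None = None) -> FeatureVector:
    """Full per-record pipeline: resample, denoise, segment, all blocks.

    The record is resampled to the working rate and peak-normalized before
    and after denoising, which makes the whole vector invariant to
    waveform gain.  At least 2 beats must survive segmentation.
    """
    config = config or RunConfig()
    rec = resample(record, config.working_rate).peak_normalized()
    rec = denoise_record(rec, config.noise_seconds, config.frame_len)
    rec = rec.peak_normalized()
    seg = segment_record(rec, config)
    if len(seg.anchors) < 2:
        raise ValueError("insufficient beats: need at least 2 anchors")
    rate = rec.rate
    span = rec.samples[int(round(seg.begin * rate)):int(round(seg.end * rate))]

    bands = wp_band_energies(span, config.wavelet_name)
    en, en_h, Et = [], [], []
    for start, stop in seg.beat_windows:
        beat = rec.samples[int(round(start * rate)):int(round(stop * rate))]
        try:
            e, eh, et = beat_band_ratios(beat, config.wavelet_name)
        except ValueError:
            warnings.warn("beat with no 50-400 Hz energy skipped")
            continue
        en.append(e); en_h.append(eh); Et.append(et)
    if len(en) < 2:
        raise ValueError("insufficient beats: need at least 2 with in-band energy")
    series = BeatFeatureSeries(en=en, en_h=en_h, Et=Et, Ti=seg.intervals)

    values = energy_feature_block(series, bands)
    values.update(statistical_features(span, rate))
    h_signal, h_freq = entropy_features(span, rate, config.entropy_bins)
    values.update({"H_signal": h_signal, "H_freq": h_freq})
    mfcc = mfcc_features(span, rate, config.mfcc_filters,
                         frame_len=config.frame_len, overlap=config.frame_overlap)
    values.update({name: float(c) for name, c in zip(MFCC_FEATURES, mfcc)})

    ordered = {name: values[name] for name in FEATURE_NAMES}
    meta = {"n_beats": len(en), "begin": seg.begin, "end": seg.end,
            "config": config.to_dict()}
    return FeatureVector(values=ordered, source_id=record.source_id,
                         label=record.label, metadata=meta)
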