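"""Wiener-filter noise reduction for KS records.

The observed record y(n) = s(n) + d(n) is the clean pulse train plus
broadband measurement noise.  The minimum-mean-square-error estimate of
s(n) is realized in the short-time spectral domain: the record is framed
(Hann window, 50 % overlap), each frame's spectrum is multiplied by a
per-bin Wiener gain xi/(1 + xi), and the frames are overlap-added back.
The a-priori SNR xi is tracked with the decision-directed rule, which
smooths the gain over time and avoids musical noise.

The noise power spectrum is estimated from the silent lead-in of the
recording: during cuff inflation, before the first Korotkoff sound, the
channel carries only noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import istft, stft

from .audio_io import AudioRecord, logger

__all__ = ["NoiseProfile", "estimate_noise", "wiener_filter", "denoise_record"]

#: decision-directed a-priori SNR smoothing factor
DD_SMOOTHING = 0.98
#: lower bound on the spectral gain (limits distortion of weak signal bins)
GAIN_FLOOR = 0.05


@dataclass
class NoiseProfile:
    """Per-frequency-bin noise power estimate.

    psd has one entry per one-sided FFT bin of the analysis frame; rate and
    frame_len record the geometry the profile was built at so a mismatched
    record can be rejected.
    """

    psd: np.ndarray
    n_frames_used: int
    frame_len: float
    rate: float

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if np.any(self.psd < 0):
            raise ValueError("noise psd must be non-negative")

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_len * self.rate))


def _stft_params(frame_samples: int) -> dict:
    return dict(window="hann", nperseg=frame_samples, noverlap=frame_samples // 2)


def estimate_noise(record: AudioRecord, n_frames: int = 50,
                   frame_len: float = 0.040) -> NoiseProfile:
    """Average periodogram of the first n_frames analysis frames.

    The caller is responsible for pointing this at a noise-only stretch
    (by default the pipeline uses the silent lead-in).
    """
    L = int(round(frame_len * record.rate))
    hop = L // 2
    needed = L + (n_frames - 1) * hop
    if n_frames < 1 or record.samples.size < needed:
        raise ValueError(
            f"record too short for {n_frames} noise frames "
            f"({record.samples.size} < {needed} samples)")
    _, _, Z = stft(record.samples[:needed], fs=record.rate,
                   **_stft_params(L), boundary=None, padded=False)
    psd = np.mean(np.abs(Z[:, :n_frames]) ** 2, axis=1)
    return NoiseProfile(psd=psd, n_frames_used=n_frames,
                        frame_len=frame_len, rate=record.rate)


def wiener_filter(record: AudioRecord, profile: NoiseProfile) -> AudioRecord:
    """Apply the spectral Wiener gain with decision-directed SNR tracking.

    Output has the record's length and rate.  Per-bin gain lies in
    [GAIN_FLOOR, 1] wherever noise is present and is exactly 1 in bins with
    zero estimated noise, so a zero profile passes the signal through
    unchanged and denoising never increases signal energy.
    """
    if profile.rate != record.rate:
        raise ValueError("noise profile was built at a different sampling rate")
    L = profile.frame_samples
    if profile.psd.size != L // 2 + 1:
        raise ValueError("noise profile psd length does not match frame geometry")
    x = record.samples
    _, _, Z = stft(x, fs=record.rate, **_stft_params(L))
    noise = profile.psd[:, None]
    out = np.empty_like(Z)
    prev_clean_power = None
    noisy = noise[:, 0] > 0
    for t in range(Z.shape[1]):
        power = np.abs(Z[:, t]) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            gamma = np.where(noisy, power / np.maximum(noise[:, 0], 1e-300), np.inf)
        ml = np.maximum(gamma - 1.0, 0.0)
        if prev_clean_power is None:
            xi = ml
        else:
            with np.errstate(invalid="ignore"):
                xi = DD_SMOOTHING * prev_clean_power / np.maximum(noise[:, 0], 1e-300) \
                    + (1.0 - DD_SMOOTHING) * ml
        with np.errstate(invalid="ignore"):
            gain = xi / (1.0 + xi)
        gain = np.where(noisy, np.clip(gain, GAIN_FLOOR, 1.0), 1.0)
        out[:, t] = gain * Z[:, t]
        prev_clean_power = (gain ** 2) * power
    _, y = istft(out, fs=record.rate, **_stft_params(L))
    y = y[:x.size]
    if y.size < x.size:  # istft may round down by a partial hop
        y = np.pad(y, (0, x.size - y.size))
    return replace(record, samples=y)


def denoise_record(record: AudioRecord, noise_seconds: float = 0.5,
                   frame_len: float = 0.040) -> AudioRecord:
    """Estimate noise from the first noise_seconds and Wiener-filter.

    Convenience wrapper used by the pipeline; the lead-in of a cuff
    measurement is silent, so its spectrum is a noise estimate.
    """
    L = int(round(frame_len * record.rate))
    hop = L // 2
    n_frames = max(1, int((noise_seconds * record.rate - L) // hop) + 1)
    profile = estimate_noise(record, n_frames=n_frames, frame_len=frame_len)
    logger.debug("noise profile from %d frames (%.2f s)", n_frames, noise_seconds)
    return wiener_filter(record, profile)
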