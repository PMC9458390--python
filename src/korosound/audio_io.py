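"""Audio and configuration I/O for Korotkoff-sound (KS) processing.

A KS recording is a mono cuff-deflation measurement: a silent lead-in, a
train of short damped pulses whose amplitude rises then falls across the
deflation, and a silent tail.  This module holds the record container, the
run configuration shared by the whole pipeline, WAV read/write, and
anti-aliased resampling to the pipeline's working rate.

The working rate defaults to 800 Hz: a 3-level wavelet-packet tree at that
rate splits the spectrum into eight bands of exactly 50 Hz (0-50, 50-100,
..., 350-400 Hz), which is the band grid the energy features are defined on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger("korosound")

__all__ = [
    "AudioRecord",
    "RunConfig",
    "load_record",
    "write_record",
    "resample",
    "configure_logging",
]


def configure_logging(level: str = "INFO") -> None:
    """Route package log output to stderr at the given level."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


@dataclass
class AudioRecord:
    """A sampled KS waveform.

    samples are dimensionless amplitudes scaled into [-1, 1] at load time;
    rate is the sampling rate in Hz; source_id is a free-text provenance
    tag; label is an optional class tag ("healthy" | "chf" | "unlabeled").
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("mono required: samples must be one-dimensional")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.rate

    def peak_normalized(self) -> "AudioRecord":
        """Return a copy rescaled so max |sample| = 1 (all-zero left as is)."""
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak == 0.0:
            return replace(self, samples=self.samples.copy())
        return replace(self, samples=self.samples / peak)


@dataclass
class RunConfig:
    """Pipeline parameters.

    Durations are in seconds.  frame_len/frame_overlap set the 40 ms / 50 %
    analysis framing used by the Shannon envelope, the Wiener filter and the
    MFCC front end.  anchor_threshold_frac is the fraction of the maximum
    envelope value a local maximum must reach to become an anchor; merge_gap
    is the minimum spacing between anchors (closer pairs are merged);
    pre_extend/post_extend delimit the record span around the first/last
    anchor.  beat_pre/beat_post define the per-beat analysis window around
    each anchor.  noise_seconds is the silent lead-in used for the noise
    estimate.
    """

    working_rate: float = 800.0
    frame_len: float = 0.040
    frame_overlap: float = 0.5
    anchor_threshold_frac: float = 0.2
    merge_gap: float = 0.100
    pre_extend: float = 0.300
    post_extend: float = 0.500
    beat_pre: float = 0.100
    beat_post: float = 0.300
    noise_seconds: float = 0.5
    wavelet_name: str = "db24"
    mfcc_filters: int = 26
    entropy_bins: int = 128
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frame_overlap < 1:
            raise ValueError("frame_overlap must lie in (0, 1)")
        if not 0 < self.anchor_threshold_frac < 1:
            raise ValueError("anchor_threshold_frac must lie in (0, 1)")
        for name in ("working_rate", "frame_len", "merge_gap", "pre_extend",
                     "post_extend", "beat_pre", "beat_post", "noise_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_record(path: str | Path, label: str = "unlabeled") -> AudioRecord:
    """Read a mono WAV file and peak-normalize it.

    PCM 16/24/32-bit and float encodings are accepted.  Stereo input,
    missing files and zero-length audio are errors.  After loading,
    max |sample| = 1 unless the file is all zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"mono required: {path} has {data.shape[1]} channels")
    if data.size == 0:
        raise ValueError(f"zero-length audio: {path}")
    samples = np.asarray(data, dtype=np.float64)
    if np.issubdtype(data.dtype, np.integer):
        samples /= float(np.iinfo(data.dtype).max)
    record = AudioRecord(samples, float(rate), source_id=path.stem, label=label)
    return record.peak_normalized()


def write_record(record: AudioRecord, path: str | Path) -> None:
    """Write a record as a 32-bit float WAV file."""
    wavfile.write(Path(path), int(round(record.rate)),
                  record.samples.astype(np.float32))


def resample(record: AudioRecord, target_rate: float) -> AudioRecord:
    """Polyphase FIR resampling to target_rate (anti-aliased).

    At equal rates the sample array is returned unchanged.  Duration is
    preserved to within one output sample period.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if record.samples.size == 0:
        raise ValueError("cannot resample an empty record")
    if target_rate == record.rate:
        return record
    ratio = Fraction(target_rate / record.rate).limit_denominator(1000)
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator)
    return replace(record, samples=out, rate=float(target_rate))
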