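"""Shannon-energy envelope and Korotkoff-sound segmentation.

The record is framed into 40 ms windows with 50 % overlap; each frame's
Shannon energy E_j = -(1/N) sum z_i^2 log z_i^2 (natural log, z scaled into
[-1, 1] by the record peak) emphasizes medium-amplitude components, which
makes the pulse train stand out against both weak noise and rare large
spikes.  The envelope is standardized to mean 0 / std 1 and pulses are
located as local maxima above a fraction of the envelope maximum.

Localization is then cleaned up with the rules a human annotator would
apply to a cuff recording: peaks closer than 100 ms belong to one sound and
are merged; isolated clicks far from the quasi-periodic train (friction of
the stethoscope diaphragm against the skin at the start/end of the
measurement) are rejected; the record span [B, E] extends 300 ms before the
first and 500 ms after the last retained anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelextrema

from .audio_io import AudioRecord, RunConfig, logger

__all__ = [
    "EnvelopeSeries", "AnchorSet", "RecordSegmentation",
    "frame_signal", "shannon_energy", "normalize_envelope",
    "locate_anchors", "merge_anchors", "reject_artifacts",
    "delimit_record", "slice_beats", "compute_envelope", "segment_record",
]

#: beat-to-beat gaps a physiological KS train can show (heart rate 30-200 bpm)
PERIODIC_GAP_RANGE = (0.3, 2.0)
#: an anchor farther than this from the periodic train is an artifact
ISOLATION_GAP = 2.0


@dataclass
class EnvelopeSeries:
    """Standardized Shannon energy per frame (mean 0, std 1 by construction)."""

    values: np.ndarray
    frame_times: np.ndarray
    frame_len: float
    hop: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must align")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if abs(float(np.mean(self.values))) > 1e-9:
            raise ValueError("envelope must be zero-mean")
        if abs(float(np.std(self.values)) - 1.0) > 1e-9:
            raise ValueError("envelope must have unit standard deviation")


@dataclass
class AnchorSet:
    """Detected pulse times (s) with their envelope heights, sorted in time."""

    times: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.times.shape != self.heights.shape:
            raise ValueError("times and heights must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("anchor times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RecordSegmentation:
    """Record delimiters B/E, anchors, per-beat windows and intervals Ti."""

    begin: float
    end: float
    anchors: AnchorSet
    beat_windows: list[tuple[float, float]]
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if len(self.anchors):
            if self.begin > self.anchors.times[0] or self.end < self.anchors.times[-1]:
                raise ValueError("[B, E] must cover all anchors")
        if self.intervals.size != max(len(self.anchors) - 1, 0):
            raise ValueError("need exactly len(anchors) - 1 intervals")


def frame_signal(record: AudioRecord, frame_len: float,
                 overlap: float) -> np.ndarray:
    """Split into overlapping frames; shape (n_frames, frame_samples).

    Frame count is floor((N - L) / H) + 1 with hop H = L * (1 - overlap);
    a record shorter than one frame is an error.
    """
    L = int(round(frame_len * record.rate))
    H = int(round(L * (1.0 - overlap)))
    if H < 1:
        raise ValueError("overlap too large: hop would be zero")
    N = record.samples.size
    if N < L:
        raise ValueError(f"record shorter than one frame ({N} < {L} samples)")
    n = (N - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n)[:, None]
    return record.samples[idx]


def shannon_energy(frame: np.ndarray) -> float:
    """Shannon energy -(1/N) sum z^2 ln z^2 of a frame scaled into [-1, 1].

    The frame is expected already normalized by the record-level peak
    (|z| <= 1); zero samples contribute 0 by the 0 log 0 convention, so an
    all-zero frame returns 0 and a frame of unit-magnitude samples returns
    0 (ln 1 = 0).
    """
    z = np.asarray(frame, dtype=np.float64)
    if z.size == 0:
        raise ValueError("frame must be non-empty")
    if np.max(np.abs(z)) > 1.0 + 1e-12:
        raise ValueError("frame must be normalized into [-1, 1]")
    z2 = z ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(z2 > 0, z2 * np.log(z2), 0.0)
    return float(-np.mean(terms))


def normalize_envelope(raw: np.ndarray, frame_times: np.ndarray,
                       frame_len: float, hop: float) -> EnvelopeSeries:
    """Standardize the raw Shannon-energy series to mean 0 / std 1.

    Population standard deviation; a constant series is degenerate.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size < 2:
        raise ValueError("need at least two frames")
    std = float(np.std(raw))
    if std == 0.0:
        raise ValueError("degenerate envelope: constant Shannon energy")
    values = (raw - np.mean(raw)) / std
    return EnvelopeSeries(values=values, frame_times=np.asarray(frame_times),
                          frame_len=frame_len, hop=hop)


def compute_envelope(record: AudioRecord, config: RunConfig | None = None) -> EnvelopeSeries:
    """Record -> standardized Shannon-energy envelope.

    The record is scaled by its global peak before per-frame Shannon
    energy, so the envelope is invariant to waveform gain.
    """
    config = config or RunConfig()
    normalized = record.peak_normalized()
    frames = frame_signal(normalized, config.frame_len, config.frame_overlap)
    raw = np.array([shannon_energy(f) for f in frames])
    L = int(round(config.frame_len * record.rate))
    H = int(round(L * (1.0 - config.frame_overlap)))
    times = (np.arange(frames.shape[0]) * H + L / 2.0) / record.rate
    return normalize_envelope(raw, times, config.frame_len, H / record.rate)


def locate_anchors(env: EnvelopeSeries, threshold_frac: float = 0.2) -> AnchorSet:
    """Local maxima of the envelope above threshold_frac * max(P).

    The envelope is standardized (zero mean), so candidates must also be
    positive; otherwise the relative threshold is ill-posed for near-flat
    envelopes.  A monotone envelope yields an empty set with a warning.
    """
    P = env.values
    peaks = argrelextrema(P, np.greater)[0]
    # plateau peaks (equal neighbours) are rare on real envelopes but cheap to keep
    if peaks.size == 0:
        warnings.warn("no local maxima in envelope; no anchors located")
        return AnchorSet(times=np.empty(0), heights=np.empty(0))
    threshold = threshold_frac * float(np.max(P))
    keep = peaks[(P[peaks] >= threshold) & (P[peaks] > 0)]
    return AnchorSet(times=env.frame_times[keep], heights=P[keep])


def merge_anchors(anchors: AnchorSet, min_gap: float = 0.100) -> AnchorSet:
    """Merge anchors closer than min_gap, greedily left to right.

    Within a merged cluster the anchor with the largest envelope height
    survives; surviving pairs are at least min_gap apart.
    """
    if len(anchors) == 0:
        return anchors
    times, heights = [], []
    ct, ch = [anchors.times[0]], [anchors.heights[0]]
    for t, h in zip(anchors.times[1:], anchors.heights[1:]):
        if t - ct[-1] < min_gap:
            ct.append(t)
            ch.append(h)
        else:
            best = int(np.argmax(ch))
            times.append(ct[best])
            heights.append(ch[best])
            ct, ch = [t], [h]
    best = int(np.argmax(ch))
    times.append(ct[best])
    heights.append(ch[best])
    merged = AnchorSet(times=np.array(times), heights=np.array(heights))
    assert len(merged) < 2 or np.min(np.diff(merged.times)) >= min_gap
    return merged


def reject_artifacts(anchors: AnchorSet, record_duration: float) -> AnchorSet:
    """Drop anchors isolated from the quasi-periodic KS train.

    The train is the longest run of consecutive anchors whose gaps all lie
    in PERIODIC_GAP_RANGE; anchors separated from that run by more than
    ISOLATION_GAP (friction clicks in the silent phases) are removed.
    Fewer than 3 anchors are returned unchanged with a warning.
    """
    if len(anchors) < 3:
        warnings.warn("fewer than 3 anchors; artifact rejection skipped")
        return anchors
    gaps = np.diff(anchors.times)
    lo, hi = PERIODIC_GAP_RANGE
    periodic = (gaps >= lo) & (gaps <= hi)
    # longest run of consecutive periodic gaps -> anchor index span [i, j]
    best_len, best_start = 0, 0
    run_start = None
    for k, ok in enumerate(periodic):
        if ok and run_start is None:
            run_start = k
        if (not ok or k == len(periodic) - 1) and run_start is not None:
            end = k if ok else k - 1
            if end - run_start + 1 > best_len:
                best_len, best_start = end - run_start + 1, run_start
            run_start = None
    if best_len == 0:
        warnings.warn("no quasi-periodic anchor run found; keeping all anchors")
        return anchors
    i, j = best_start, best_start + best_len  # anchors i..j inclusive
    t0, t1 = anchors.times[i], anchors.times[j]
    keep = (anchors.times >= t0 - ISOLATION_GAP) & (anchors.times <= t1 + ISOLATION_GAP)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.debug("rejected %d isolated anchors", dropped)
    return AnchorSet(times=anchors.times[keep], heights=anchors.heights[keep])


def delimit_record(anchors: AnchorSet, pre_extend: float, post_extend: float,
                   duration: float) -> tuple[float, float]:
    """Record span: B = first anchor - pre_extend, E = last + post_extend.

    Both clamped to [0, duration]; an empty anchor set means no KS was
    detected.
    """
    if len(anchors) == 0:
        raise ValueError("no KS detected: empty anchor set")
    B = max(0.0, float(anchors.times[0]) - pre_extend)
    E = min(duration, float(anchors.times[-1]) + post_extend)
    return B, E


def slice_beats(record: AudioRecord, anchors: AnchorSet,
                pre: float = 0.100, post: float = 0.300,
                begin: float | None = None,
                end: float | None = None) -> RecordSegmentation:
    """Per-beat windows [anchor - pre, anchor + post] and intervals Ti.

    Windows are clipped to the record; Ti is the successive difference of
    anchor times.  begin/end default to the clipped union of the windows.
    """
    if len(anchors) == 0:
        raise ValueError("no KS detected: empty anchor set")
    duration = record.duration
    windows = [(max(0.0, t - pre), min(duration, t + post)) for t in anchors.times]
    if begin is None:
        begin = windows[0][0]
    if end is None:
        end = windows[-1][1]
    return RecordSegmentation(begin=begin, end=end, anchors=anchors,
                              beat_windows=windows,
                              intervals=np.diff(anchors.times))


def segment_record(record: AudioRecord,
                   config: RunConfig | None = None) -> RecordSegmentation:
    """Full segmentation: envelope -> locate -> merge -> reject -> delimit.

    Returns beat windows of [-beat_pre, +beat_post] around each surviving
    anchor and the record span [B, E].
    """
    config = config or RunConfig()
    env = compute_envelope(record, config)
    anchors = locate_anchors(env, config.anchor_threshold_frac)
    anchors = merge_anchors(anchors, config.merge_gap)
    anchors = reject_artifacts(anchors, record.duration)
    B, E = delimit_record(anchors, config.pre_extend, config.post_extend,
                          record.duration)
    return slice_beats(record, anchors, config.beat_pre, config.beat_post,
                       begin=B, end=E)
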