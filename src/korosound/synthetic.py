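"""Synthetic Korotkoff-sound records with ground truth.

A cuff-deflation measurement is emulated as: a silent lead-in, a train of
short (< 150 ms) pulses at quasi-periodic beat times, and a silent tail.
Each pulse is a sum of exponentially damped sinusoids (an impact component
at 50-150 Hz with fast decay plus optional murmur components at higher
frequency), Gaussian-windowed; pulse amplitudes rise then fall across the
deflation, mimicking the appearance and disappearance of the sounds as
cuff pressure passes between systolic and diastolic.  Broadband Gaussian
noise is added at a controlled SNR, and occasional friction-artifact
clicks are placed in the silent phases.

Every random quantity flows from a single integer seed, so records and
cohorts are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio_io import AudioRecord

__all__ = ["SyntheticSpec", "generate_record", "generate_cohorts",
           "healthy_spec", "chf_spec"]

#: clicks are kept this far (s) from the beat train and the noise-estimation
#: window, emulating handling artifacts at the very start/end of a recording
CLICK_GUARD = 2.2
CLICK_LEAD_GUARD = 0.6


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic KS record.

    pulse_components is a list of (center frequency Hz, bandwidth Hz,
    relative amplitude); the bandwidth sets the exponential decay of the
    damped sinusoid (Lorentzian half-power width 1 / (pi * tau)).
    amplitude_profile = (peak position fraction, sharpness) shapes the
    rise-then-fall of pulse amplitudes across the train.  en_jitter is the
    fractional beat-to-beat spread of the component amplitudes, which
    controls the variability of the per-beat energy ratios.
    """

    n_beats: int = 22
    mean_period: float = 0.8
    period_jitter_sd: float = 0.06
    pulse_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(75.0, 15.0, 1.0), (150.0, 35.0, 0.8),
                                 (220.0, 60.0, 0.3)])
    amplitude_profile: tuple[float, float] = (0.45, 2.0)
    noise_snr_db: float = 20.0
    artifact_rate: float = 0.5
    lead_in: float = 3.5
    lead_out: float = 3.0
    en_jitter: float = 0.2
    rate: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_beats < 2:
            raise ValueError("need at least 2 beats")
        if self.mean_period <= 4 * self.period_jitter_sd:
            raise ValueError("mean_period must exceed 4 x period_jitter_sd")
        for f, bw, amp in self.pulse_components:
            if not 0 < f <= 400:
                raise ValueError("component frequencies must lie in (0, 400] Hz")
            if bw <= 0 or amp < 0:
                raise ValueError("component bandwidths must be positive, amplitudes >= 0")


def _pulse(spec: SyntheticSpec, rng: np.random.Generator,
           jitter: bool) -> tuple[np.ndarray, float]:
    """One pulse waveform (< 150 ms) and the offset of its amplitude peak."""
    t = np.arange(int(round(0.150 * spec.rate))) / spec.rate
    window = np.exp(-0.5 * ((t - 0.040) / 0.025) ** 2)
    x = np.zeros_like(t)
    for f, bw, amp in spec.pulse_components:
        if jitter and spec.en_jitter > 0:
            amp = amp * max(0.0, 1.0 + spec.en_jitter * rng.standard_normal())
        tau = 1.0 / (np.pi * bw)
        x += amp * np.exp(-t / tau) * np.sin(2 * np.pi * f * t)
    x *= window
    peak = float(np.max(np.abs(x)))
    if peak > 0:
        x /= peak
    return x, float(np.argmax(np.abs(x))) / spec.rate


def _click(rate: float, rng: np.random.Generator) -> np.ndarray:
    """A 10 ms broadband friction click."""
    t = np.arange(int(round(0.010 * rate))) / rate
    burst = rng.standard_normal(t.size) * np.exp(-t / 0.003)
    return burst / np.max(np.abs(burst))


def generate_record(spec: SyntheticSpec, seed: int) -> tuple[AudioRecord, np.ndarray]:
    """Synthesize one record; returns (record, ground-truth beat times).

    Beat times are lead_in + cumulative jittered periods; the returned
    truth times mark each pulse's amplitude peak (what the envelope anchor
    should find).  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    periods = spec.mean_period + spec.period_jitter_sd * rng.standard_normal(spec.n_beats - 1)
    onsets = spec.lead_in + np.concatenate([[0.0], np.cumsum(periods)])
    duration = onsets[-1] + 0.150 + spec.lead_out
    n = int(round(duration * spec.rate))
    x = np.zeros(n)

    peak_pos, sharpness = spec.amplitude_profile
    u = np.linspace(0.0, 1.0, spec.n_beats)
    amplitudes = np.exp(-sharpness * (u - peak_pos) ** 2)

    truth = np.empty(spec.n_beats)
    for k, onset in enumerate(onsets):
        pulse, peak_offset = _pulse(spec, rng, jitter=True)
        i = int(round(onset * spec.rate))
        j = min(n, i + pulse.size)
        x[i:j] += amplitudes[k] * pulse[: j - i]
        truth[k] = onset + peak_offset

    # broadband noise at the requested SNR relative to the pulse-train power
    active = x != 0
    signal_power = float(np.mean(x[active] ** 2)) if active.any() else 1.0
    noise_power = signal_power / (10.0 ** (spec.noise_snr_db / 10.0))
    x += np.sqrt(noise_power) * rng.standard_normal(n)

    # friction clicks in the outer silent phases, clear of the train
    n_clicks = rng.poisson(spec.artifact_rate)
    windows = []
    lead_window = (CLICK_LEAD_GUARD, spec.lead_in - CLICK_GUARD)
    if lead_window[1] > lead_window[0]:
        windows.append(lead_window)
    tail_window = (truth[-1] + CLICK_GUARD, duration - 0.05)
    if tail_window[1] > tail_window[0]:
        windows.append(tail_window)
    click_amp = 0.9 * float(np.max(amplitudes))
    for _ in range(int(n_clicks)):
        if not windows:
            break
        lo, hi = windows[rng.integers(len(windows))]
        t0 = rng.uniform(lo, hi)
        click = click_amp * _click(spec.rate, rng)
        i = int(round(t0 * spec.rate))
        j = min(n, i + click.size)
        x[i:j] += click[: j - i]

    record = AudioRecord(x, spec.rate, source_id=f"synthetic-{seed}")
    return record.peak_normalized(), truth


def healthy_spec() -> SyntheticSpec:
    """Healthy template: strong mid-band (100-200 Hz) content and large
    beat-to-beat variability of the energy ratios."""
    return SyntheticSpec(
        pulse_components=[(75.0, 15.0, 1.0), (150.0, 35.0, 0.8), (220.0, 60.0, 0.3)],
        en_jitter=0.25,
    )


def chf_spec() -> SyntheticSpec:
    """Reduced-output template: energy shifted from 100-200 Hz toward
    50-100 Hz and above 200 Hz, with reduced beat-to-beat variability."""
    return SyntheticSpec(
        pulse_components=[(70.0, 15.0, 1.3), (130.0, 30.0, 0.35), (240.0, 65.0, 0.6)],
        en_jitter=0.08,
    )


def _jitter_spec(spec: SyntheticSpec, rng: np.random.Generator,
                 frac: float = 0.10) -> SyntheticSpec:
    """Per-record +-frac jitter of the main spec parameters (within-class
    variance of a cohort)."""
    def j(v):
        return v * (1.0 + frac * rng.uniform(-1.0, 1.0))

    comps = [(f, j(bw), j(amp)) for f, bw, amp in spec.pulse_components]
    return replace(
        spec,
        mean_period=j(spec.mean_period),
        pulse_components=comps,
        amplitude_profile=(spec.amplitude_profile[0], j(spec.amplitude_profile[1])),
        noise_snr_db=j(spec.noise_snr_db),
    )


def generate_cohorts(n_per_class: int, healthy: SyntheticSpec,
                     patient: SyntheticSpec, seed: int
                     ) -> tuple[list[AudioRecord], list[np.ndarray]]:
    """Labeled two-class record set with per-record parameter jitter.

    Identical specs give a null cohort (labels carry no signal).  Returns
    (records, ground-truth beat time arrays), deterministic given seed.
    """
    if n_per_class < 2:
        raise ValueError("need at least 2 records per class")
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for label, spec in (("healthy", healthy), ("chf", patient)):
        for k in range(n_per_class):
            record_seed = int(rng.integers(2 ** 31))
            jittered = _jitter_spec(spec, np.random.default_rng(record_seed))
            rec, truth = generate_record(jittered, record_seed)
            rec.label = label
            rec.source_id = f"{label}-{k:03d}"
            records.append(rec)
            truths.append(truth)
    return records, truths
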