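"""Synthetic multichannel EEG with lobe-localized spike-wave seizures.

The generator emulates the structure of annotated clinical scalp-EEG
corpora: pink-noise background with alpha- and delta-band oscillations
on every channel, ~3 Hz spike-wave bursts injected only into the
channels of one chosen lobe, three burst-amplitude tiers (Low, Medium,
High), per-sample seizure masks, and subject-wise train/validation/test
partitions.  It makes every downstream stage testable without any
external download; it does not attempt physiological realism (no
dipole/forward modelling, no EMG or ocular artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .recording import LOBES, Annotation, EEGRecording, lobe_channel_indices

__all__ = [
    "SynthConfig",
    "SeizureEvent",
    "LabeledRecording",
    "LabeledDataset",
    "DEFAULT_CHANNELS",
    "ACTIVITY_FACTORS",
    "generate_background",
    "spike_wave_burst",
    "inject_seizure",
    "generate_recording",
    "generate_dataset",
    "split_subjects",
]

#: Eight bipolar 10-20 channels covering all four lobes (two per lobe).
DEFAULT_CHANNELS = [
    "FP1-F7",
    "FP2-F8",
    "T7-P7",
    "T8-P8",
    "P7-O1",
    "P8-O2",
    "O1-A1",
    "O2-A2",
]

#: Burst-amplitude multipliers per activity tier.  The tier spacing is a
#: free design choice: wide enough that tertile binning of band-power
#: features separates the tiers.
ACTIVITY_FACTORS = {"Low": 1.0, "Medium": 2.0, "High": 3.5}


@dataclass
class SeizureEvent:
    onset: float
    offset: float
    lobe: str
    level: str = "Medium"

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("seizure event must have onset < offset")
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")
        if self.level not in ACTIVITY_FACTORS:
            raise ValueError(f"activity level must be one of {list(ACTIVITY_FACTORS)}")


@dataclass
class SynthConfig:
    """Parameters of one synthetic subject recording.

    Amplitude-like fields are RMS amplitudes in microvolts: `noise_level`
    scales the pink-noise floor, the `background_*_power` weights scale
    narrowband alpha (8-13 Hz) and delta (0.5-4 Hz) oscillations, and
    `burst_amplitude` is the unit-tier spike-wave RMS (multiplied by the
    activity-tier factor).
    """

    sampling_rate: float = 256.0
    channel_names: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    duration: float = 120.0
    seizure_events: list = field(default_factory=list)
    background_alpha_power: float = 2.0
    background_delta_power: float = 2.0
    noise_level: float = 5.0
    burst_amplitude: float = 20.0
    seed: int = 0
    subject: str = "S000"

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        lobes_present = {
            lobe for lobe, idx in lobe_channel_indices(self.channel_names).items() if idx
        }
        for ev in self.seizure_events:
            if ev.offset > self.duration:
                raise ValueError("seizure event extends past recording duration")
            if ev.lobe not in lobes_present:
                raise ValueError(f"no channel maps to lobe {ev.lobe!r}")

    @property
    def n_channels(self):
        return len(self.channel_names)


@dataclass
class LabeledRecording:
    """A recording plus ground truth: per-lobe sample masks and event labels."""

    recording: EEGRecording
    lobe_masks: dict  # lobe -> boolean array over samples
    events: list  # list of SeizureEvent

    @property
    def seizure_mask(self):
        mask = np.zeros(self.recording.n_samples, dtype=bool)
        for m in self.lobe_masks.values():
            mask |= m
        return mask


@dataclass
class LabeledDataset:
    train: list
    validation: list
    test: list

    def partitions(self):
        return {"train": self.train, "validation": self.validation, "test": self.test}


def _narrowband(rng, n, rate, lo, hi):
    """Unit-RMS band-limited noise (4th-order Butterworth on white noise)."""
    lo = max(lo, 1e-3)
    sos = sps.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink(rng, n):
    """Unit-RMS 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_background(config):
    """Pink-noise background plus alpha- and delta-band oscillations.

    Each channel gets an independent seeded draw; identical configs
    (including the seed) produce bit-identical recordings.
    """
    rate = config.sampling_rate
    n = int(round(config.duration * rate))
    if n < 1:
        raise ValueError("recording must contain at least one sample")
    rng = np.random.default_rng(config.seed)
    data = np.zeros((config.n_channels, n))
    for ch in range(config.n_channels):
        if config.noise_level > 0:
            data[ch] += config.noise_level * _pink(rng, n)
        else:
            rng.standard_normal(n)  # keep stream alignment across configs
        if config.background_alpha_power > 0:
            data[ch] += config.background_alpha_power * _narrowband(rng, n, rate, 8.0, 13.0)
        else:
            rng.standard_normal(n)
        if config.background_delta_power > 0:
            data[ch] += config.background_delta_power * _narrowband(rng, n, rate, 0.5, 4.0)
        else:
            rng.standard_normal(n)
    return EEGRecording(
        data=data,
        sampling_rate=rate,
        channel_names=list(config.channel_names),
        subject=config.subject,
    )


def spike_wave_burst(duration, rate, spike_rate=3.0):
    """Unit-RMS spike-and-wave train: biphasic spike (Gaussian derivative)
    followed by a slow half-wave, repeated at `spike_rate` Hz, with a
    Tukey taper at the burst edges."""
    n = int(round(duration * rate))
    cycle = int(round(rate / spike_rate))
    t = np.arange(cycle) / rate
    spike_w = 0.015  # spike half-width, seconds
    tc = t - 0.05
    spike = -tc * np.exp(-0.5 * (tc / spike_w) ** 2) / spike_w
    wave_len = cycle - int(0.1 * rate)
    wave = np.zeros(cycle)
    wave[int(0.1 * rate) :] = -0.6 * np.sin(np.pi * np.arange(wave_len) / wave_len)
    template = spike + wave
    burst = np.tile(template, int(np.ceil(n / cycle)))[:n]
    burst *= sps.windows.tukey(n, alpha=0.1)
    rms = np.sqrt(np.mean(burst**2))
    return burst / rms if rms > 0 else burst


def inject_seizure(rec_or_labeled, event, burst_amplitude=20.0):
    """Add a ~3 Hz spike-wave burst to the channels of `event.lobe` only.

    Amplitude is `burst_amplitude` x the activity-tier factor
    (Low 1.0 < Medium 2.0 < High 3.5).  Returns a LabeledRecording with
    the per-lobe sample mask set over the event interval (the mask is
    set even at zero amplitude).
    """
    if isinstance(rec_or_labeled, LabeledRecording):
        labeled = rec_or_labeled
        rec = labeled.recording
    else:
        rec = rec_or_labeled
        labeled = LabeledRecording(
            recording=rec,
            lobe_masks={lobe: np.zeros(rec.n_samples, dtype=bool) for lobe in LOBES},
            events=[],
        )
    if event.onset < 0 or event.offset > rec.duration + 1e-9:
        raise ValueError("seizure event interval outside the recording")
    lobe_idx = lobe_channel_indices(rec.channel_names)
    channels = lobe_idx.get(event.lobe, [])
    if not channels:
        raise ValueError(f"no channel maps to lobe {event.lobe!r}")
    rate = rec.sampling_rate
    i0 = int(round(event.onset * rate))
    i1 = int(round(event.offset * rate))
    amp = burst_amplitude * ACTIVITY_FACTORS[event.level]
    if amp > 0:
        burst = amp * spike_wave_burst((i1 - i0) / rate, rate)
        for ch in channels:
            rec.data[ch, i0:i1] += burst
    labeled.lobe_masks[event.lobe][i0:i1] = True
    labeled.events.append(event)
    rec.annotations.append(
        Annotation(event.onset, event.offset, "seizure", lobe=event.lobe, level=event.level)
    )
    return labeled


def generate_recording(config):
    """Background plus all configured seizure events, fully seeded."""
    rec = generate_background(config)
    labeled = LabeledRecording(
        recording=rec,
        lobe_masks={lobe: np.zeros(rec.n_samples, dtype=bool) for lobe in LOBES},
        events=[],
    )
    for event in config.seizure_events:
        labeled = inject_seizure(labeled, event, burst_amplitude=config.burst_amplitude)
    return labeled


def split_subjects(n_subjects, seed=0):
    """Subject-wise 70/10/20 split (by count, rounded), at least one
    subject per partition; partitions are disjoint by construction."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a 3-way subject-wise split")
    order = list(np.random.default_rng(seed).permutation(n_subjects))
    n_val = max(1, int(round(0.1 * n_subjects)))
    n_test = max(1, int(round(0.2 * n_subjects)))
    n_train = n_subjects - n_val - n_test
    if n_train < 1:
        raise ValueError("too few subjects to keep one in every partition")
    return (
        sorted(order[:n_train]),
        sorted(order[n_train : n_train + n_val]),
        sorted(order[n_train + n_val :]),
    )


def generate_dataset(
    n_subjects=10,
    duration=120.0,
    events_per_subject=2,
    sampling_rate=256.0,
    channel_names=None,
    seed=0,
    base_config=None,
):
    """Generate `n_subjects` labeled recordings and split them 70/10/20
    subject-wise.  Each subject receives `events_per_subject` seizure
    bursts with seeded lobes, tiers, onsets, and durations (8-16 s),
    spaced so that inter-ictal stretches remain on both sides."""
    if channel_names is None:
        channel_names = list(DEFAULT_CHANNELS)
    base = base_config or SynthConfig()
    rng = np.random.default_rng(seed)
    recordings = []
    for s in range(n_subjects):
        events = []
        # place events inside equal time slots to keep them apart
        slot = duration / events_per_subject
        for k in range(events_per_subject):
            ev_dur = rng.uniform(8.0, 16.0)
            lo = k * slot + 0.35 * slot
            onset = lo + rng.uniform(0.0, max(slot * 0.1, 1.0))
            events.append(
                SeizureEvent(
                    onset=float(onset),
                    offset=float(min(onset + ev_dur, (k + 1) * slot - 1.0)),
                    # balanced design: lobes cycle across subjects/events so
                    # every lobe is represented in every partition
                    lobe=LOBES[(s * events_per_subject + k) % len(LOBES)],
                    level=list(ACTIVITY_FACTORS)[int(rng.integers(3))],
                )
            )
        config = replace(
            base,
            sampling_rate=sampling_rate,
            channel_names=list(channel_names),
            duration=duration,
            seizure_events=events,
            seed=int(rng.integers(2**31 - 1)),
            subject=f"S{s:03d}",
        )
        recordings.append(generate_recording(config))
    tr, va, te = split_subjects(n_subjects, seed=seed)
    return LabeledDataset(
        train=[recordings[i] for i in tr],
        validation=[recordings[i] for i in va],
        test=[recordings[i] for i in te],
    )
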