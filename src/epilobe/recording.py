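"""Core EEG containers: recordings, annotations, channel-to-lobe mapping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

LOBES = ("frontal", "temporal", "parietal", "occipital")

#: 10-20 electrode prefix -> lobe of the first electrode of a bipolar pair.
#: FP must be checked before F; C (central) is excluded from lobe labels.
_PREFIX_RULES = (
    ("FP", "frontal"),
    ("F", "frontal"),
    ("T", "temporal"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("C", "excluded"),
)


@dataclass
class Annotation:
    onset: float
    offset: float
    label: str = "seizure"
    lobe: str | None = None
    level: str | None = None

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError(f"annotation offset {self.offset} <= onset {self.onset}")


@dataclass
class EEGRecording:
    """Multichannel EEG: channels x samples, microvolts."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list
    annotations: list = field(default_factory=list)
    subject: str = "S000"

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} channel names"
            )
        for ann in self.annotations:
            if ann.onset < 0 or ann.offset > self.duration + 1e-9:
                raise ValueError(
                    f"annotation [{ann.onset}, {ann.offset}] outside recording "
                    f"of duration {self.duration:.3f}s"
                )

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    @property
    def duration(self):
        return self.n_samples / self.sampling_rate

    def copy(self, data=None):
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            annotations=list(self.annotations),
            subject=self.subject,
        )


def map_channel_to_lobe(name):
    """Lobe of a 10-20 channel (or bipolar pair) by first-electrode prefix.

    FP*/F* -> frontal, T* -> temporal, P* -> parietal, O* -> occipital,
    C* -> excluded.  Unknown prefixes are excluded (logged), never raise.
    """
    first = name.strip().upper().split("-")[0]
    for prefix, lobe in _PREFIX_RULES:
        if first.startswith(prefix):
            return lobe
    logger.warning("channel %r has no recognized 10-20 prefix; excluded", name)
    return "excluded"


def channel_lobe_map(channel_names):
    """Total, deterministic mapping channel name -> lobe/excluded."""
    return {name: map_channel_to_lobe(name) for name in channel_names}


def lobe_channel_indices(channel_names):
    """Indices of channels per lobe (excluded channels dropped)."""
    out = {lobe: [] for lobe in LOBES}
    for i, name in enumerate(channel_names):
        lobe = map_channel_to_lobe(name)
        if lobe in out:
            out[lobe].append(i)
    return out
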