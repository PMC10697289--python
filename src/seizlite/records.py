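"""Core data containers shared across the pipeline.

The unit every input source is harmonized into is the :class:`Record`: a
single-channel, fixed-rate, fixed-length labeled EEG trace. Multi-channel
sources are first held as a :class:`RawRecording` and reduced to records by
the ingest module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: sampling rate every record is harmonized to (Hz)
TARGET_RATE_HZ = 173.61
#: number of samples in a harmonized record
RECORD_LENGTH = 4097


class ClassLabel(IntEnum):
    """Three-class seizure-detection target."""

    NORMAL = 0
    INTERICTAL = 1
    ICTAL = 2

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown class label {name!r}") from None


@dataclass
class Record:
    """One single-channel, fixed-length, fixed-rate labeled EEG trace."""

    samples: np.ndarray
    sampling_rate_hz: float
    label: ClassLabel
    provenance: tuple[str, int] = ("", 0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("record samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("record contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.label = ClassLabel(self.label)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz


@dataclass
class RawRecording:
    """Multi-channel recording plus seizure-interval annotations.

    Intervals are half-open ``[start_s, end_s)`` in seconds from recording
    onset.
    """

    samples: np.ndarray  # (n_channels, n_times)
    sampling_rate_hz: float
    channel_names: list[str] = field(default_factory=list)
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        dur = self.duration_s
        for start, end in self.seizure_intervals:
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"seizure interval ({start}, {end}) outside [0, {dur:.3f}]"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.sampling_rate_hz


@dataclass
class DatasetManifest:
    """Per-class counts and provenance of a merged, harmonized dataset."""

    records: list[Record]
    harmonization: dict = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[ClassLabel, int]:
        counts = {label: 0 for label in ClassLabel}
        for rec in self.records:
            counts[rec.label] += 1
        return counts

    @property
    def provenance(self) -> list[tuple[str, int]]:
        return [rec.provenance for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_dict(self) -> dict:
        return {
            "n_records": len(self.records),
            "class_counts": {lab.name.lower(): n for lab, n in self.class_counts.items()},
            "provenance": [list(p) for p in self.provenance],
            "harmonization": self.harmonization,
        }
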