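"""Class-conditional surrogate EEG generation and on-disk fixtures.

The generator exists so the whole pipeline — readers, harmonization,
augmentation, training — can be exercised without downloading the public
recordings. The three class recipes follow textbook EEG phenomenology:

* ``normal``: broadband noise plus a low-amplitude ~10 Hz posterior alpha
  rhythm;
* ``interictal``: the normal recipe plus sparse high-amplitude biphasic
  spike transients arriving as a Poisson process;
* ``ictal``: a high-amplitude ~3 Hz rhythmic discharge with harmonics
  (spike-and-wave-like) riding on noise.

Amplitudes are unitless "µV-like"; no physical calibration is attempted.
Every function is a pure function of its spec and seed; per-record seeds are
derived with numpy's SeedSequence spawn scheme, which is a documented
counter-based derivation stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import edf
from .records import RECORD_LENGTH, TARGET_RATE_HZ, ClassLabel, Record


@dataclass
class SyntheticSpec:
    """Parameters of one class-conditional record generator."""

    class_label: ClassLabel
    base_noise_sd: float = 1.0
    dominant_freq_hz: float = 10.0
    rhythm_amplitude: float = 1.5
    spike_rate_hz: float = 0.0
    record_length: int = RECORD_LENGTH
    sampling_rate_hz: float = TARGET_RATE_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_label = ClassLabel(self.class_label)
        if self.record_length < 1:
            raise ValueError("record_length must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.dominant_freq_hz < self.sampling_rate_hz / 2:
            raise ValueError("dominant_freq_hz must be below the Nyquist rate")
        if self.spike_rate_hz < 0:
            raise ValueError("spike_rate_hz must be non-negative")
        if self.base_noise_sd < 0 or self.rhythm_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def default_spec(label: ClassLabel, seed: int = 0) -> SyntheticSpec:
    """Default per-class recipes.

    The interictal spike rate of 2 Hz models frequent interictal discharges;
    it is high enough that essentially every window longer than ~1.5 s
    contains at least one spike, which is what makes the interictal class
    separable from normal at small window sizes.
    """
    label = ClassLabel(label)
    if label is ClassLabel.NORMAL:
        return SyntheticSpec(label, base_noise_sd=1.0, dominant_freq_hz=10.0,
                             rhythm_amplitude=1.5, seed=seed)
    if label is ClassLabel.INTERICTAL:
        return SyntheticSpec(label, base_noise_sd=1.0, dominant_freq_hz=10.0,
                             rhythm_amplitude=1.5, spike_rate_hz=2.0, seed=seed)
    return SyntheticSpec(label, base_noise_sd=1.0, dominant_freq_hz=3.0,
                         rhythm_amplitude=5.0, seed=seed)


def _biphasic_spike(fs_hz: float) -> np.ndarray:
    """~70 ms biphasic transient (first derivative of a Gaussian)."""
    half = max(int(round(0.035 * fs_hz)), 2)
    t = np.arange(-half, half + 1) / fs_hz
    sigma = 0.012  # s
    wave = -t / sigma * np.exp(0.5 - (t / sigma) ** 2 / 2.0)
    return wave / np.max(np.abs(wave))


def generate_record(spec: SyntheticSpec) -> Record:
    """Generate one surrogate record; a pure function of the spec."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.record_length
    fs = spec.sampling_rate_hz
    t = np.arange(n) / fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = rng.normal(0.0, spec.base_noise_sd, size=n)
    x += spec.rhythm_amplitude * np.sin(2.0 * np.pi * spec.dominant_freq_hz * t + phase)

    if spec.class_label is ClassLabel.ICTAL:
        # rhythmic discharge with decreasing-amplitude harmonics
        for mult, amp in ((2, 0.4), (3, 0.2)):
            if mult * spec.dominant_freq_hz < fs / 2:
                x += (spec.rhythm_amplitude * amp
                      * np.sin(2.0 * np.pi * mult * spec.dominant_freq_hz * t
                               + mult * phase))

    if spec.spike_rate_hz > 0:
        spike = _biphasic_spike(fs) * 8.0 * spec.base_noise_sd
        duration = n / fs
        n_events = rng.poisson(spec.spike_rate_hz * duration)
        starts = np.sort(rng.uniform(0.0, duration, size=n_events))
        polarity = rng.choice([-1.0, 1.0], size=n_events)
        for start, pol in zip(starts, polarity):
            i0 = int(round(start * fs))
            i1 = min(i0 + spike.shape[0], n)
            x[i0:i1] += pol * spike[: i1 - i0]

    return Record(
        samples=x,
        sampling_rate_hz=fs,
        label=spec.class_label,
        provenance=(f"synthetic/{spec.class_label.name.lower()}/seed{spec.seed}", 0),
    )


def generate_dataset(
    counts_per_class: dict[ClassLabel, int],
    seed: int = 0,
    specs: dict[ClassLabel, SyntheticSpec] | None = None,
) -> list[Record]:
    """Generate the requested number of records per class.

    Records are emitted in label order (normal, interictal, ictal), each with
    a distinct seed spawned from ``seed``; the same seed always reproduces
    the identical dataset.
    """
    counts = {ClassLabel(k): int(v) for k, v in counts_per_class.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("per-class counts must be non-negative")
    total = sum(counts.values())
    children = np.random.SeedSequence(seed).spawn(total)
    records: list[Record] = []
    i = 0
    for label in ClassLabel:
        base = (specs or {}).get(label) or default_spec(label)
        for _ in range(counts.get(label, 0)):
            child_seed = int(children[i].generate_state(1, np.uint32)[0])
            records.append(generate_record(replace(base, seed=child_seed)))
            i += 1
    return records


def write_bonn_ascii(record: Record, path: str | Path) -> None:
    """Write a record in the single-column integer ASCII layout."""
    values = np.round(record.samples).astype(np.int64)
    with Path(path).open("w") as fh:
        for v in values:
            fh.write(f"{int(v)}\n")


def write_minimal_edf(
    channels: np.ndarray,
    fs_hz: float,
    seizure_intervals: list[tuple[float, float]],
    path: str | Path,
) -> tuple[Path, Path]:
    """Write an EDF fixture plus its plain-text seizure annotation sidecar.

    Returns the (edf_path, annotation_path) pair; the annotation file is
    ``<path>.seizures.txt``.
    """
    path = Path(path)
    edf.write_edf(channels, fs_hz, path)
    ann_path = path.with_suffix(path.suffix + ".seizures.txt")
    edf.write_annotations(seizure_intervals, ann_path)
    return path, ann_path


def make_multichannel_fixture(
    n_channels: int = 2,
    duration_s: float = 10.0,
    fs_hz: float = 256.0,
    seizure_intervals: list[tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Surrogate multi-channel scalp EEG with an ictal discharge inside the
    annotated intervals and alpha-band background elsewhere."""
    if seizure_intervals is None:
        seizure_intervals = [(duration_s * 0.4, duration_s * 0.6)]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    in_seizure = np.zeros(n, dtype=bool)
    for start, end in seizure_intervals:
        in_seizure[int(start * fs_hz): int(end * fs_hz)] = True
    channels = np.empty((n_channels, n))
    for ch in range(n_channels):
        x = rng.normal(0.0, 1.0, size=n)
        x += 1.5 * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        x[in_seizure] += 5.0 * np.sin(2 * np.pi * 3.0 * t[in_seizure]
                                      + rng.uniform(0, 2 * np.pi))
        channels[ch] = x
    return channels, seizure_intervals
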