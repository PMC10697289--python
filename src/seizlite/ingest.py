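"""Read both source formats and harmonize them into labeled records.

Two public EEG collections are supported structurally:

* single-channel ASCII records of 4097 integer samples at 173.61 Hz,
  organized in subsets A-E (A, B: healthy scalp EEG; C, D: interictal
  intracranial EEG; E: ictal intracranial EEG);
* multi-channel EDF at 256 Hz with seizure-interval annotations.

Harmonization pipeline for the multi-channel source: channel-average ->
resample to 173.61 Hz -> split into ictal/interictal stretches using the
annotations -> chunk into 4097-sample records -> merge with the ASCII
records by class.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from pathlib import Path

import numpy as np
import scipy.signal

from . import edf
from .records import RECORD_LENGTH, TARGET_RATE_HZ, ClassLabel, DatasetManifest, RawRecording, Record

#: subset letter -> class label for the ASCII source
SUBSET_LABELS: dict[str, ClassLabel] = {
    "A": ClassLabel.NORMAL,
    "B": ClassLabel.NORMAL,
    "C": ClassLabel.INTERICTAL,
    "D": ClassLabel.INTERICTAL,
    "E": ClassLabel.ICTAL,
}


def read_bonn_file(
    path: str | Path,
    subset_letter: str,
    record_length: int = RECORD_LENGTH,
    strict_length: bool = True,
) -> Record:
    """Read a one-sample-per-line ASCII record and map its subset to a label.

    In strict mode a file whose length differs from ``record_length`` is an
    error; otherwise longer files are truncated and shorter ones rejected.
    """
    subset = subset_letter.strip().upper()
    if subset not in SUBSET_LABELS:
        raise ValueError(f"unknown subset letter {subset!r}; expected one of A-E")
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric sample {line!r}") from None
    if not values:
        raise ValueError(f"{path}: empty record file")
    if len(values) != record_length:
        if strict_length or len(values) < record_length:
            raise ValueError(
                f"{path}: expected {record_length} samples, found {len(values)}"
            )
        values = values[:record_length]
    return Record(
        samples=np.asarray(values),
        sampling_rate_hz=TARGET_RATE_HZ,
        label=SUBSET_LABELS[subset],
        provenance=(f"{subset}/{path.name}", 0),
    )


def read_edf(path: str | Path, annotation_path: str | Path | None = None) -> RawRecording:
    """Read an EDF file (via mne) plus an optional seizure annotation sidecar."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed headers
        raise ValueError(f"{path}: not a readable EDF file ({exc})") from exc
    data = raw.get_data(units="uV")
    fs = float(raw.info["sfreq"])
    intervals: list[tuple[float, float]] = []
    if annotation_path is not None:
        intervals = edf.read_annotations(annotation_path)
        duration = data.shape[1] / fs
        for start, end in intervals:
            if end > duration + 1e-9:
                raise ValueError(
                    f"annotation ({start}, {end}) extends past the {duration:.3f}s recording"
                )
    return RawRecording(
        samples=data,
        sampling_rate_hz=fs,
        channel_names=list(raw.ch_names),
        seizure_intervals=intervals,
        source_id=path.name,
    )


def average_channels(raw: RawRecording) -> np.ndarray:
    """Element-wise mean across channels; length and rate are preserved."""
    if raw.n_channels < 1:
        raise ValueError("recording has no channels")
    return raw.samples.mean(axis=0)


def resample(series: np.ndarray, fs_in: float, fs_out: float = TARGET_RATE_HZ) -> np.ndarray:
    """Rational-ratio polyphase resampling with anti-aliasing.

    The output length honours ``round(n_in * fs_out / fs_in)`` exactly; the
    polyphase ratio is a ``limit_denominator`` approximation of the exact
    (possibly coprime-huge) ratio, trimmed or edge-padded by at most a sample
    to meet the length contract.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    series = np.asarray(series, dtype=np.float64)
    if fs_in == fs_out:
        return series.copy()
    n_out = int(round(series.shape[0] * fs_out / fs_in))
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    out = scipy.signal.resample_poly(series, frac.numerator, frac.denominator)
    if out.shape[0] > n_out:
        out = out[:n_out]
    elif out.shape[0] < n_out:
        out = np.pad(out, (0, n_out - out.shape[0]), mode="edge")
    return out


def extract_class_series(
    series: np.ndarray,
    fs_hz: float,
    seizure_intervals: list[tuple[float, float]],
    margin_s: float = 0.0,
) -> dict[ClassLabel, np.ndarray]:
    """Split a harmonized single-channel series into ictal / interictal parts.

    ``series`` is the channel-averaged, resampled signal; the seizure
    intervals (seconds) are mapped onto its rate. Ictal samples are those
    inside any annotated interval; interictal samples are those outside every
    interval dilated by ``margin_s`` on each side. With margin 0 the two
    parts partition the series.
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[0]
    ictal_mask = np.zeros(n, dtype=bool)
    excluded = np.zeros(n, dtype=bool)
    for start, end in seizure_intervals:
        i0, i1 = int(np.floor(start * fs_hz)), int(np.ceil(end * fs_hz))
        ictal_mask[max(i0, 0): min(i1, n)] = True
        j0 = int(np.floor((start - margin_s) * fs_hz))
        j1 = int(np.ceil((end + margin_s) * fs_hz))
        excluded[max(j0, 0): min(j1, n)] = True
    return {
        ClassLabel.ICTAL: series[ictal_mask],
        ClassLabel.INTERICTAL: series[~excluded],
    }


def chunk_to_records(
    series: np.ndarray,
    label: ClassLabel,
    record_length: int = RECORD_LENGTH,
    sampling_rate_hz: float = TARGET_RATE_HZ,
    source_id: str = "",
) -> list[Record]:
    """Cut consecutive non-overlapping full-length chunks; the trailing
    remainder shorter than ``record_length`` is discarded."""
    series = np.asarray(series, dtype=np.float64)
    n_chunks = series.shape[0] // record_length
    return [
        Record(
            samples=series[i * record_length: (i + 1) * record_length],
            sampling_rate_hz=sampling_rate_hz,
            label=label,
            provenance=(source_id, i * record_length),
        )
        for i in range(n_chunks)
    ]


def merge_datasets(*record_groups: list[Record], harmonization: dict | None = None) -> DatasetManifest:
    """Merge harmonized record groups into one manifest.

    All records must share length and sampling rate; ordering is
    deterministic (source id, then offset, then label).
    """
    records = [rec for group in record_groups for rec in group]
    manifest = DatasetManifest(records=[], harmonization=harmonization or {})
    if not records:
        return manifest
    length = len(records[0])
    rate = records[0].sampling_rate_hz
    for rec in records:
        if len(rec) != length or rec.sampling_rate_hz != rate:
            raise ValueError(
                "harmonization error: records differ in length or sampling rate "
                f"({len(rec)} @ {rec.sampling_rate_hz} vs {length} @ {rate})"
            )
    records.sort(key=lambda r: (r.provenance[0], r.provenance[1], int(r.label)))
    manifest.records = records
    manifest.harmonization.setdefault("record_length", length)
    manifest.harmonization.setdefault("sampling_rate_hz", rate)
    return manifest


def harmonize_edf_recording(
    raw: RawRecording,
    margin_s: float = 0.0,
    record_length: int = RECORD_LENGTH,
) -> list[Record]:
    """Full multi-channel harmonization: average, resample, extract, chunk."""
    mean_series = average_channels(raw)
    series = resample(mean_series, raw.sampling_rate_hz, TARGET_RATE_HZ)
    parts = extract_class_series(
        series, TARGET_RATE_HZ, raw.seizure_intervals, margin_s=margin_s
    )
    records: list[Record] = []
    for label, part in parts.items():
        records.extend(
            chunk_to_records(
                part, label, record_length,
                sampling_rate_hz=TARGET_RATE_HZ,
                source_id=f"{raw.source_id}/{label.name.lower()}",
            )
        )
    if not records:
        warnings.warn(f"{raw.source_id}: no full-length records after harmonization")
    return records
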