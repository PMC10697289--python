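"""Minimal EDF (European Data Format) writing and annotation sidecars.

Only the subset of EDF needed for fixtures and round-trip testing is
implemented: one or more signals at a common integer sampling rate, 16-bit
digital samples, 1-second data records. Seizure annotations are kept in a
plain-text sidecar file (one "start_s<TAB>end_s" line per interval), the
layout used by scalp-EEG seizure summaries. Reading goes through :mod:`mne`.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value covered by one digital step of the 16-bit range."""
    return (phys_max - phys_min) / (DIG_MAX - DIG_MIN)


def write_edf(
    channels: np.ndarray,
    fs_hz: float,
    path: str | Path,
    channel_names: list[str] | None = None,
    physical_dimension: str = "uV",
) -> None:
    """Write a channels x time matrix as a standards-conformant EDF file.

    The physical range is taken from the data (symmetric, with a small
    margin) so the quantization error is at most one digital step of
    ``(phys_max - phys_min) / 65535``.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=np.float64))
    n_ch, n_times = channels.shape
    if n_ch < 1 or n_times < 1:
        raise ValueError("need at least one channel and one sample")
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if abs(fs_hz - round(fs_hz)) > 1e-9:
        raise ValueError("minimal EDF writer requires an integer sampling rate")
    fs = int(round(fs_hz))
    if n_times % fs != 0:
        raise ValueError(
            "signal length must be a whole number of seconds "
            f"(got {n_times} samples at {fs} Hz)"
        )
    n_records = n_times // fs
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]

    amax = float(np.max(np.abs(channels)))
    if amax == 0.0:
        amax = 1.0
    phys_max = amax
    phys_min = -amax
    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.round((channels - phys_min) * scale + DIG_MIN)
    if digital.min() < DIG_MIN or digital.max() > DIG_MAX:
        raise ValueError("quantization overflow: amplitudes exceed physical range")
    digital = digital.astype("<i2")

    now = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field(str(n_ch), 4),
        ]
    )
    sig_fields = [
        ("label", 16, [name[:16] for name in channel_names]),
        ("transducer", 80, [""] * n_ch),
        ("dimension", 8, [physical_dimension] * n_ch),
        ("phys_min", 8, [f"{phys_min:.6g}"[:8] for _ in range(n_ch)]),
        ("phys_max", 8, [f"{phys_max:.6g}"[:8] for _ in range(n_ch)]),
        ("dig_min", 8, [str(DIG_MIN)] * n_ch),
        ("dig_max", 8, [str(DIG_MAX)] * n_ch),
        ("prefilter", 80, [""] * n_ch),
        ("n_samples", 8, [str(fs)] * n_ch),
        ("reserved", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        _field(v, width) for _name, width, values in sig_fields for v in values
    )

    path = Path(path)
    with path.open("wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        for rec in range(n_records):
            sl = slice(rec * fs, (rec + 1) * fs)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())


def write_annotations(
    seizure_intervals: list[tuple[float, float]], path: str | Path
) -> None:
    """Write seizure intervals as 'start_s<TAB>end_s' lines."""
    with Path(path).open("w") as fh:
        for start, end in seizure_intervals:
            fh.write(f"{float(start):g}\t{float(end):g}\n")


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    intervals: list[tuple[float, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'start_s end_s', got {line!r}")
        start, end = float(parts[0]), float(parts[1])
        if not start < end:
            raise ValueError(f"{path}:{lineno}: interval start must precede end")
        intervals.append((start, end))
    return intervals
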