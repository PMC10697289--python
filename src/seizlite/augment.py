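"""Sliding-window segmentation and SMOTE class balancing.

Segmentation turns each long record into ``floor((l - w) / s) + 1`` short
overlapping windows. SMOTE (Synthetic Minority Over-sampling Technique)
grows every minority class to the majority count by linear interpolation
``x_new = x_i + lambda * (x_j - x_i)`` between a minority sample and one of
its k nearest same-class neighbours, with lambda ~ Uniform[0, 1].

The per-class sampling amount is the majority/minority count ratio; its
fractional part is realized as a per-reference probability of one extra
sample, then the result is trimmed (newest synthetic samples first) or
topped up deterministically under the seed to hit the exact majority count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance

from .records import ClassLabel, Record


@dataclass
class WindowConfig:
    """Sliding-window parameters (samples)."""

    window_size: int = 256
    step_size: int = 32

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step_size < 1:
            raise ValueError("window_size and step_size must be >= 1")


@dataclass
class SmoteConfig:
    """Neighbour count and balancing policy for the oversampler."""

    k_nn: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_nn < 1:
            raise ValueError("k_nn must be >= 1")


@dataclass
class SegmentSet:
    """Windowed fixed-length training instances with provenance.

    ``parents`` holds one ``(source_id, start_offset)`` pair per segment;
    SMOTE-generated segments carry a fractional offset (midpoint marker) and
    ``synthetic_flags`` True.
    """

    values: np.ndarray  # (n_segments, window)
    labels: np.ndarray  # (n_segments,) int
    parents: list[tuple[str, float]]
    synthetic_flags: np.ndarray  # (n_segments,) bool
    window: WindowConfig | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.synthetic_flags = np.asarray(self.synthetic_flags, dtype=bool)
        n = self.values.shape[0]
        if not (self.labels.shape[0] == n == len(self.parents) == self.synthetic_flags.shape[0]):
            raise ValueError("segment arrays have inconsistent lengths")

    def __len__(self) -> int:
        return self.values.shape[0]

    def class_counts(self) -> dict[ClassLabel, int]:
        return {lab: int(np.sum(self.labels == int(lab))) for lab in ClassLabel
                if np.any(self.labels == int(lab))}

    def subset(self, idx: np.ndarray) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            values=self.values[idx],
            labels=self.labels[idx],
            parents=[self.parents[i] for i in np.atleast_1d(idx)],
            synthetic_flags=self.synthetic_flags[idx],
            window=self.window,
        )


def count_segments(l: int, w: int, s: int) -> int:
    """Number of windows of size ``w`` at stride ``s`` in a series of length
    ``l``: the integer part of ``(l - w)/s + 1``, or 0 when ``l < w``."""
    if w < 1 or s < 1:
        raise ValueError("window and step must be >= 1")
    if l < w:
        return 0
    return (l - w) // s + 1


def segment_records(records: list[Record], cfg: WindowConfig) -> SegmentSet:
    """Cut every record into windows at offsets 0, s, 2s, ...; labels and
    provenance are inherited from the parent record."""
    if not records:
        raise ValueError("no records to segment")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"mixed record lengths {sorted(lengths)}")
    l = lengths.pop()
    if l < cfg.window_size:
        raise ValueError(f"records ({l}) shorter than window ({cfg.window_size})")
    starts = np.arange(count_segments(l, cfg.window_size, cfg.step_size)) * cfg.step_size
    windows = starts[:, None] + np.arange(cfg.window_size)[None, :]
    values = np.concatenate([rec.samples[windows] for rec in records], axis=0)
    labels = np.repeat([int(rec.label) for rec in records], starts.shape[0])
    parents = [
        (rec.provenance[0], float(rec.provenance[1] + start))
        for rec in records
        for start in starts
    ]
    return SegmentSet(
        values=values,
        labels=labels,
        parents=parents,
        synthetic_flags=np.zeros(values.shape[0], dtype=bool),
        window=cfg,
    )


def smote_neighbors(values: np.ndarray, k_nn: int, chunk: int = 512) -> np.ndarray:
    """k nearest same-class neighbours under Euclidean distance.

    Self-matches are excluded; distance ties break toward the lower index
    (stable sort). Returns an (n, k) index table. If ``k_nn >= n`` the
    neighbour count falls back to ``n - 1`` with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to find neighbours")
    if k_nn >= n:
        warnings.warn(f"k_nn={k_nn} >= class size {n}; using k_nn={n - 1}")
        k_nn = n - 1
    out = np.empty((n, k_nn), dtype=np.int64)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        dist = scipy.spatial.distance.cdist(values[lo:hi], values)
        rows = np.arange(lo, hi)
        dist[rows - lo, rows] = np.inf  # exclude self
        order = np.argsort(dist, axis=1, kind="stable")
        out[lo:hi] = order[:, :k_nn]
    return out


def _interpolate(x_i: np.ndarray, x_j: np.ndarray, lam: float) -> np.ndarray:
    return x_i + lam * (x_j - x_i)


def smote_balance(segs: SegmentSet, cfg: SmoteConfig) -> SegmentSet:
    """Grow every non-majority class to exactly the majority count.

    References x_i are visited round-robin; for each, the fractional part of
    the majority/minority ratio becomes the probability of one extra sample;
    the surplus (or shortfall) is then trimmed from the newest synthetic
    samples (or topped up) to land exactly on the majority count. Original
    segments are preserved unchanged and come first in the output.
    """
    counts = segs.class_counts()
    if len(counts) < 2:
        warnings.warn("fewer than two classes present; SMOTE is a no-op")
        return segs
    majority = max(counts.values())
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    new_values: list[np.ndarray] = []
    new_labels: list[int] = []
    new_parents: list[tuple[str, float]] = []
    for label in sorted(counts, key=int):
        n_min = counts[label]
        deficit = majority - n_min
        if deficit == 0:
            continue
        if n_min < 2:
            raise ValueError(f"class {label.name} has fewer than 2 segments; cannot oversample")
        idx = np.flatnonzero(segs.labels == int(label))
        minority = segs.values[idx]
        nbrs = smote_neighbors(minority, cfg.k_nn)
        ratio = majority / n_min
        n_extra_int = int(ratio) - 1  # guaranteed synthetic draws per reference
        frac = ratio - int(ratio)

        k_eff = nbrs.shape[1]
        gen_v: list[np.ndarray] = []
        gen_p: list[tuple[str, float]] = []
        ref = 0
        # round-robin over references until the deficit is covered; the
        # seeded surplus trim below then lands exactly on the majority count
        while len(gen_v) < deficit:
            i = ref % n_min
            n_draws = n_extra_int + (1 if rng.random() < frac else 0)
            for _ in range(n_draws):
                j = nbrs[i, rng.integers(k_eff)]
                lam = rng.random()
                gen_v.append(_interpolate(minority[i], minority[j], lam))
                src = segs.parents[idx[i]]
                gen_p.append((f"smote:{src[0]}", src[1] + lam))
            ref += 1
        gen_v = gen_v[:deficit]  # trim newest surplus
        gen_p = gen_p[:deficit]
        new_values.extend(gen_v)
        new_labels.extend([int(label)] * deficit)
        new_parents.extend(gen_p)

    if not new_values:
        return segs
    return SegmentSet(
        values=np.concatenate([segs.values, np.asarray(new_values)], axis=0),
        labels=np.concatenate([segs.labels, np.asarray(new_labels, dtype=np.int64)]),
        parents=list(segs.parents) + new_parents,
        synthetic_flags=np.concatenate(
            [segs.synthetic_flags, np.ones(len(new_values), dtype=bool)]
        ),
        window=segs.window,
    )
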