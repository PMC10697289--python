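"""The sixteen-model window/step/SMOTE sweep harness.

The grid crosses window sizes {128, 256, 512, 1024}, step sizes {32, 64} and
SMOTE on/off. Because the published model-id numbering is internally
inconsistent, every row here carries its explicit (window, step, smote)
coordinates; the id column is merely this package's enumeration order
(SMOTE-on cells first, then window ascending, then step ascending).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from .augment import SegmentSet, SmoteConfig, WindowConfig, segment_records, smote_balance
from .network import ModelConfig, summarize
from .records import Record
from .training import TrainConfig, cross_validate


@dataclass
class SweepSpec:
    windows: tuple[int, ...] = (128, 256, 512, 1024)
    steps: tuple[int, ...] = (32, 64)
    smote_options: tuple[bool, ...] = (True, False)
    smote_config: SmoteConfig = field(default_factory=SmoteConfig)

    def cells(self) -> list[dict]:
        out = []
        model_id = 1
        for smote in self.smote_options:
            for w in self.windows:
                for s in sorted(self.steps):
                    out.append({"model_id": model_id, "window": w,
                                "step": s, "smote": smote})
                    model_id += 1
        return out


def run_sweep(
    records: list[Record],
    spec: SweepSpec | None = None,
    train_cfg: TrainConfig | None = None,
    model_builder=ModelConfig.lightweight,
    train: bool = False,
) -> pd.DataFrame:
    """Segment counts, parameter/FLOP accounting and (optionally) CV metrics
    for every grid cell. Per-cell failures are isolated into an ``error``
    column and the sweep continues."""
    spec = spec or SweepSpec()
    rows = []
    for cell in spec.cells():
        row = dict(cell)
        try:
            segs = segment_records(records, WindowConfig(cell["window"], cell["step"]))
            row["n_segments"] = len(segs)
            if cell["smote"]:
                segs = smote_balance(segs, spec.smote_config)
            row["n_samples"] = len(segs)
            row["class_counts"] = {k.name.lower(): v for k, v in segs.class_counts().items()}
            config = model_builder(cell["window"])
            summary = summarize(config)
            row["parameters"] = summary.trainable_parameter_count
            row["macs"] = sum(summary.per_layer_macs.values())
            if train and train_cfg is not None:
                t0 = time.perf_counter()
                result = cross_validate(config, segs, train_cfg)
                elapsed = time.perf_counter() - t0
                n_epochs_total = train_cfg.epochs * train_cfg.folds
                row["time_per_epoch_s"] = elapsed / n_epochs_total
                row.update({k: v for k, v in result["mean_report"].as_dict().items()})
        except Exception as exc:  # isolate per-cell failures
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
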