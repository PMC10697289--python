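"""Model/Results facade over the pipeline.

:class:`SeizureClassifier` is built from data (a segment set, or records via
:meth:`SeizureClassifier.from_records`); :meth:`fit` runs k-fold
cross-validated training and returns a :class:`CrossValidationResults`
carrying per-fold metrics, confusion matrices, loss curves and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import SegmentSet, SmoteConfig, WindowConfig, segment_records, smote_balance
from .network import ModelConfig, ModelSummary, summarize
from .records import Record
from .training import ConfusionMatrix, MetricsReport, TrainConfig, cross_validate


@dataclass
class CrossValidationResults:
    """Estimates and diagnostics from one cross-validated fit."""

    model_config: ModelConfig
    train_config: TrainConfig
    fold_reports: list[MetricsReport]
    mean_report: MetricsReport
    table: pd.DataFrame
    confusions: list[ConfusionMatrix]
    loss_curves: list[np.ndarray]
    model_summary: ModelSummary = field(default=None)

    @property
    def accuracy(self) -> float:
        return self.mean_report.acc

    @property
    def total_confusion(self) -> ConfusionMatrix:
        total = self.confusions[0]
        for cm in self.confusions[1:]:
            total = total + cm
        return total

    def summary(self) -> str:
        """Per-fold metric table (percent) plus the model size figures."""
        df = (self.table * 100.0).round(2)
        df.columns = ["Acc %", "Sens %", "Spec %", "Prec %"]
        lines = [
            f"{self.train_config.folds}-fold cross-validation, "
            f"window {self.model_config.input_length}, "
            f"{self.model_summary.trainable_parameter_count:,} trainable parameters",
            df.to_string(),
            f"mean accuracy: {self.mean_report.acc * 100.0:.2f}%",
        ]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Per-fold training-loss curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, curve in enumerate(self.loss_curves):
            ax.plot(curve, label=f"fold {i + 1}", alpha=0.7)
        ax.set_xlabel("epoch")
        ax.set_ylabel("training cross-entropy")
        ax.legend(fontsize="small")
        return ax


class SeizureClassifier:
    """Three-class EEG seizure classifier fitted by cross-validation."""

    def __init__(
        self,
        segments: SegmentSet,
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> None:
        self.segments = segments
        window = segments.values.shape[1]
        self.model_config = model_config or ModelConfig.lightweight(window)
        if self.model_config.input_length != window:
            raise ValueError(
                f"model input length {self.model_config.input_length} "
                f"does not match segment width {window}"
            )
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_records(
        cls,
        records: list[Record],
        window: WindowConfig | None = None,
        smote: SmoteConfig | None = SmoteConfig(),
        model_config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
    ) -> "SeizureClassifier":
        """Segment records (and optionally SMOTE-balance, the replication
        order: augmentation before the fold split) into a classifier."""
        segs = segment_records(records, window or WindowConfig())
        if smote is not None:
            segs = smote_balance(segs, smote)
        return cls(segs, model_config=model_config, train_config=train_config)

    def fit(
        self,
        stratified: bool = False,
        split_by_record: bool = False,
        smote_in_fold: SmoteConfig | None = None,
    ) -> CrossValidationResults:
        result = cross_validate(
            self.model_config,
            self.segments,
            self.train_config,
            stratified=stratified,
            split_by_record=split_by_record,
            smote_in_fold=smote_in_fold,
        )
        return CrossValidationResults(
            model_config=self.model_config,
            train_config=self.train_config,
            fold_reports=result["fold_reports"],
            mean_report=result["mean_report"],
            table=result["table"],
            confusions=result["confusions"],
            loss_curves=result["loss_curves"],
            model_summary=summarize(self.model_config),
        )
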