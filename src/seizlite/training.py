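"""Normalization, k-fold cross-validated training, and confusion-matrix
metrics for the PCNN-BiLSTM classifier.

Training minimizes multi-class cross-entropy with Adam. The default
hyperparameters replicate the published protocol (learning rate 2e-5,
beta1 0.9, beta2 0.999, epsilon 1e-8, no decay, no amsgrad, 1000 epochs,
10 folds); desk-scale smoke runs use far fewer epochs and a larger learning
rate via an explicit config.

Metric reduction for the 3-class task: accuracy is overall (micro);
sensitivity, specificity and precision are computed per class one-vs-rest
and macro-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augment import SegmentSet, SmoteConfig, smote_balance
from .network import ModelConfig, PCNNBiLSTM, softmax

LOG_EPS = 1e-12  # clamp for -log p at the true class


@dataclass
class TrainConfig:
    """Adam and cross-validation settings."""

    learning_rate: float = 2e-5
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    amsgrad: bool = False
    epochs: int = 1000
    folds: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def smoke(cls, epochs: int = 20, seed: int = 0) -> "TrainConfig":
        """Desk-scale settings: few epochs, a standard Adam step size."""
        return cls(learning_rate=1e-3, epochs=epochs, batch_size=128, seed=seed)


def normalize(segments: SegmentSet) -> SegmentSet:
    """Per-segment z-score; zero-variance segments map to all zeros."""
    if len(segments) == 0:
        raise ValueError("empty segment set")
    v = segments.values
    mean = v.mean(axis=1, keepdims=True)
    std = v.std(axis=1, keepdims=True)
    out = np.where(std > 0, (v - mean) / np.where(std > 0, std, 1.0), 0.0)
    return SegmentSet(
        values=out,
        labels=segments.labels,
        parents=segments.parents,
        synthetic_flags=segments.synthetic_flags,
        window=segments.window,
    )


def make_folds(
    n_samples: int,
    folds: int = 10,
    seed: int = 0,
    labels: np.ndarray | None = None,
    stratified: bool = False,
    groups: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random partition into near-equal disjoint test subsets.

    Returns (train_idx, test_idx) pairs; every sample is tested exactly once.
    ``stratified`` preserves class proportions per fold; ``groups`` keeps all
    segments of one parent record in the same fold (leakage-safe splitting).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if n_samples < folds:
        raise ValueError(f"n_samples={n_samples} < folds={folds}")
    if groups is not None:
        uniq = np.unique(groups)
        if uniq.shape[0] < folds:
            raise ValueError("fewer groups than folds")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perm = rng.permutation(uniq)
        chunks = np.array_split(perm, folds)
        all_idx = np.arange(n_samples)
        out = []
        for chunk in chunks:
            test_mask = np.isin(groups, chunk)
            out.append((all_idx[~test_mask], all_idx[test_mask]))
        return out
    if stratified:
        if labels is None:
            raise ValueError("stratified folds require labels")
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n_samples), labels))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n_samples)))


def cross_entropy(probabilities: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean -log p(true class); zero probabilities are clamped at 1e-12."""
    probabilities = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    true_labels = np.atleast_1d(np.asarray(true_labels, dtype=np.int64))
    p = probabilities[np.arange(true_labels.shape[0]), true_labels]
    if np.any(p <= LOG_EPS):
        warnings.warn("zero probability at the true class clamped for the log")
        p = np.clip(p, LOG_EPS, None)
    return float(np.mean(-np.log(p)))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.vhat_max = (
            {k: np.zeros_like(v) for k, v in params.items()} if cfg.amsgrad else None
        )
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c = self.cfg
        lr = c.learning_rate / (1.0 + c.decay * (self.t - 1))
        for k, p in params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1 ** self.t)
            vhat = self.v[k] / (1 - c.beta2 ** self.t)
            if self.vhat_max is not None:
                self.vhat_max[k] = np.maximum(self.vhat_max[k], vhat)
                vhat = self.vhat_max[k]
            p -= lr * mhat / (np.sqrt(vhat) + c.epsilon)


def train_fold(
    model_config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    seed: int | None = None,
) -> tuple[PCNNBiLSTM, np.ndarray]:
    """Train one network on (X, y); returns the network and per-epoch loss."""
    seed = cfg.seed if seed is None else seed
    net = PCNNBiLSTM(model_config, seed=seed)
    opt = Adam(net.params, cfg)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    n = X.shape[0]
    losses = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            logits = net.forward(X[idx], training=True)
            probs = softmax(logits)
            loss = cross_entropy(probs, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}; "
                    f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(idx.shape[0]), y[idx]] = 1.0
            net.backward((probs - onehot) / idx.shape[0])
            if cfg.learning_rate > 0:
                opt.step(net.params, net.grads)
            epoch_loss += loss * idx.shape[0]
        losses[epoch] = epoch_loss / n
    return net, losses


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for the given class as the positive."""
        tp = int(self.counts[cls, cls])
        fn = int(self.counts[cls].sum() - tp)
        fp = int(self.counts[:, cls].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


def evaluate(net: PCNNBiLSTM, X: np.ndarray, y: np.ndarray,
             batch_size: int = 512) -> ConfusionMatrix:
    """Tally argmax predictions into the confusion matrix."""
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    k = net.config.num_classes
    counts = np.zeros((k, k), dtype=np.int64)
    for lo in range(0, X.shape[0], batch_size):
        pred = net.predict(X[lo: lo + batch_size])
        np.add.at(counts, (y[lo: lo + batch_size], pred), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Accuracy (overall) and macro-averaged Sens/Spec/Prec, as fractions."""

    acc: float
    sens: float
    spec: float
    prec: float
    per_class: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sens": self.sens, "spec": self.spec, "prec": self.prec}


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision from the matrix.

    Acc = (TP + TN) / total over all classes at once (= trace / total);
    Sens = TP/(TP+FN), Spec = TN/(FP+TN), Prec = TP/(TP+FP) per class
    one-vs-rest, macro-averaged. A zero denominator contributes 0 and is
    flagged.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts) / cm.total)
    per_class: dict[int, dict[str, float]] = {}
    flags: list[str] = []
    sens_l, spec_l, prec_l = [], [], []

    def safe(num: int, den: int, name: str, cls: int) -> float:
        if den == 0:
            flags.append(f"class {cls}: undefined {name} (zero denominator)")
            return 0.0
        return num / den

    for cls in range(cm.n_classes):
        tp, tn, fp, fn = cm.one_vs_rest(cls)
        s = safe(tp, tp + fn, "sensitivity", cls)
        sp = safe(tn, fp + tn, "specificity", cls)
        p = safe(tp, tp + fp, "precision", cls)
        per_class[cls] = {"sens": s, "spec": sp, "prec": p,
                          "tp": tp, "tn": tn, "fp": fp, "fn": fn}
        sens_l.append(s)
        spec_l.append(sp)
        prec_l.append(p)
    return MetricsReport(
        acc=acc,
        sens=float(np.mean(sens_l)),
        spec=float(np.mean(spec_l)),
        prec=float(np.mean(prec_l)),
        per_class=per_class,
        flags=flags,
    )


def aggregate_folds(reports: list[MetricsReport]) -> tuple[MetricsReport, pd.DataFrame]:
    """Arithmetic mean of each metric plus a per-fold table."""
    if not reports:
        raise ValueError("no fold reports")
    df = pd.DataFrame([r.as_dict() for r in reports])
    df.index = [f"fold {i + 1}" for i in range(len(reports))]
    mean = df.mean()
    df.loc["mean"] = mean
    report = MetricsReport(
        acc=float(mean["acc"]), sens=float(mean["sens"]),
        spec=float(mean["spec"]), prec=float(mean["prec"]),
    )
    return report, df


def cross_validate(
    model_config: ModelConfig,
    segments: SegmentSet,
    cfg: TrainConfig,
    stratified: bool = False,
    split_by_record: bool = False,
    smote_in_fold: SmoteConfig | None = None,
) -> dict:
    """k-fold cross-validation over normalized segments.

    In replication mode the incoming segment set is used as-is (typically
    already SMOTE-balanced before splitting). The leakage-safe alternative
    groups folds by parent record (``split_by_record``) and/or fits SMOTE
    inside each training fold only (``smote_in_fold``).
    """
    segs = normalize(segments)
    y = segs.labels
    groups = None
    if split_by_record:
        sources = np.asarray([p[0] for p in segs.parents])
        _, groups = np.unique(sources, return_inverse=True)
    folds = make_folds(
        len(segs), folds=cfg.folds, seed=cfg.seed,
        labels=y, stratified=stratified, groups=groups,
    )
    fold_reports: list[MetricsReport] = []
    confusions: list[ConfusionMatrix] = []
    loss_curves: list[np.ndarray] = []
    for i, (train_idx, test_idx) in enumerate(folds):
        train_set = segs.subset(train_idx)
        if smote_in_fold is not None:
            train_set = normalize(smote_balance(train_set, smote_in_fold))
        net, losses = train_fold(
            model_config, train_set.values, train_set.labels, cfg,
            seed=cfg.seed + i,
        )
        cm = evaluate(net, segs.values[test_idx], y[test_idx])
        confusions.append(cm)
        fold_reports.append(metrics(cm))
        loss_curves.append(losses)
    mean_report, table = aggregate_folds(fold_reports)
    return {
        "fold_reports": fold_reports,
        "mean_report": mean_report,
        "table": table,
        "confusions": confusions,
        "loss_curves": loss_curves,
        "folds": folds,
    }
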