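"""Bootstrap + k-fold cross-validation assessment of the full pipeline.

The evaluation protocol draws bootstrap resamples of the cohort (with
replacement, original size, stratified per class), runs stratified 3-fold
cross-validation of the LSTM + ECOC-SVM pipeline on every resample, pools
each resample's fold predictions into one confusion matrix, and records
accuracy, macro sensitivity, macro specificity and macro precision (in
percent).  Replicate metrics are summarized by mean, standard deviation and
the percentile 95% confidence interval (2.5th / 97.5th percentiles).

Also provided is the one-axis-at-a-time hill-climbing hyperparameter sweep
(learning rate -> mini-batch size -> hidden units -> optimizer) used to fix
the published architecture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import ecoc as ecoc_mod
from . import lstm as lstm_mod
from .ecoc import SVMConfig
from .lstm import TrainConfig
from .recording import CLASSES, StepSequence, class_index

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass
class PipelineSettings:
    """Model settings evaluated by the protocol."""

    train: TrainConfig = field(default_factory=TrainConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    hidden_units: int = 256
    classifier: str = "ecoc_svm"  # or "softmax" (ablation arm)
    feature_pooling: str = "last"


@dataclass
class EvalConfig:
    """Evaluation protocol settings.

    ``n_bootstrap`` is 250 during design-phase comparisons and 2000 for the
    final assessment.
    """

    n_bootstrap: int = 250
    k_folds: int = 3
    stratified: bool = True
    seed: int = 0
    settings: PipelineSettings = field(default_factory=PipelineSettings)

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


@dataclass
class BootstrapReport:
    """Per-replicate metric records with mean / SD / 95% CI summaries."""

    replicates: pd.DataFrame  # columns: the four metrics, one row per replicate
    config: EvalConfig | None = None

    @property
    def summary(self) -> pd.DataFrame:
        """Mean, SD, and percentile 95% CI per metric.

        With a single replicate the SD is 0 by convention.
        """
        rows = {}
        for m in METRIC_NAMES:
            vals = self.replicates[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows[m] = {
                "mean": float(np.mean(vals)),
                "sd": sd,
                "ci_low": float(np.percentile(vals, 2.5)),
                "ci_high": float(np.percentile(vals, 97.5)),
            }
        return pd.DataFrame(rows).T[["mean", "sd", "ci_low", "ci_high"]]

    def to_dict(self) -> dict:
        return {m: dict(self.summary.loc[m]) for m in METRIC_NAMES}


def bootstrap_sample(dataset: list[StepSequence], rng: np.random.Generator,
                     stratified: bool = True) -> list[StepSequence]:
    """Draw ``len(dataset)`` items with replacement.

    With ``stratified=True`` (default) each class is resampled within
    itself (n_c draws among its own n_c members), which guarantees every
    class stays represented — a requirement for the downstream stratified
    k-fold split.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if not stratified:
        idx = rng.integers(0, len(dataset), size=len(dataset))
        return [dataset[i] for i in idx]
    labels = np.array([class_index(s.label) for s in dataset])
    chosen: list[int] = []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        chosen.extend(members[rng.integers(0, len(members), size=len(members))])
    return [dataset[i] for i in chosen]


def compute_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Accuracy and macro one-vs-rest sensitivity/specificity/precision.

    ``confusion`` has true classes on rows, predictions on columns.
    All values are percentages.  A class with zero predicted positives
    contributes 0 precision and logs a warning.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    sens = np.divide(tp, tp + fn, out=np.zeros_like(tp), where=(tp + fn) > 0)
    spec = np.divide(tn, tn + fp, out=np.zeros_like(tn), where=(tn + fp) > 0)
    predicted = tp + fp
    if (predicted == 0).any():
        warnings.warn(
            "a class has zero predicted positives; its precision counts as 0",
            stacklevel=2,
        )
    prec = np.divide(tp, predicted, out=np.zeros_like(tp), where=predicted > 0)
    return {
        "accuracy": 100.0 * tp.sum() / total,
        "sensitivity": 100.0 * sens.mean(),
        "specificity": 100.0 * spec.mean(),
        "precision": 100.0 * prec.mean(),
    }


def _standardize(train_seqs, test_seqs):
    """Per-channel z-scoring with training-fold statistics."""
    train_data = np.stack([s.data for s in train_seqs])  # (N, T, C, S)
    mean = train_data.mean(axis=(0, 1, 3), keepdims=True)[0]
    std = train_data.std(axis=(0, 1, 3), keepdims=True)[0]
    std[std == 0] = 1.0

    def scale(seqs):
        return [StepSequence(data=(s.data - mean) / std, label=s.label, id=s.id)
                for s in seqs]

    return scale(train_seqs), scale(test_seqs)


def _fit_and_predict(train_seqs, test_seqs, settings: PipelineSettings,
                     seed: int):
    """Train the pipeline on one fold; return predictions for the test fold."""
    train_seqs, test_seqs = _standardize(train_seqs, test_seqs)
    train_cfg = replace(settings.train, seed=seed)
    model, _ = lstm_mod.train_lstm(train_seqs, train_cfg,
                                   H=settings.hidden_units)
    if settings.classifier == "softmax":
        return lstm_mod.predict_softmax(model, test_seqs)
    if settings.feature_pooling == "last":
        feats_train = lstm_mod.extract_feature_matrix(model, train_seqs)
        feats_test = lstm_mod.extract_feature_matrix(model, test_seqs)
    else:
        feats_train = np.vstack([
            lstm_mod.extract_features(model, s, settings.feature_pooling).values
            for s in train_seqs])
        feats_test = np.vstack([
            lstm_mod.extract_features(model, s, settings.feature_pooling).values
            for s in test_seqs])
    y_train = np.array([class_index(s.label) for s in train_seqs])
    svm_cfg = replace(settings.svm, seed=seed)
    ecoc_model = ecoc_mod.train_ecoc(feats_train, y_train,
                                     svm_config=svm_cfg)
    return ecoc_mod.predict(ecoc_model, feats_test)


def _grouped_stratified_folds(sample: list[StepSequence], k: int,
                              rng: np.random.Generator) -> list[np.ndarray]:
    """Fold assignment that never splits duplicates across folds.

    Bootstrap copies of the same original recording (identified by id) all
    go to one fold, so no information leaks from a training fold into a
    test fold through a duplicate.  Within each class, distinct originals
    are dealt to folds largest-multiplicity-first onto the currently
    lightest fold, which keeps fold sizes balanced (exactly ``n/k`` when
    the sample has no duplicates).  Returns per-fold item-index arrays.
    """
    ids = [s.id for s in sample]
    labels = [class_index(s.label) for s in sample]
    members: dict[str, list[int]] = {}
    for i, gid in enumerate(ids):
        members.setdefault(gid, []).append(i)
    fold_items: list[list[int]] = [[] for _ in range(k)]
    class_counts = np.zeros((k, len(CLASSES)), dtype=int)
    for cls in sorted(set(labels)):
        gids = sorted({ids[i] for i in range(len(sample)) if labels[i] == cls})
        if len(gids) < 2:
            raise RuntimeError(
                f"class {CLASSES[cls]!r} has {len(gids)} distinct item(s); "
                f"at least 2 are needed to appear in both train and test splits"
            )
        rng.shuffle(gids)
        gids.sort(key=lambda g: -len(members[g]))  # stable: shuffle breaks ties
        for g in gids:
            totals = np.array([len(f) for f in fold_items])
            # prefer folds not yet covering this class, then the lightest
            priority = (class_counts[:, cls] > 0).astype(int) * 10**6 + totals
            f = int(np.argmin(priority))
            fold_items[f].extend(members[g])
            class_counts[f, cls] += len(members[g])
    return [np.array(sorted(f), dtype=int) for f in fold_items]


def cross_validate(sample: list[StepSequence], k: int,
                   settings: PipelineSettings,
                   rng: np.random.Generator) -> np.ndarray:
    """Stratified k-fold CV of the full pipeline on one bootstrap sample.

    Every item (duplicates included) is assigned to exactly one fold and
    tested exactly once.  All copies of the same original stay in the same
    fold, so a duplicated item can never sit in a training fold while a
    copy of it is being tested.  Fold predictions are pooled into a single
    confusion matrix (rows true, columns predicted).
    """
    labels = np.array([class_index(s.label) for s in sample])
    n_classes = len(CLASSES)
    folds = _grouped_stratified_folds(sample, k, rng)
    for test_idx in folds:
        train_mask = np.ones(len(sample), dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(labels[train_mask])) < n_classes:
            raise RuntimeError(
                f"a {k}-fold training split lost a class entirely"
            )
    y_true_all, y_pred_all = [], []
    for test_idx in folds:
        fold_seed = int(rng.integers(0, 2**31))
        train_idx = np.setdiff1d(np.arange(len(sample)), test_idx)
        preds = _fit_and_predict(
            [sample[i] for i in train_idx],
            [sample[i] for i in test_idx],
            settings, fold_seed,
        )
        y_pred_all.extend(int(p) for p in preds)
        y_true_all.extend(labels[test_idx])
    return confusion_matrix(y_true_all, y_pred_all,
                            labels=list(range(n_classes)))


def run_bootstrap_evaluation(dataset: list[StepSequence],
                             config: EvalConfig) -> BootstrapReport:
    """The full protocol: resample -> cross-validate -> metrics, repeated.

    Deterministic given ``config.seed``; each replicate draws from its own
    pre-spawned random stream, and a failing replicate is retried once with
    a derived seed before aborting.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_bootstrap)
    records = []
    for b, stream in enumerate(streams):
        for attempt, child in enumerate(stream.spawn(2)):
            rng = np.random.default_rng(child)
            try:
                sample = bootstrap_sample(dataset, rng, config.stratified)
                cm = cross_validate(sample, config.k_folds, config.settings, rng)
                records.append(compute_metrics(cm))
                break
            except Exception:
                if attempt == 1:
                    raise RuntimeError(
                        f"bootstrap replicate {b} failed twice"
                    ) from None
    return BootstrapReport(replicates=pd.DataFrame.from_records(records),
                           config=config)


#: Published search grids, in hill-climbing order.
DEFAULT_SWEEP_GRID: dict[str, list] = {
    "learning_rate": [0.1, 0.01, 0.001, 0.0001],
    "mini_batch": [1, 2, 4, 8, 16, 32, 64],
    "hidden_units": [8, 16, 32, 64, 128, 256],
    "optimizer": ["sgd_momentum", "adam"],
}


def _apply_axis(settings: PipelineSettings, axis: str, value) -> PipelineSettings:
    if axis == "hidden_units":
        return replace(settings, hidden_units=int(value))
    if axis in ("learning_rate", "mini_batch", "optimizer"):
        return replace(settings, train=replace(settings.train, **{axis: value}))
    raise ValueError(f"unknown sweep axis {axis!r}")


def sweep(dataset: list[StepSequence], config: EvalConfig,
          grid: dict[str, list] | None = None):
    """One-axis-at-a-time hill-climbing sweep.

    Each axis is evaluated over its grid with the other axes fixed; the
    best-mean-accuracy value is frozen before the next axis.  Returns
    ``(table, best_settings)`` where the table has one row per evaluated
    setting.
    """
    grid = grid or DEFAULT_SWEEP_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("sweep grid must be non-empty")
    settings = config.settings
    rows = []
    for axis, values in grid.items():
        best_value, best_acc = None, -np.inf
        for value in values:
            candidate = _apply_axis(settings, axis, value)
            report = run_bootstrap_evaluation(
                dataset, replace(config, settings=candidate)
            )
            summ = report.summary
            rows.append({
                "axis": axis, "value": value,
                **{m: summ.loc[m, "mean"] for m in METRIC_NAMES},
                **{f"{m}_sd": summ.loc[m, "sd"] for m in METRIC_NAMES},
            })
            if summ.loc["accuracy", "mean"] > best_acc:
                best_acc, best_value = summ.loc["accuracy", "mean"], value
        settings = _apply_axis(settings, axis, best_value)
    return pd.DataFrame(rows), settings
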