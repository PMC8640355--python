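"""Sample-level MLP classification of fingerprint spectra.

The network is the small multilayer perceptron of the study design:
1201 fingerprint intensities -> 64 ReLU -> 64 ReLU -> 2-class softmax,
trained with Adam on cross-entropy. Training follows the study protocol:

* the training cohort is a random *sample-level* draw of 30 blastula + 30
  non-blastula samples (all five replicate spectra of a sample travel
  together, so 300 training spectra); the remaining 50 + 18 samples (340
  spectra) form the test cohort;
* 10-fold cross-validation, stratified by group and split at sample level
  (spectrum-level folding would leak replicates between folds and is
  refused), with patience-based early stopping on each fold's validation
  cross-entropy;
* the final model is retrained on the whole training cohort for the median
  of the fold-wise best epochs;
* per-spectrum predictions are aggregated to one call per sample by
  majority vote over its (odd number of) replicates; mean-probability
  aggregation is available via config.

Metrics follow the study's conventions: sensitivity is the recall of the
non-blastula class, specificity the recall of the blastula class, both at
sample level and reported as percentages to two decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .preprocessing import FeatureMatrix

log = logging.getLogger("ramanembryo")

__all__ = [
    "MLPConfig",
    "SplitPlan",
    "TrainedMLP",
    "ConfusionMatrix",
    "MetricsReport",
    "split_dataset",
    "train_mlp",
    "predict_spectra",
    "aggregate_to_samples",
    "confusion_and_metrics",
    "evaluate_model",
]

#: Class order used everywhere: row/column 0 = non_blastula, 1 = blastula.
CLASSES = ("non_blastula", "blastula")


@dataclass
class MLPConfig:
    """Architecture and training-protocol knobs."""

    hidden_units: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    alpha: float = 1e-4  # L2 penalty
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 32
    cv_folds: int = 10
    aggregation: str = "majority"  # or "mean_probability"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.aggregation not in ("majority", "mean_probability"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class SplitPlan:
    """Sample-disjoint train/test split; replicates never straddle the split."""

    train_samples: tuple[str, ...]
    test_samples: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_samples) & set(self.test_samples)
        if overlap:
            raise ValueError(f"train/test sample sets overlap: {sorted(overlap)[:5]}")


@dataclass
class TrainedMLP:
    """Final fitted network plus the cross-validation record."""

    estimator: MLPClassifier
    fold_best_epochs: list[int]
    final_epoch: int
    fold_val_losses: list[list[float]]
    config: MLPConfig
    n_features: int


def _sample_table(features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Unique sample ids (first-appearance order) and their group labels."""
    uniq = list(dict.fromkeys(features.sample_ids))
    groups = np.array([features.groups[features.sample_ids == s][0] for s in uniq])
    return np.array(uniq), groups


def split_dataset(features: FeatureMatrix, n_per_group: int = 30, seed: int = 0) -> SplitPlan:
    """Uniform random sample-level split: ``n_per_group`` samples of each group train."""
    samples, groups = _sample_table(features)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    for group in CLASSES:
        pool = samples[groups == group]
        if pool.size < n_per_group:
            raise ValueError(
                f"group {group!r} has {pool.size} samples; cannot draw {n_per_group}"
            )
        train.extend(rng.choice(pool, size=n_per_group, replace=False))
    train_set = set(train)
    test = [s for s in samples if s not in train_set]
    return SplitPlan(train_samples=tuple(train), test_samples=tuple(test), seed=seed)


def _encode(groups: np.ndarray) -> np.ndarray:
    y = np.full(groups.shape, -1, dtype=int)
    for k, name in enumerate(CLASSES):
        y[groups == name] = k
    if np.any(y < 0):
        bad = groups[y < 0][0]
        raise ValueError(f"unknown group label {bad!r}")
    return y


def _fresh_net(config: MLPConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_units),
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        alpha=config.alpha,
        random_state=seed,
        max_iter=1,  # epochs are driven externally via partial_fit
    )


def _run_epochs(
    net: MLPClassifier,
    X: np.ndarray,
    y: np.ndarray,
    config: MLPConfig,
    rng: np.random.Generator,
    n_epochs: int,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[list[float], int]:
    """Drive mini-batch training; returns (val-loss trace, best 1-based epoch).

    With a validation set, stops early once the validation cross-entropy has
    not improved for ``config.patience`` epochs.
    """
    classes = np.arange(len(CLASSES))
    n = X.shape[0]
    losses: list[float] = []
    best_loss, best_epoch, stale = np.inf, 0, 0
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            net.partial_fit(X[batch], y[batch], classes=classes)
        if X_val is None:
            continue
        val_loss = float(log_loss(y_val, net.predict_proba(X_val), labels=classes))
        if not np.isfinite(val_loss):
            raise RuntimeError(
                f"non-finite validation loss at epoch {epoch} "
                f"(lr={config.learning_rate}, batch_size={config.batch_size})"
            )
        losses.append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_epoch, stale = val_loss, epoch, 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return losses, best_epoch if X_val is not None else n_epochs


def train_mlp(features: FeatureMatrix, split: SplitPlan, config: MLPConfig) -> TrainedMLP:
    """Cross-validated training with early stopping, then full-cohort retraining.

    For each of ``cv_folds`` sample-level stratified folds of the training
    cohort, a fresh network is trained with early stopping on the held-out
    fold's cross-entropy. The final network is retrained on all training
    spectra for the median of the fold-wise best epochs.
    """
    if not np.all(np.isfinite(features.X)):
        raise ValueError("feature matrix contains non-finite values")
    train_mask = features.rows_for_samples(split.train_samples)
    assert not (set(split.train_samples) & set(split.test_samples)), "train/test leakage"
    X = features.X[train_mask]
    y = _encode(features.groups[train_mask])
    sample_ids = features.sample_ids[train_mask]

    uniq = np.array(list(dict.fromkeys(sample_ids)))
    uniq_groups = np.array([y[sample_ids == s][0] for s in uniq])
    folds = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)

    best_epochs: list[int] = []
    traces: list[list[float]] = []
    for k, (tr, va) in enumerate(folds.split(uniq, uniq_groups)):
        tr_rows = np.isin(sample_ids, uniq[tr])
        va_rows = np.isin(sample_ids, uniq[va])
        net = _fresh_net(config, seed=config.seed + 100 + k)
        rng = np.random.default_rng(config.seed * 1000 + k)
        trace, best = _run_epochs(
            net, X[tr_rows], y[tr_rows], config, rng, config.max_epochs,
            X_val=X[va_rows], y_val=y[va_rows],
        )
        best_epochs.append(max(1, best))
        traces.append(trace)

    final_epoch = int(round(float(np.median(best_epochs))))
    final_epoch = max(1, final_epoch)
    net = _fresh_net(config, seed=config.seed)
    rng = np.random.default_rng(config.seed * 1000 + 999)
    _run_epochs(net, X, y, config, rng, final_epoch)
    log.info(
        "train_mlp: %d folds, best epochs %s, final model trained %d epochs on %d spectra",
        config.cv_folds, best_epochs, final_epoch, X.shape[0],
    )
    return TrainedMLP(
        estimator=net,
        fold_best_epochs=best_epochs,
        final_epoch=final_epoch,
        fold_val_losses=traces,
        config=config,
        n_features=X.shape[1],
    )


def predict_spectra(model: TrainedMLP, X: np.ndarray | FeatureMatrix):
    """Per-spectrum class probabilities (columns: non_blastula, blastula) and labels."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else X.shape} does not match "
            f"model input width {model.n_features}"
        )
    proba = model.estimator.predict_proba(X)
    labels = np.array([CLASSES[j] for j in np.argmax(proba, axis=1)])
    return proba, labels


def aggregate_to_samples(
    spectrum_labels: np.ndarray,
    sample_ids: np.ndarray,
    method: str = "majority",
    probabilities: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-spectrum predictions to one label per sample.

    ``majority`` requires an odd number of replicate predictions per sample
    (with the default five, ties are impossible); an even count raises,
    pointing at the mean-probability tie-break policy in config.
    ``mean_probability`` averages class probabilities and takes the argmax.
    Returns samples in first-appearance order.
    """
    spectrum_labels = np.asarray(spectrum_labels)
    sample_ids = np.asarray(sample_ids)
    uniq = list(dict.fromkeys(sample_ids))
    out = []
    for s in uniq:
        mask = sample_ids == s
        if method == "majority":
            if mask.sum() % 2 == 0:
                raise ValueError(
                    f"sample {s!r} has an even number of replicate predictions "
                    f"({int(mask.sum())}); majority vote can tie — set the "
                    "aggregation config to 'mean_probability' to define a tie-break"
                )
            votes = spectrum_labels[mask]
            counts = {c: int(np.sum(votes == c)) for c in CLASSES}
            out.append(max(CLASSES, key=lambda c: counts[c]))
        elif method == "mean_probability":
            if probabilities is None:
                raise ValueError("mean_probability aggregation needs the probability matrix")
            mean_p = np.asarray(probabilities)[mask].mean(axis=0)
            out.append(CLASSES[int(np.argmax(mean_p))])
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
    return np.array(uniq), np.array(out)


@dataclass
class ConfusionMatrix:
    """2x2 sample-level counts, rows = real class, columns = predicted class.

    Index order is (non_blastula, blastula) on both axes.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Sensitivity (non-blastula recall), specificity (blastula recall), accuracy; %."""

    sensitivity: float
    specificity: float
    accuracy: float


def confusion_and_metrics(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Build the 2x2 confusion matrix and the three percentage metrics.

    All three are reported to two decimals; order of the label sequences is
    irrelevant as long as they are aligned.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have equal length")
    idx = {name: k for k, name in enumerate(CLASSES)}
    counts = np.zeros((2, 2), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in idx or p not in idx:
            raise ValueError(f"unknown label {t if t not in idx else p!r}")
        counts[idx[t], idx[p]] += 1
    cm = ConfusionMatrix(counts)
    n, b = idx["non_blastula"], idx["blastula"]
    sens = 100.0 * float(counts[n, n]) / max(1, int(counts[n].sum()))
    spec = 100.0 * float(counts[b, b]) / max(1, int(counts[b].sum()))
    acc = 100.0 * float(counts[n, n] + counts[b, b]) / max(1, cm.total)
    report = MetricsReport(
        sensitivity=round(sens, 2), specificity=round(spec, 2), accuracy=round(acc, 2)
    )
    return cm, report


def evaluate_model(
    model: TrainedMLP, features: FeatureMatrix, split: SplitPlan
) -> tuple[ConfusionMatrix, MetricsReport, dict]:
    """Predict the test cohort, aggregate to samples, and score against truth."""
    test_mask = features.rows_for_samples(split.test_samples)
    proba, labels = predict_spectra(model, features.X[test_mask])
    samples, predicted = aggregate_to_samples(
        labels,
        features.sample_ids[test_mask],
        method=model.config.aggregation,
        probabilities=proba,
    )
    truth = np.array(
        [features.groups[features.sample_ids == s][0] for s in samples]
    )
    cm, report = confusion_and_metrics(truth, predicted)
    detail = {
        "samples": samples.tolist(),
        "true": truth.tolist(),
        "predicted": predicted.tolist(),
        "n_test_spectra": int(test_mask.sum()),
    }
    return cm, report, detail
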