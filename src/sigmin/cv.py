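"""Repeated stratified k-fold cross-validation around a pluggable classifier.

The evaluation protocol is 5-fold stratified CV repeated 10 times by
default.  Within one repeat, the held-out predictions of the k folds are
pooled into a single confusion table before any metric is computed, so each
repeat contributes exactly one value per metric; means and standard
deviations are taken across repeats.  Pooling keeps the per-repeat confusion
well populated even when the positive class is rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import LabeledExpressionDataset, ValidationError
from .metrics import (
    ConfusionCounts,
    MetricSample,
    accuracy_sensitivity_specificity,
    confusion,
    index1,
    index2,
    mcc,
)

METRIC_NAMES = ("mcc", "acc", "sen", "spe", "index1", "index2")


@dataclass(frozen=True)
class ClassifierSpec:
    """Name + hyperparameters of a registered binary classifier."""

    name: str = "svm-linear"
    hyperparameters: tuple = ()
    seed: int = 0

    def build(self):
        return build_classifier(self.name, dict(self.hyperparameters), self.seed)


_REGISTRY: dict[str, Callable] = {}


def register_classifier(name: str, factory: Callable) -> None:
    """Register ``factory(hyperparameters: dict, seed: int) -> estimator``."""
    _REGISTRY[name] = factory


def build_classifier(name: str, hyperparameters: dict | None = None, seed: int = 0):
    if name not in _REGISTRY:
        raise ValidationError(
            f"unknown classifier {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name](hyperparameters or {}, seed)


register_classifier(
    "svm-linear",
    lambda hp, seed: SVC(kernel="linear", C=hp.get("C", 1.0), random_state=seed),
)
register_classifier(
    "svm-rbf",
    lambda hp, seed: SVC(
        kernel="rbf", C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"),
        random_state=seed,
    ),
)


@dataclass
class CVResult:
    """Per-repeat metric samples of one repeated-CV evaluation."""

    metrics: dict[str, MetricSample]
    confusions: list[ConfusionCounts]
    folds: int
    repeats: int
    seed: int

    @property
    def mcc(self) -> MetricSample:
        return self.metrics["mcc"]

    @property
    def acc(self) -> MetricSample:
        return self.metrics["acc"]

    @property
    def sen(self) -> MetricSample:
        return self.metrics["sen"]

    @property
    def spe(self) -> MetricSample:
        return self.metrics["spe"]

    def index_mean(self, fitting_index: str) -> float:
        """Mean of the chosen fitting index across repeats."""
        return self.metrics[fitting_index].mean


def _repeat_seed(seed: int, repeat: int) -> int:
    """Deterministic per-repeat fold seed; prefix-stable in ``repeat``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(repeat),))
    return int(ss.generate_state(1)[0] % (2**31))


def _metric_bundle(c: ConfusionCounts) -> dict[str, float]:
    acc, sen, spe = accuracy_sensitivity_specificity(c)
    return {
        "mcc": mcc(c),
        "acc": acc,
        "sen": sen,
        "spe": spe,
        "index1": index1(c),
        "index2": index2(c),
    }


def evaluate_cv(
    ds: LabeledExpressionDataset,
    probes: Sequence[str],
    spec: ClassifierSpec,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of ``spec`` on the given probe subset."""
    if not ds.has_both_classes():
        raise ValidationError("both endpoint classes must be present for CV")
    idx = ds.probe_index(probes)
    X = ds.values[:, idx]
    y = ds.y()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValidationError(
            f"minority class has {counts.min()} samples < {folds} folds"
        )
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    confusions: list[ConfusionCounts] = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_repeat_seed(seed, r)
        )
        pooled_truth = np.empty_like(y)
        pooled_pred = np.empty_like(y)
        for train_idx, test_idx in skf.split(X, y):
            clf = spec.build()
            clf.fit(X[train_idx], y[train_idx])
            pooled_truth[test_idx] = y[test_idx]
            pooled_pred[test_idx] = clf.predict(X[test_idx])
        c = confusion(pooled_truth, pooled_pred, positive=1)
        confusions.append(c)
        for name, value in _metric_bundle(c).items():
            per_metric[name].append(value)
    return CVResult(
        metrics={m: MetricSample(v) for m, v in per_metric.items()},
        confusions=confusions,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def cv_fold_assignments(
    ds: LabeledExpressionDataset, folds: int, repeats: int, seed: int
) -> list[np.ndarray]:
    """Fold index per sample for each repeat (for auditing/stratification tests)."""
    y = ds.y()
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=_repeat_seed(seed, r)
        )
        assign = np.empty(len(y), dtype=int)
        for k, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
            assign[test_idx] = k
        out.append(assign)
    return out


@dataclass
class FittedModel:
    """A classifier trained on a fixed probe list; predicts by class name."""

    probes: list[str]
    positive_class: str
    classes: list[str]
    estimator: object = field(repr=False, default=None)

    def predict(self, ds: LabeledExpressionDataset) -> np.ndarray:
        idx = ds.probe_index(self.probes)
        return np.asarray(self.estimator.predict(ds.values[:, idx]))


def train_model(
    ds: LabeledExpressionDataset,
    probes: Sequence[str],
    spec: ClassifierSpec,
) -> FittedModel:
    """Fit the classifier on the full dataset restricted to ``probes``."""
    if not ds.has_both_classes():
        raise ValidationError("both endpoint classes must be present to train")
    idx = ds.probe_index(probes)
    clf = spec.build()
    clf.fit(ds.values[:, idx], ds.y())
    return FittedModel(
        probes=list(probes),
        positive_class=ds.positive_class,
        classes=ds.classes,
        estimator=clf,
    )


def external_validate(
    m: FittedModel, ds: LabeledExpressionDataset
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Score a fitted model on every sample of ``ds`` without refitting.

    The validation labels are mapped by class name: samples whose label
    equals the model's positive class are positives regardless of how the
    validation file orders its classes.
    """
    pred = m.predict(ds)
    truth = np.array([1 if l == m.positive_class else 0 for l in ds.labels])
    c = confusion(truth, pred, positive=1)
    return c, _metric_bundle(c)


def cross_endpoint_validate(
    m: FittedModel,
    ds: LabeledExpressionDataset,
    alternate_labels: Sequence[str],
    alternate_positive: str,
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Score a fitted model against a different endpoint's labels.

    Identical to :func:`external_validate` except the truth vector comes
    from ``alternate_labels`` (aligned to ``ds.sample_ids``).
    """
    if len(alternate_labels) != ds.n_samples:
        raise ValidationError(
            f"{len(alternate_labels)} alternate labels for {ds.n_samples} samples"
        )
    pred = m.predict(ds)
    truth = np.array([1 if l == alternate_positive else 0 for l in alternate_labels])
    c = confusion(truth, pred, positive=1)
    return c, _metric_bundle(c)
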