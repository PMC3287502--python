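"""Minimize Feature's Size (MFS): backward stepwise signature minimization.

MFS takes a (typically consensus-derived) probe list and iteratively tries
to drop each probe.  Per iteration it first scores the current set with the
chosen fitting index (mean repeated-CV MCC by default), then visits the
probes one at a time: the index is re-evaluated without the probe under the
*same* CV fold seeds, so the comparison reflects the removal rather than
fold noise.  A removal that lowers the index is undone; one that keeps it
equal or raises it stands — equality removing the probe is the mechanism
that strips redundant features.  Iterations repeat until the set stops
shrinking or reaches a minimum size.  Every evaluated state is recorded and
the best-scoring one is reported regardless of the intermediate-emission
threshold.

The estimator :class:`MFSSelector` exposes the procedure in scikit-learn
form (``fit``/``transform``/``get_support``); :func:`run_mfs` is the
dataset-level wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .cv import ClassifierSpec, CVResult, evaluate_cv, train_model
from .dataset import (
    LabeledExpressionDataset,
    SignatureCollection,
    ValidationError,
)
from .metrics import (
    confusion,
    index1,
    index2,
    mcc,
    resolve_robustness_weights,
)
from .similarity import consensus_set, probe_frequency, weighted_merge

FITTING_INDICES = ("mcc", "index1", "index2")


@dataclass
class MFSConfig:
    """Knobs of one MFS run.

    ``criteria_value`` gates only the emission of intermediate signatures;
    the best model is recorded unconditionally.  ``elimination_order``
    "ascending_weight" challenges the least-supported probes first;
    "input_order" visits probes as given.
    """

    fitting_index: str = "mcc"
    criteria_value: float = 0.6
    min_size: int = 5
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    elimination_order: str = "ascending_weight"
    weights: Mapping[str, float] | None = None
    evaluation: str = "cv"  # "cv" | "resubstitution"

    def __post_init__(self) -> None:
        if self.fitting_index not in FITTING_INDICES:
            raise ValidationError(f"unknown fitting index {self.fitting_index!r}")
        if self.min_size < 1:
            raise ValidationError("min_size must be >= 1")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.elimination_order not in ("ascending_weight", "input_order"):
            raise ValidationError(
                f"unknown elimination order {self.elimination_order!r}"
            )
        if self.evaluation not in ("cv", "resubstitution"):
            raise ValidationError(f"unknown evaluation mode {self.evaluation!r}")


@dataclass
class FeatureDecision:
    probe: str
    candidate_value: float | None
    action: str  # "removed" | "restored" | "restored_on_error"


@dataclass
class IterationTrace:
    iteration: int
    start_features: tuple[str, ...]
    start_value: float
    decisions: list[FeatureDecision]
    end_features: tuple[str, ...]
    end_value: float


@dataclass
class Candidate:
    """One evaluated feature set (an iteration start or an accepted removal)."""

    features: tuple[str, ...]
    value: float
    order: int
    cv: CVResult | None = None


@dataclass
class MFSResult:
    iterations: list[IterationTrace]
    intermediates: list[tuple[tuple[str, ...], float]]
    candidates: list[Candidate]
    best: Candidate
    termination_reason: str  # "size_le_min" | "no_decrease"

    @property
    def best_features(self) -> tuple[str, ...]:
        return self.best.features

    @property
    def best_value(self) -> float:
        return self.best.value


def _iteration_seed(seed: int, iteration: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(iteration),))
    return int(ss.generate_state(1)[0] % (2**31))


def _resubstitution_evaluator(cfg: MFSConfig) -> Callable:
    """Deterministic index: train on all samples, score on the same samples."""
    def evaluate(ds, probes, seed):
        model = train_model(ds, probes, cfg.classifier)
        pred = model.predict(ds)
        c = confusion(ds.y(), pred, positive=1)
        value = {"mcc": mcc, "index1": index1, "index2": index2}[
            cfg.fitting_index
        ](c)
        return float(value), None

    return evaluate


def _cv_evaluator(cfg: MFSConfig) -> Callable:
    def evaluate(ds, probes, seed):
        res = evaluate_cv(
            ds, probes, cfg.classifier, folds=cfg.folds,
            repeats=cfg.repeats, seed=seed,
        )
        return res.index_mean(cfg.fitting_index), res

    return evaluate


def _visit_order(
    features: Sequence[str], cfg: MFSConfig
) -> list[str]:
    if cfg.elimination_order == "input_order":
        return list(features)
    w = cfg.weights or {}
    return sorted(features, key=lambda p: (w.get(p, 0.0), p))


def run_mfs(
    ds: LabeledExpressionDataset,
    features: Sequence[str],
    cfg: MFSConfig,
    evaluator: Callable | None = None,
) -> MFSResult:
    """Run backward stepwise elimination on ``features`` of ``ds``.

    ``evaluator(ds, probes, seed) -> (index value, CVResult | None)`` may be
    injected; by default it is repeated stratified CV (or resubstitution
    when ``cfg.evaluation == "resubstitution"``).
    """
    features = list(dict.fromkeys(features))
    if not features:
        raise ValidationError("empty feature list")
    ds.probe_index(features)  # raises KeyError on unknown probes
    if not ds.has_both_classes():
        raise ValidationError("both endpoint classes must be present")
    if evaluator is None:
        evaluator = (
            _resubstitution_evaluator(cfg)
            if cfg.evaluation == "resubstitution"
            else _cv_evaluator(cfg)
        )

    current = list(features)
    iterations: list[IterationTrace] = []
    intermediates: list[tuple[tuple[str, ...], float]] = []
    candidates: list[Candidate] = []
    order_counter = 0
    termination = None
    iteration = 0

    while termination is None:
        iteration += 1
        seed_i = _iteration_seed(cfg.seed, iteration)
        value, cvres = evaluator(ds, current, seed_i)
        candidates.append(
            Candidate(tuple(current), float(value), order_counter, cvres)
        )
        order_counter += 1
        start_features = tuple(current)
        start_value = float(value)

        if len(current) <= cfg.min_size:
            iterations.append(
                IterationTrace(
                    iteration, start_features, start_value, [],
                    tuple(current), float(value),
                )
            )
            termination = "size_le_min"
            break

        decisions: list[FeatureDecision] = []
        size_before = len(current)
        for probe in _visit_order(current, cfg):
            trial = [p for p in current if p != probe]
            try:
                new_value, new_cv = evaluator(ds, trial, seed_i)
            except Exception as exc:  # CV failure: keep the probe
                warnings.warn(
                    f"evaluation failed without probe {probe!r}: {exc}; "
                    "probe restored",
                    stacklevel=2,
                )
                decisions.append(FeatureDecision(probe, None, "restored_on_error"))
                continue
            if new_value < value:
                decisions.append(FeatureDecision(probe, new_value, "restored"))
            else:
                current = trial
                value = float(new_value)
                decisions.append(FeatureDecision(probe, new_value, "removed"))
                candidates.append(
                    Candidate(tuple(current), float(value), order_counter, new_cv)
                )
                order_counter += 1

        iterations.append(
            IterationTrace(
                iteration, start_features, start_value, decisions,
                tuple(current), float(value),
            )
        )
        if value > cfg.criteria_value:
            intermediates.append((tuple(current), float(value)))
        if len(current) <= cfg.min_size:
            termination = "size_le_min"
        elif len(current) == size_before:
            termination = "no_decrease"

    best = select_best_candidate(candidates)
    return MFSResult(
        iterations=iterations,
        intermediates=intermediates,
        candidates=candidates,
        best=best,
        termination_reason=termination,
    )


def select_best_candidate(candidates: Sequence[Candidate]) -> Candidate:
    """Max fitting-index value; ties prefer the smaller set, then the earlier."""
    if not candidates:
        raise ValidationError("no candidates recorded")
    return min(
        candidates, key=lambda c: (-c.value, len(c.features), c.order)
    )


def select_best(result: MFSResult) -> tuple[tuple[str, ...], CVResult | None]:
    """The recorded best model: (feature set, its CV result if available)."""
    best = select_best_candidate(result.candidates)
    return best.features, best.cv


def prepare_mfs_input(
    colls: SignatureCollection | Sequence[SignatureCollection],
    ds: LabeledExpressionDataset,
    min_support: int = 2,
    zero_sd_policy: str = "smallest",
) -> tuple[list[str], dict[str, float], dict]:
    """Build MFS's feature list and probe weights from signature collections.

    The feature list is the consensus set at ``min_support`` restricted to
    probes present in the dataset (a single input signature passes through
    unchanged).  Probe weights come from a weighted merge where each model
    weighs in with its MCC-robustness when per-model CV metadata
    (``mcc_mean``/``mcc_sd``) is available for every model, else uniformly.
    """
    if isinstance(colls, SignatureCollection):
        colls = [colls]
    colls = list(colls)
    if not colls or all(len(c) == 0 for c in colls):
        raise ValidationError("no input signatures")

    merged = SignatureCollection(
        endpoint_id=colls[0].endpoint_id,
        signatures=[
            s for c in colls for s in c
        ] if len(colls) == 1 else _relabel(colls),
    )

    n_models = len(merged)
    if n_models == 1:
        sig = merged.signatures[0]
        feats = [p for p in sig.probes if p in set(ds.probe_ids)]
        missing = [p for p in sig.probes if p not in set(ds.probe_ids)]
        if not feats:
            raise ValidationError("no signature probe is present in the dataset")
        weights = {p: 1.0 for p in feats}
        return feats, weights, {"missing_from_dataset": missing}

    model_weights = _model_weights(merged, zero_sd_policy)
    freq = probe_frequency(merged)
    cons = consensus_set(freq, min_support)
    ranked = weighted_merge(merged, model_weights)
    present = set(ds.probe_ids)
    feats = [p for p, _ in ranked if p in cons and p in present]
    missing = sorted(p for p in cons if p not in present)
    if not feats:
        raise ValidationError(
            f"consensus at min_support={min_support} has no probe "
            "present in the dataset"
        )
    weights = {p: w for p, w in ranked if p in cons}
    return feats, weights, {"missing_from_dataset": missing}


def _relabel(colls: Sequence[SignatureCollection]) -> list:
    out = []
    for c in colls:
        for s in c:
            s2 = type(s)(
                model_id=f"{c.endpoint_id}:{s.model_id}",
                endpoint_id=colls[0].endpoint_id,
                probes=list(s.probes),
                weights=list(s.weights) if s.weights else None,
                metadata=dict(s.metadata),
            )
            out.append(s2)
    return out


def _model_weights(
    coll: SignatureCollection, zero_sd_policy: str
) -> dict[str, float]:
    metas = [s.metadata for s in coll]
    if all("mcc_mean" in m and "mcc_sd" in m for m in metas):
        raw = []
        for m in metas:
            sd = float(m["mcc_sd"])
            mean = float(m["mcc_mean"])
            raw.append(float("inf") if sd == 0 else mean / sd)
        resolved = resolve_robustness_weights(raw, zero_sd_policy)
        return {
            s.model_id: max(w, 0.0) for s, w in zip(coll, resolved)
        }
    return {s.model_id: 1.0 for s in coll}


class MFSSelector(SelectorMixin, BaseEstimator):
    """Backward stepwise signature minimization as a scikit-learn selector.

    Parameters mirror :class:`MFSConfig`.  ``fit(X, y)`` runs the
    elimination over the columns of ``X``; ``transform`` keeps the best
    model's columns.

    Attributes
    ----------
    support_ : bool ndarray of shape (n_features,)
        Columns retained by the recorded best model.
    result_ : MFSResult
        Full elimination trace.
    best_score_ : float
        Fitting-index value of the best model.
    """

    def __init__(
        self,
        fitting_index: str = "mcc",
        criteria_value: float = 0.6,
        min_size: int = 5,
        classifier: ClassifierSpec | None = None,
        folds: int = 5,
        repeats: int = 10,
        seed: int = 0,
        elimination_order: str = "ascending_weight",
        weights: Mapping[str, float] | None = None,
        evaluation: str = "cv",
    ):
        self.fitting_index = fitting_index
        self.criteria_value = criteria_value
        self.min_size = min_size
        self.classifier = classifier
        self.folds = folds
        self.repeats = repeats
        self.seed = seed
        self.elimination_order = elimination_order
        self.weights = weights
        self.evaluation = evaluation

    def _config(self) -> MFSConfig:
        return MFSConfig(
            fitting_index=self.fitting_index,
            criteria_value=self.criteria_value,
            min_size=self.min_size,
            classifier=self.classifier or ClassifierSpec(),
            folds=self.folds,
            repeats=self.repeats,
            seed=self.seed,
            elimination_order=self.elimination_order,
            weights=self.weights,
            evaluation=self.evaluation,
        )

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X, y = check_X_y(X, y)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
        ds = LabeledExpressionDataset(
            sample_ids=[f"s{i}" for i in range(X.shape[0])],
            probe_ids=list(feature_names),
            values=X,
            labels=[str(int(v)) for v in y],
            positive_class="1",
        )
        cfg = self._config()
        self.result_ = run_mfs(ds, list(feature_names), cfg)
        kept = set(self.result_.best_features)
        self.support_ = np.array([p in kept for p in feature_names])
        self.best_score_ = self.result_.best_value
        self.n_features_in_ = X.shape[1]
        self.feature_names_ = list(feature_names)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_
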