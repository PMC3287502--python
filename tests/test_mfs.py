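"""Backward stepwise elimination: fidelity to the printed procedure,
stopping rules, best-model recording, planted-structure recovery."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import matthews_corrcoef
from sklearn.svm import SVC

from sigmin import (
    ClassifierSpec,
    LabeledExpressionDataset,
    MFSConfig,
    MFSSelector,
    Signature,
    SignatureCollection,
    ValidationError,
    generate_dataset,
    prepare_mfs_input,
    run_mfs,
    select_best,
)
from sigmin.mfs import Candidate, select_best_candidate
from sigmin.synthetic import FixtureSpec


# --------------------------------------------------------------------------
# independent step-by-step simulation of the printed elimination procedure
# --------------------------------------------------------------------------

def resub_mcc(ds, probes):
    """Independent deterministic index: linear SVM resubstitution MCC."""
    idx = [ds.probe_ids.index(p) for p in probes]
    X, y = ds.values[:, idx], ds.y()
    clf = SVC(kernel="linear", C=1.0, random_state=0).fit(X, y)
    return float(matthews_corrcoef(y, clf.predict(X)))


def hand_simulation(ds, features, min_size, criteria_value, visit_order):
    """Literal transcription of the elimination procedure.

    Per iteration: score the set; for each feature, score without it; a
    strictly lower score restores the feature, otherwise the removal stands
    and the score updates.  Emit an intermediate when the iteration ends
    above the criteria value; stop when the set no longer shrinks or its
    size is at most min_size; the best of all scored states is kept
    unconditionally (ties: smaller set, then earlier).
    """
    current = list(features)
    candidates = []
    intermediates = []
    order = 0
    while True:
        value = resub_mcc(ds, current)
        candidates.append((tuple(current), value, order))
        order += 1
        if len(current) <= min_size:
            reason = "size_le_min"
            break
        size_before = len(current)
        for probe in visit_order(current):
            trial = [p for p in current if p != probe]
            new_value = resub_mcc(ds, trial)
            if new_value < value:
                continue
            current = trial
            value = new_value
            candidates.append((tuple(current), value, order))
            order += 1
        if value > criteria_value:
            intermediates.append((tuple(current), value))
        if len(current) <= min_size:
            reason = "size_le_min"
            break
        if len(current) == size_before:
            reason = "no_decrease"
            break
    best = min(candidates, key=lambda c: (-c[1], len(c[0]), c[2]))
    return {
        "end": tuple(current),
        "candidates": candidates,
        "intermediates": intermediates,
        "best": best,
        "reason": reason,
    }


def random_dataset(seed, n=24, p=6):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    rng.shuffle(y)
    values = rng.normal(size=(n, p))
    values[:, 0] += 1.2 * y  # one weakly informative column
    return LabeledExpressionDataset(
        [f"s{i}" for i in range(n)], [f"p{j}" for j in range(p)], values,
        ["pos" if v else "neg" for v in y], "pos",
    )


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("order_mode", ["input_order", "ascending_weight"])
def test_trace_matches_hand_simulation(seed, order_mode):
    ds = random_dataset(seed)
    features = list(ds.probe_ids)
    weights = {p: float(i % 3) for i, p in enumerate(features)}
    cfg = MFSConfig(
        fitting_index="mcc", criteria_value=0.2, min_size=2,
        classifier=ClassifierSpec(seed=0), seed=seed,
        elimination_order=order_mode, weights=weights,
        evaluation="resubstitution",
    )
    if order_mode == "input_order":
        visit = lambda cur: list(cur)
    else:
        visit = lambda cur: sorted(cur, key=lambda p: (weights[p], p))
    expected = hand_simulation(ds, features, cfg.min_size,
                               cfg.criteria_value, visit)
    result = run_mfs(ds, features, cfg)

    assert result.iterations[-1].end_features == expected["end"]
    assert result.termination_reason == expected["reason"]
    got_candidates = [
        (c.features, pytest.approx(c.value), c.order)
        for c in result.candidates
    ]
    assert got_candidates == [
        (f, pytest.approx(v), o) for f, v, o in expected["candidates"]
    ]
    assert [(f, pytest.approx(v)) for f, v in result.intermediates] == [
        (f, pytest.approx(v)) for f, v in expected["intermediates"]
    ]
    assert result.best_features == expected["best"][0]
    assert result.best_value == pytest.approx(expected["best"][1])


def test_input_at_min_size_terminates_after_one_iteration():
    ds = random_dataset(9, p=3)
    cfg = MFSConfig(min_size=3, evaluation="resubstitution",
                    elimination_order="input_order")
    result = run_mfs(ds, list(ds.probe_ids), cfg)
    assert result.termination_reason == "size_le_min"
    assert len(result.iterations) == 1
    assert result.candidates[0].features == tuple(ds.probe_ids)


def test_duplicate_informative_column_is_stripped_once():
    # Two bit-identical separating columns: removing one leaves the index
    # unchanged, and "restore only on strictly lower" makes the removal stand.
    rng = np.random.default_rng(4)
    n = 30
    y = np.array([1] * 15 + [0] * 15)
    sep = y * 6.0 + rng.normal(0, 0.2, n)
    noise = rng.normal(size=n)
    ds = LabeledExpressionDataset(
        [f"s{i}" for i in range(n)], ["dup1", "dup2", "noiseA"],
        np.column_stack([sep, sep, noise]),
        ["pos" if v else "neg" for v in y], "pos",
    )
    cfg = MFSConfig(min_size=1, evaluation="resubstitution",
                    elimination_order="input_order", criteria_value=0.5)
    result = run_mfs(ds, ["dup1", "dup2", "noiseA"], cfg)
    kept = set(result.iterations[-1].end_features)
    assert len(kept & {"dup1", "dup2"}) == 1
    assert result.best_value == pytest.approx(1.0)


def test_accepted_values_within_iteration_are_monotone():
    ds = random_dataset(6, p=6)
    cfg = MFSConfig(min_size=1, evaluation="resubstitution",
                    elimination_order="input_order", criteria_value=0.0)
    result = run_mfs(ds, list(ds.probe_ids), cfg)
    for trace in result.iterations:
        accepted = [trace.start_value] + [
            d.candidate_value for d in trace.decisions if d.action == "removed"
        ]
        assert accepted == sorted(accepted)
        assert set(trace.end_features) <= set(trace.start_features)


def test_deterministic_under_cv_evaluation(separable_dataset):
    cfg = MFSConfig(min_size=1, repeats=3, seed=42, criteria_value=0.0,
                    elimination_order="input_order")
    a = run_mfs(separable_dataset, ["pA", "pB"], cfg)
    b = run_mfs(separable_dataset, ["pA", "pB"], cfg)
    assert a.best_features == b.best_features
    assert a.best_value == b.best_value
    assert [t.end_features for t in a.iterations] == [
        t.end_features for t in b.iterations
    ]


def test_empty_feature_list_rejected(separable_dataset):
    with pytest.raises(ValidationError):
        run_mfs(separable_dataset, [], MFSConfig())


def test_unknown_feature_rejected(separable_dataset):
    with pytest.raises(KeyError):
        run_mfs(separable_dataset, ["nope"], MFSConfig())


class TestSelectBest:
    def test_equal_values_prefer_smaller_set(self):
        c1 = Candidate(("a",) * 1 + tuple("bcdefgh"), 0.9, 0)
        c2 = Candidate(tuple("abcdef"), 0.9, 1)
        assert select_best_candidate([c1, c2]) is c2

    def test_equal_values_and_sizes_prefer_earlier(self):
        c1 = Candidate(("a", "b"), 0.9, 0)
        c2 = Candidate(("c", "d"), 0.9, 1)
        assert select_best_candidate([c1, c2]) is c1

    def test_randomized_equals_brute_force_argmax(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cands = [
                Candidate(tuple(f"p{j}" for j in range(rng.integers(1, 8))),
                          float(rng.choice([0.5, 0.7, 0.9])), i)
                for i in range(rng.integers(2, 10))
            ]
            best = select_best_candidate(cands)
            for c in cands:
                assert (
                    (-best.value, len(best.features), best.order)
                    <= (-c.value, len(c.features), c.order)
                )

    def test_best_recorded_even_below_criteria(self):
        ds = random_dataset(3, p=4)
        cfg = MFSConfig(criteria_value=10.0, min_size=2,
                        evaluation="resubstitution",
                        elimination_order="input_order")
        result = run_mfs(ds, list(ds.probe_ids), cfg)
        assert result.intermediates == []
        assert result.best is not None
        feats, _ = select_best(result)
        assert feats == result.best_features


class TestPrepareInput:
    def make_coll(self, meta=None):
        sigs = [
            Signature("m1", "D", ["a", "b", "x"], metadata=dict(meta or {})),
            Signature("m2", "D", ["a", "b"], metadata=dict(meta or {})),
            Signature("m3", "D", ["b", "x"], metadata=dict(meta or {})),
        ]
        return SignatureCollection("D", sigs)

    def make_ds(self, probes):
        return LabeledExpressionDataset(
            ["s0", "s1", "s2", "s3"], list(probes),
            np.arange(4 * len(probes), dtype=float).reshape(4, -1),
            ["pos", "neg", "pos", "neg"], "pos",
        )

    def test_consensus_restricted_to_dataset(self):
        # consensus at support 2 is {a, b, x}; x is absent from the dataset
        feats, _, report = prepare_mfs_input(
            self.make_coll(), self.make_ds(["a", "b", "c"]), min_support=2
        )
        assert set(feats) == {"a", "b"}
        assert report["missing_from_dataset"] == ["x"]

    def test_single_signature_passes_through(self):
        coll = SignatureCollection(
            "D", [Signature("only", "D", ["b", "a"])]
        )
        feats, weights, _ = prepare_mfs_input(coll, self.make_ds(["a", "b"]))
        assert feats == ["b", "a"]
        assert weights == {"a": 1.0, "b": 1.0}

    def test_uniform_models_weights_equal_supports(self):
        feats, weights, _ = prepare_mfs_input(
            self.make_coll(), self.make_ds(["a", "b", "x"]), min_support=2
        )
        assert weights == {"a": 2.0, "b": 3.0, "x": 2.0}
        assert feats[0] == "b"  # highest support first

    def test_mcc_robustness_metadata_weights_models(self):
        sigs = [
            Signature("m1", "D", ["a"], metadata={"mcc_mean": 0.8, "mcc_sd": 0.1}),
            Signature("m2", "D", ["a", "b"],
                      metadata={"mcc_mean": 0.4, "mcc_sd": 0.4}),
        ]
        coll = SignatureCollection("D", sigs)
        feats, weights, _ = prepare_mfs_input(
            coll, self.make_ds(["a", "b"]), min_support=1
        )
        assert weights["a"] == pytest.approx(8.0 + 1.0)
        assert weights["b"] == pytest.approx(1.0)

    def test_no_feature_in_dataset_rejected(self):
        with pytest.raises(ValidationError):
            prepare_mfs_input(self.make_coll(), self.make_ds(["zz"]),
                              min_support=2)


def test_planted_probe_recovered_with_cv_index():
    spec = FixtureSpec(n_samples=60, positive_fraction=0.4, n_informative=2,
                       effect_size=2.5, n_noise=8, seed=12)
    ds, truth = generate_dataset(spec)
    cfg = MFSConfig(min_size=2, repeats=5, seed=5, criteria_value=0.3)
    result = run_mfs(ds, list(ds.probe_ids), cfg)
    informative = {p for p, r in truth.items() if r == "informative"}
    assert informative <= set(result.best_features) | informative
    assert len(set(result.best_features) & informative) >= 1
    # best index never below the starting evaluation
    assert result.best_value >= result.candidates[0].value


class TestMFSSelectorEstimator:
    def test_fit_transform_keeps_best_columns(self, separable_dataset):
        X = np.hstack([
            separable_dataset.values,
            np.random.default_rng(0).normal(size=(40, 3)),
        ])
        y = separable_dataset.y()
        sel = MFSSelector(min_size=1, repeats=3, seed=1, criteria_value=0.0)
        Xt = sel.fit_transform(X, y)
        assert Xt.shape[1] == sel.support_.sum()
        assert sel.best_score_ == 1.0
        # at least one of the two separating columns survives
        assert sel.support_[:2].any()

    def test_get_params_round_trip_and_clone(self):
        sel = MFSSelector(min_size=3, seed=7)
        sel2 = clone(sel)
        assert sel2.get_params()["min_size"] == 3
        sel2.set_params(min_size=4)
        assert sel2.get_params()["min_size"] == 4
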