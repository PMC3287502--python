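import numpy as np
import pytest

from sigmin import (
    ClassifierSpec,
    LabeledExpressionDataset,
    Signature,
    SignatureCollection,
)


@pytest.fixture
def separable_dataset():
    """Two well-separated Gaussian clouds on 2 probes, n=40 (margin >> noise)."""
    rng = np.random.default_rng(7)
    n_per = 20
    pos = rng.normal(5.0, 0.3, size=(n_per, 2))
    neg = rng.normal(-5.0, 0.3, size=(n_per, 2))
    values = np.vstack([pos, neg])
    labels = ["pos"] * n_per + ["neg"] * n_per
    return LabeledExpressionDataset(
        sample_ids=[f"s{i}" for i in range(2 * n_per)],
        probe_ids=["pA", "pB"],
        values=values,
        labels=labels,
        positive_class="pos",
    )


@pytest.fixture
def small_collection():
    return SignatureCollection(
        endpoint_id="D",
        signatures=[
            Signature(model_id="m1", endpoint_id="D", probes=["a", "b", "c"]),
            Signature(model_id="m2", endpoint_id="D", probes=["b", "c", "d", "e"]),
            Signature(model_id="m3", endpoint_id="D", probes=["c", "e", "f"]),
        ],
    )


@pytest.fixture
def linear_spec():
    return ClassifierSpec(name="svm-linear", seed=0)
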